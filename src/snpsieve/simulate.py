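"""Balanced case-control simulation with a single causal SNP.

Individuals are formed by drawing two haplotypes uniformly with replacement
from a reference panel; disease status is assigned by retrospective rejection
sampling under the rare-disease approximation.  Controls are drawn from the
population genotype distribution; a candidate becomes a case with probability
``OR**e / max_e OR**e`` where ``e`` is the mode-encoded causal genotype, so
the sampled case/control genotype odds are exactly ``OR**e`` and a logistic
regression on the causal SNP estimates the specified per-allele log odds
ratio.  Case and control counts are always exactly equal.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .panel import HaplotypePanel, panel_maf

__all__ = [
    "CausalSpec",
    "CaseControlData",
    "select_causal_snp",
    "simulate_case_control",
    "encode_mode",
    "load_dose_data",
    "write_dose_data",
]

MODES = ("additive", "dominant", "recessive")


@dataclass(frozen=True)
class CausalSpec:
    """Causal-SNP specification: target MAF (or explicit index), per-allele
    odds ratio, and mode of inheritance."""

    target_maf: float = 0.2
    per_allele_or: float = 1.1
    mode: str = "additive"
    causal_index: int | None = None
    maf_tolerance: float = 0.02

    def __post_init__(self) -> None:
        if self.per_allele_or <= 0:
            raise ValueError("per_allele_or must be positive")
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")
        if self.causal_index is None and not (0.0 < self.target_maf <= 0.5):
            raise ValueError("target_maf must be in (0, 0.5]")


@dataclass
class CaseControlData:
    """Genotype doses with phenotypes for one simulated (or imputed) dataset.

    ``doses`` is n×p in [0, 2] (integers when simulated, possibly fractional
    when supplied as imputed doses), ``phenotype`` is n {0,1} with exactly
    equal class counts, and ``haplotypes`` (when simulated) is the underlying
    2n×p phased allele matrix whose column-pair sums equal the doses.
    """

    doses: np.ndarray
    phenotype: np.ndarray
    causal_index: int | None = None
    haplotypes: np.ndarray | None = None
    snp_ids: list[str] | None = None
    positions: np.ndarray | None = None
    map_cM: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.doses = np.asarray(self.doses)
        self.phenotype = np.asarray(self.phenotype, dtype=np.int8)
        n, p = self.doses.shape
        if self.phenotype.shape != (n,):
            raise ValueError("phenotype must align with dose rows")
        n_case = int(self.phenotype.sum())
        if 2 * n_case != n:
            raise ValueError(f"cases ({n_case}) and controls ({n - n_case}) must be equal")
        if self.doses.min() < 0 or self.doses.max() > 2:
            raise ValueError("doses must lie in [0, 2]")
        if self.causal_index is not None and not (0 <= self.causal_index < p):
            raise ValueError("causal_index out of range")
        if self.haplotypes is not None:
            hap = np.asarray(self.haplotypes, dtype=np.int8)
            if hap.shape != (2 * n, p):
                raise ValueError("haplotypes must be 2n x p")
            if not np.array_equal(hap[0::2] + hap[1::2], self.doses):
                raise ValueError("doses must equal haplotype column-pair sums")
            self.haplotypes = hap

    @property
    def n_individuals(self) -> int:
        return self.doses.shape[0]

    @property
    def n_snps(self) -> int:
        return self.doses.shape[1]

    @property
    def is_integral(self) -> bool:
        return bool(np.all(self.doses == np.round(self.doses)))


def select_causal_snp(panel: HaplotypePanel, target_maf: float,
                      tolerance: float = 0.02) -> int:
    """Index of the SNP whose MAF is nearest ``target_maf``; ties go to the
    lowest index.  Errors if no SNP lies within ``tolerance``."""
    maf = panel_maf(panel)
    dist = np.abs(maf - target_maf)
    best = int(np.argmin(dist))
    if dist[best] > tolerance:
        nearest = np.sort(maf[np.argsort(dist)[:5]])
        raise ValueError(
            f"no SNP within {tolerance} of MAF {target_maf}; nearest MAFs: "
            + ", ".join(f"{m:.3f}" for m in nearest))
    return best


def encode_mode(dose, mode: str):
    """Mode-of-inheritance encoding of a genotype dose in [0, 2].

    additive → the dose itself; dominant → carrier indicator (dose ≥ 1);
    recessive → homozygote indicator (dose = 2).  Fractional (imputed) doses
    use thresholds 0.5 and 1.5 respectively.
    """
    d = np.asarray(dose, dtype=float)
    if np.any(d < 0) or np.any(d > 2):
        raise ValueError("dose must lie in [0, 2]")
    if mode == "additive":
        out = d
    elif mode == "dominant":
        out = (d >= 0.5).astype(float)
    elif mode == "recessive":
        out = (d >= 1.5).astype(float)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return out if out.ndim else out.item()


def _resolve_causal(panel: HaplotypePanel, spec: CausalSpec) -> int:
    if spec.causal_index is not None:
        if not (0 <= spec.causal_index < panel.n_snps):
            raise ValueError("causal_index out of range for panel")
        return spec.causal_index
    return select_causal_snp(panel, spec.target_maf, spec.maf_tolerance)


def simulate_case_control(panel: HaplotypePanel, spec: CausalSpec, n_total: int,
                          seed: int, keep_haplotypes: bool = True,
                          max_draw_factor: int = 2000) -> CaseControlData:
    """Simulate a balanced case-control dataset from a haplotype panel.

    Deterministic given ``(panel, spec, n_total, seed)``.  The acceptance
    loop for cases aborts with an error if more than ``max_draw_factor``
    times the needed number of candidates is consumed (pathological for very
    large OR with a panel lacking risk-allele carriers).
    """
    if n_total % 2 or n_total < 2:
        raise ValueError("n_total must be even and >= 2")
    causal = _resolve_causal(panel, spec)
    causal_col = panel.alleles[:, causal]
    if causal_col.min() == causal_col.max():
        raise ValueError("causal SNP is monomorphic in the panel")

    rng = np.random.default_rng(seed)
    H = panel.n_haplotypes
    n_half = n_total // 2

    # acceptance probability per encoded causal genotype, normalized by max
    enc = np.array([encode_mode(g, spec.mode) for g in (0, 1, 2)])
    w = spec.per_allele_or ** enc
    accept_p = w / w.max()

    # controls: population draws (rare-disease approximation)
    ctrl_idx = rng.integers(0, H, size=(n_half, 2))

    # cases: rejection sampling on the encoded causal genotype
    case_rows: list[np.ndarray] = []
    n_have = 0
    n_drawn = 0
    budget = max_draw_factor * n_half
    while n_have < n_half:
        batch = max(256, 2 * (n_half - n_have))
        if n_drawn + batch > budget:
            batch = budget - n_drawn
            if batch <= 0:
                raise RuntimeError(
                    "case rejection sampling exhausted its retry budget; "
                    "use a larger panel or a smaller odds ratio")
        cand = rng.integers(0, H, size=(batch, 2))
        g = causal_col[cand[:, 0]] + causal_col[cand[:, 1]]
        keep = rng.random(batch) < accept_p[g]
        case_rows.append(cand[keep])
        n_have += int(keep.sum())
        n_drawn += batch
    case_idx = np.concatenate(case_rows)[:n_half]

    pair_idx = np.vstack([case_idx, ctrl_idx])
    hap = panel.alleles[pair_idx.reshape(-1)]
    doses = hap[0::2] + hap[1::2]
    phenotype = np.concatenate([np.ones(n_half, dtype=np.int8),
                                np.zeros(n_half, dtype=np.int8)])
    return CaseControlData(
        doses=doses.astype(np.int16),
        phenotype=phenotype,
        causal_index=causal,
        haplotypes=hap if keep_haplotypes else None,
        snp_ids=list(panel.snp_ids),
        positions=panel.positions.copy(),
        map_cM=panel.map_cM.copy(),
    )


# ---------------------------------------------------------------------------
# external genotype-dose input (e.g. imputed data)
# ---------------------------------------------------------------------------

def load_dose_data(path: str | Path, phenotype_column: str = "phenotype",
                   causal_index: int | None = None) -> CaseControlData:
    """Read a tab-separated dose matrix with a phenotype column.

    Rows are individuals; every column except ``phenotype_column`` is a SNP
    dose in [0, 2] (fractional doses from imputation are accepted).
    """
    df = pd.read_csv(path, sep="\t")
    if phenotype_column not in df.columns:
        raise ValueError(f"missing phenotype column {phenotype_column!r}")
    y = df[phenotype_column].to_numpy()
    doses = df.drop(columns=[phenotype_column])
    return CaseControlData(doses=doses.to_numpy(dtype=float), phenotype=y,
                           causal_index=causal_index,
                           snp_ids=list(doses.columns))


def write_dose_data(data: CaseControlData, path: str | Path,
                    phenotype_column: str = "phenotype") -> None:
    ids = data.snp_ids or [f"snp{i:05d}" for i in range(data.n_snps)]
    df = pd.DataFrame(data.doses, columns=ids)
    df[phenotype_column] = data.phenotype
    df.to_csv(path, sep="\t", index=False)
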