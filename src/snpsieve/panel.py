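"""Haplotype reference panels: synthetic generation and real-panel IO.

A fine-mapped region is represented as a :class:`HaplotypePanel` — a matrix of
phased binary haplotypes with physical (bp) and genetic-map (cM) coordinates.
Panels either come from an external phased reference (IMPUTE hap/legend or a
phased VCF, plus a recombination map) or from the built-in founder-mosaic
generator, which produces block-structured linkage disequilibrium (LD) with a
controllable mean block length so that "high", "mixed" and "low" LD regions
(block scales of roughly 130, 22 and 8 kb) can be emulated without any
external download.

The generative model: the region is chopped into blocks with exponentially
distributed lengths (mean ``mean_block_kb``); within each block a small set of
founder haplotypes is drawn and every output haplotype copies one founder
(founder choice is independent across blocks, optionally with a rare per-site
copy error).  Limited within-block haplotype diversity yields high within-block
LD, while independent founder choice across blocks breaks LD at block
boundaries — the single controlled variable of the simulation study.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

__all__ = [
    "MafSpectrum",
    "RegionProfile",
    "HaplotypePanel",
    "PanelGenerationError",
    "generate_panel",
    "panel_maf",
    "load_panel",
    "write_panel",
    "read_recombination_map",
    "interpolate_map",
    "HIGH_LD_PROFILE",
    "MIXED_LD_PROFILE",
    "LOW_LD_PROFILE",
]

logger = logging.getLogger(__name__)


class PanelGenerationError(RuntimeError):
    """Raised when a valid polymorphic panel cannot be generated."""


@dataclass(frozen=True)
class MafSpectrum:
    """Allele-frequency distribution for founder haplotypes.

    Target frequencies are drawn as ``low + (high - low) * Beta(a, b)``; the
    default shape (a=0.4, b=1.5) is strongly skewed toward rare alleles, with
    a floor of 0.01, mirroring the rare-heavy site-frequency spectrum of
    sequenced reference panels (roughly 40% of sites below MAF 0.05).
    """

    low: float = 0.01
    high: float = 0.5
    a: float = 0.4
    b: float = 1.5

    def __post_init__(self) -> None:
        if not (0.0 < self.low < self.high <= 0.5):
            raise ValueError(f"require 0 < low < high <= 0.5, got [{self.low}, {self.high}]")
        if self.a <= 0 or self.b <= 0:
            raise ValueError("beta shape parameters must be positive")

    def sample(self, size: int, rng: np.random.Generator) -> np.ndarray:
        return self.low + (self.high - self.low) * rng.beta(self.a, self.b, size=size)


@dataclass(frozen=True)
class RegionProfile:
    """Parameters of a synthetic 1 Mb-scale region.

    Parameters
    ----------
    n_snps : number of SNPs placed uniformly at random in the region.
    region_length_bp : physical length of the region in base pairs.
    mean_block_kb : mean LD-block length in kb (exponential block lengths).
        130 / 22 / 8 emulate high / mixed / low LD regions.
    n_founders : distinct ancestral haplotypes per block; fewer founders means
        stronger within-block LD.
    maf_spectrum : distribution of target allele frequencies.
    cm_per_mb : background recombination rate for the genetic map.
    hotspot_cM : extra map distance inserted at each block boundary,
        co-locating recombination hotspots with LD-block edges.
    copy_error : per-site probability that a haplotype's copy of its founder
        is flipped; keeps within-block LD just below 1 as in real data.
    seed : generator seed; equal profiles give bit-identical panels.
    """

    n_snps: int = 300
    region_length_bp: int = 1_000_000
    mean_block_kb: float = 22.0
    n_founders: int = 8
    maf_spectrum: MafSpectrum = field(default_factory=MafSpectrum)
    cm_per_mb: float = 1.0
    hotspot_cM: float = 0.05
    copy_error: float = 0.002
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_snps < 2:
            raise ValueError("n_snps must be >= 2")
        if self.mean_block_kb <= 0:
            raise ValueError("mean_block_kb must be positive")
        if self.n_founders < 2:
            raise ValueError("n_founders must be >= 2")
        if self.cm_per_mb < 0 or self.hotspot_cM < 0:
            raise ValueError("map rates must be nonnegative")
        if not (0.0 <= self.copy_error < 0.5):
            raise ValueError("copy_error must be in [0, 0.5)")
        if self.region_length_bp < self.n_snps:
            raise ValueError("region too short for requested SNP count")

    def with_seed(self, seed: int) -> "RegionProfile":
        return replace(self, seed=seed)


#: Ready-made profiles for the three LD regimes of the study design.
HIGH_LD_PROFILE = RegionProfile(mean_block_kb=130.0)
MIXED_LD_PROFILE = RegionProfile(mean_block_kb=22.0)
LOW_LD_PROFILE = RegionProfile(mean_block_kb=8.0)


@dataclass
class HaplotypePanel:
    """Phased binary haplotypes over a region.

    ``alleles`` is an H×p {0,1} matrix (H haplotypes, p SNPs), ``positions``
    are strictly increasing 1-based bp coordinates, ``map_cM`` is the
    nondecreasing cumulative genetic map, ``snp_ids`` are unique labels, and
    ``block_bounds`` (synthetic panels only) lists the SNP index starting each
    LD block.
    """

    alleles: np.ndarray
    positions: np.ndarray
    map_cM: np.ndarray
    snp_ids: list[str]
    block_bounds: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.map_cM = np.asarray(self.map_cM, dtype=float)
        self.snp_ids = list(self.snp_ids)
        if self.block_bounds is not None:
            self.block_bounds = np.asarray(self.block_bounds, dtype=np.int64)
        self.validate()

    # -- invariants -------------------------------------------------------
    def validate(self) -> None:
        H, p = self.alleles.shape
        if H < 2 or H % 2:
            raise ValueError(f"need an even number >= 2 of haplotypes, got {H}")
        if not np.isin(self.alleles, (0, 1)).all():
            raise ValueError("allele codes must be 0/1")
        if self.positions.shape != (p,) or self.map_cM.shape != (p,):
            raise ValueError("positions/map_cM must align with SNP count")
        if p and np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")
        if p and np.any(np.diff(self.map_cM) < 0):
            raise ValueError("map_cM must be nondecreasing")
        if len(self.snp_ids) != p or len(set(self.snp_ids)) != p:
            raise ValueError("snp_ids must be unique and align with SNP count")
        if self.block_bounds is not None and len(self.block_bounds):
            bb = self.block_bounds
            if bb[0] < 0 or bb[-1] >= p or np.any(np.diff(bb) <= 0):
                raise ValueError("block_bounds must be strictly increasing within [0, p)")

    @property
    def n_haplotypes(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_snps(self) -> int:
        return self.alleles.shape[1]

    def maf(self) -> np.ndarray:
        return panel_maf(self)


def panel_maf(panel: HaplotypePanel) -> np.ndarray:
    """Minor-allele frequency per SNP: ``min(f, 1 - f)`` with ``f`` the
    allele-1 frequency over haplotypes.  Entries lie in [0, 0.5]."""
    f = panel.alleles.mean(axis=0)
    return np.minimum(f, 1.0 - f)


# ---------------------------------------------------------------------------
# synthetic generation
# ---------------------------------------------------------------------------

def _block_partition(positions: np.ndarray, region_length: int,
                     mean_block_bp: float, rng: np.random.Generator) -> np.ndarray:
    """SNP index starting each (non-empty) block; always begins with 0."""
    edges = [0.0]
    while edges[-1] < region_length:
        edges.append(edges[-1] + rng.exponential(mean_block_bp))
    # block id per SNP, then first SNP index of each realized block
    block_of = np.searchsorted(np.asarray(edges[1:-1]), positions, side="right")
    starts = np.flatnonzero(np.diff(block_of, prepend=block_of[0] - 1))
    return starts


def _choose_carriers(weights: np.ndarray, f: float,
                     rng: np.random.Generator) -> tuple[np.ndarray, float]:
    """Pick a founder carrier subset whose total weight approximates ``f``.

    Greedy subset-sum over founders in random order keeps the realized panel
    allele frequency close to the target.  If the best subset undershoots
    badly (below f/2 — possible when one founder weight is tiny), the subset
    is extended past ``f`` and thinned back down, so the realized frequency
    never collapses far below the requested spectrum floor.  Returns a
    boolean carrier mask (non-empty) and a per-carrier keep probability
    (1.0 when no thinning is needed).
    """
    k = len(weights)
    order = rng.permutation(k)
    mask = np.zeros(k, dtype=bool)
    total = 0.0
    for j in order:
        if abs(total + weights[j] - f) < abs(total - f):
            mask[j] = True
            total += weights[j]
    if not mask.any():
        j = int(np.argmin(np.abs(weights - f)))
        mask[j] = True
        total = float(weights[j])
    keep = 1.0
    if total < 0.7 * f:
        for j in order:
            if not mask[j]:
                mask[j] = True
                total += weights[j]
                if total >= f:
                    break
        keep = min(1.0, f / total)
    elif mask.all():
        # realized frequency 1 is monomorphic; drop one carrier
        mask[order[-1]] = False
    return mask, keep


def generate_panel(profile: RegionProfile, n_haplotypes: int,
                   max_retries: int = 20) -> HaplotypePanel:
    """Generate a synthetic block-structured haplotype panel.

    Every SNP in the returned panel is polymorphic; monomorphic draws are
    regenerated with perturbed founder frequencies up to ``max_retries`` times
    before :class:`PanelGenerationError` is raised.  Deterministic given
    ``profile`` (including its seed) and ``n_haplotypes``.
    """
    if n_haplotypes % 2 or n_haplotypes < 2:
        raise ValueError("n_haplotypes must be even and >= 2")
    if n_haplotypes < 2 * profile.n_founders:
        raise ValueError("n_haplotypes must be >= 2 * n_founders")

    rng = np.random.default_rng(profile.seed)
    spectrum = profile.maf_spectrum

    positions = np.sort(rng.choice(profile.region_length_bp, size=profile.n_snps,
                                   replace=False)) + 1
    block_starts = _block_partition(positions, profile.region_length_bp,
                                    profile.mean_block_kb * 1000.0, rng)

    p = profile.n_snps
    nf = profile.n_founders
    alleles = np.empty((n_haplotypes, p), dtype=np.int8)
    freqs = spectrum.sample(p, rng)
    block_ends = np.r_[block_starts[1:], p]
    assignments: list[np.ndarray] = []

    for start, end in zip(block_starts, block_ends):
        weights = rng.dirichlet(np.full(nf, 4.0))
        founders = np.zeros((nf, end - start), dtype=np.int8)
        # target frequencies the founder-subset granularity cannot reach are
        # modelled as young mutations: a single founder background thinned
        # down to the target (keep probability < 1)
        thin_keep = np.ones(end - start)
        w_min = weights.min()
        for local, s in enumerate(range(start, end)):
            f = freqs[s]
            if f < w_min / 2.0:
                j = int(np.argmin(weights))
                founders[j, local] = 1
                thin_keep[local] = f / w_min
            else:
                mask, keep = _choose_carriers(weights, f, rng)
                founders[mask, local] = 1
                thin_keep[local] = keep
        assign = rng.choice(nf, size=n_haplotypes, p=weights)
        assignments.append(assign)
        block_alleles = founders[assign]
        rare = np.flatnonzero(thin_keep < 1.0)
        for local in rare:
            keep = rng.random(n_haplotypes) < thin_keep[local]
            block_alleles[:, local] &= keep
        alleles[:, start:end] = block_alleles

    if profile.copy_error > 0:
        flips = rng.random(alleles.shape) < profile.copy_error
        alleles ^= flips.astype(np.int8)

    # repair monomorphic columns: redraw the founder carrier set with the
    # frequency perturbed toward common, then re-copy that column
    block_of = np.searchsorted(block_starts, np.arange(p), side="right") - 1
    for attempt in range(max_retries):
        mono = np.flatnonzero((alleles.sum(0) == 0) | (alleles.sum(0) == n_haplotypes))
        if mono.size == 0:
            break
        for s in mono:
            b = block_of[s]
            start = block_starts[b]
            assign = assignments[b]
            weights = np.bincount(assign, minlength=nf) / n_haplotypes
            f_new = rng.uniform(0.25, 0.5)
            mask, keep = _choose_carriers(np.maximum(weights, 1e-9), f_new, rng)
            col = mask.astype(np.int8)[assign]
            if keep < 1.0:
                col &= rng.random(n_haplotypes) < keep
            if profile.copy_error > 0:
                col ^= (rng.random(n_haplotypes) < profile.copy_error).astype(np.int8)
            alleles[:, s] = col
    else:
        raise PanelGenerationError(
            f"could not make all SNPs polymorphic after {max_retries} retries")

    map_cM = _synthetic_map(positions, block_starts, profile)
    snp_ids = [f"snp{i:05d}" for i in range(p)]
    return HaplotypePanel(alleles, positions, map_cM, snp_ids, block_bounds=block_starts)


def _synthetic_map(positions: np.ndarray, block_starts: np.ndarray,
                   profile: RegionProfile) -> np.ndarray:
    """Cumulative cM: background cm_per_mb plus a hotspot at each block start."""
    gaps = np.diff(positions) * (profile.cm_per_mb / 1e6)
    map_cM = np.concatenate([[0.0], np.cumsum(gaps)])
    hot = np.zeros(len(positions))
    hot[block_starts[block_starts > 0]] = profile.hotspot_cM
    return map_cM + np.cumsum(hot)


# ---------------------------------------------------------------------------
# real-panel IO
# ---------------------------------------------------------------------------

def read_recombination_map(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read a 3-column recombination map: position(bp), rate(cM/Mb),
    cumulative map(cM).  A header line is tolerated."""
    pos, cum = [], []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            try:
                row = [float(v) for v in parts[:3]]
            except ValueError:
                continue  # header
            if len(row) < 3:
                raise ValueError(f"map line needs 3 columns: {line.rstrip()!r}")
            pos.append(row[0])
            cum.append(row[2])
    if not pos:
        raise ValueError(f"no usable rows in map file {path}")
    pos_a = np.asarray(pos)
    cum_a = np.asarray(cum)
    if np.any(np.diff(pos_a) <= 0):
        raise ValueError("map positions must be strictly increasing")
    return pos_a, cum_a


def interpolate_map(positions: np.ndarray, map_pos: np.ndarray,
                    map_cum: np.ndarray) -> np.ndarray:
    """Linear interpolation of the cumulative map at SNP positions, with
    constant extrapolation beyond the map ends."""
    return np.interp(np.asarray(positions, dtype=float), map_pos, map_cum)


def _default_map(positions: np.ndarray, cm_per_mb: float = 1.0) -> np.ndarray:
    return (positions - positions[0]) * (cm_per_mb / 1e6)


def _drop_monomorphic(alleles: np.ndarray, positions: np.ndarray,
                      snp_ids: list[str]) -> tuple[np.ndarray, np.ndarray, list[str]]:
    counts = alleles.sum(0)
    keep = (counts > 0) & (counts < alleles.shape[0])
    n_drop = int((~keep).sum())
    if n_drop:
        logger.warning("dropping %d monomorphic site(s) from loaded panel", n_drop)
        warnings.warn(f"dropped {n_drop} monomorphic site(s)", stacklevel=3)
    return alleles[:, keep], positions[keep], [s for s, k in zip(snp_ids, keep) if k]


def _read_hap_legend(hap_path: Path, legend_path: Path,
                     transposed: bool) -> tuple[np.ndarray, np.ndarray, list[str]]:
    ids: list[str] = []
    positions: list[int] = []
    with open(legend_path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if len(parts) < 4:
                raise ValueError(f"legend line needs 4 columns: {line.rstrip()!r}")
            try:
                pos = int(parts[1])
            except ValueError:
                continue  # header
            ids.append(parts[0])
            positions.append(pos)
    hap = np.loadtxt(hap_path, dtype=np.int8, ndmin=2)
    if not transposed:
        hap = hap.T  # file is SNP-per-row, haplotype-per-column
    if hap.shape[1] != len(ids):
        raise ValueError(
            f"hap file has {hap.shape[1]} SNPs but legend lists {len(ids)}")
    return hap, np.asarray(positions, dtype=np.int64), ids


def _read_phased_vcf(path: Path, strict: bool) -> tuple[np.ndarray, np.ndarray, list[str]]:
    from cyvcf2 import VCF

    cols: list[np.ndarray] = []
    positions: list[int] = []
    ids: list[str] = []
    vcf = VCF(str(path))
    for var in vcf:
        if len(var.ALT) != 1:
            if strict:
                raise ValueError(f"multiallelic record at {var.CHROM}:{var.POS}")
            continue
        gts = var.genotypes  # [[a0, a1, phased], ...]
        if any((not g[-1]) or g[0] < 0 or g[1] < 0 for g in gts):
            if strict:
                raise ValueError(f"unphased or missing genotype at {var.CHROM}:{var.POS}")
            continue
        cols.append(np.asarray([a for g in gts for a in g[:-1]], dtype=np.int8))
        positions.append(var.POS)
        ids.append(var.ID if var.ID else f"{var.CHROM}:{var.POS}")
    vcf.close()
    if not cols:
        raise ValueError(f"no usable biallelic phased records in {path}")
    return np.column_stack(cols), np.asarray(positions, dtype=np.int64), ids


def load_panel(haplotype_file: str | Path,
               legend_file: str | Path | None = None,
               map_file: str | Path | None = None,
               format: str = "impute-hap-legend",
               strict: bool = True,
               transposed: bool = False,
               cm_per_mb: float = 1.0) -> HaplotypePanel:
    """Load a phased reference panel.

    Parameters
    ----------
    haplotype_file : hap file (IMPUTE) or phased VCF.
    legend_file : legend file (IMPUTE format only).
    map_file : optional recombination map (position, rate, cumulative cM);
        when absent the genetic map defaults to a uniform ``cm_per_mb``.
    format : ``"impute-hap-legend"`` or ``"phased-vcf"``.
    strict : raise on unphased/multiallelic records instead of skipping.
    transposed : IMPUTE dialect with one row per haplotype.

    Monomorphic sites are dropped with a warning: they carry no association
    information and break the LD formulas downstream.
    """
    haplotype_file = Path(haplotype_file)
    if format == "impute-hap-legend":
        if legend_file is None:
            raise ValueError("impute-hap-legend format requires a legend file")
        alleles, positions, ids = _read_hap_legend(haplotype_file, Path(legend_file),
                                                   transposed)
    elif format == "phased-vcf":
        alleles, positions, ids = _read_phased_vcf(haplotype_file, strict)
    else:
        raise ValueError(f"unknown panel format {format!r}")

    order = np.argsort(positions, kind="stable")
    alleles, positions = alleles[:, order], positions[order]
    ids = [ids[i] for i in order]
    alleles, positions, ids = _drop_monomorphic(alleles, positions, ids)

    if map_file is not None:
        map_pos, map_cum = read_recombination_map(map_file)
        map_cM = interpolate_map(positions, map_pos, map_cum)
    else:
        map_cM = _default_map(positions, cm_per_mb)
    return HaplotypePanel(alleles, positions, map_cM, ids)


# ---------------------------------------------------------------------------
# writers (round-trip partners of load_panel)
# ---------------------------------------------------------------------------

def write_panel(panel: HaplotypePanel, haplotype_file: str | Path,
                legend_file: str | Path | None = None,
                format: str = "impute-hap-legend") -> None:
    """Write a panel as IMPUTE hap/legend or as a minimal phased VCF."""
    if format == "impute-hap-legend":
        if legend_file is None:
            raise ValueError("impute-hap-legend format requires a legend path")
        with open(legend_file, "w") as fh:
            fh.write("id position allele0 allele1\n")
            for sid, pos in zip(panel.snp_ids, panel.positions):
                fh.write(f"{sid} {pos} A G\n")
        np.savetxt(haplotype_file, panel.alleles.T, fmt="%d", delimiter=" ")
    elif format == "phased-vcf":
        n_samples = panel.n_haplotypes // 2
        with open(haplotype_file, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
            fh.write("##contig=<ID=1>\n")
            samples = "\t".join(f"S{i}" for i in range(n_samples))
            fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{samples}\n")
            for j, (sid, pos) in enumerate(zip(panel.snp_ids, panel.positions)):
                col = panel.alleles[:, j]
                gts = "\t".join(f"{col[2 * i]}|{col[2 * i + 1]}" for i in range(n_samples))
                fh.write(f"1\t{pos}\t{sid}\tA\tG\t.\tPASS\t.\tGT\t{gts}\n")
    else:
        raise ValueError(f"unknown panel format {format!r}")


def write_recombination_map(panel: HaplotypePanel, path: str | Path) -> None:
    """Write the panel's genetic map in the 3-column map format."""
    pos = panel.positions.astype(float)
    cum = panel.map_cM
    with np.errstate(divide="ignore", invalid="ignore"):
        rate = np.zeros_like(cum)
        dp = np.diff(pos)
        rate[:-1] = np.where(dp > 0, np.diff(cum) / dp * 1e6, 0.0)
    with open(path, "w") as fh:
        fh.write("position rate(cM/Mb) map(cM)\n")
        for row in zip(pos, rate, cum):
            fh.write(f"{row[0]:.0f} {row[1]:.8f} {row[2]:.8f}\n")
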