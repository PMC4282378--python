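"""Threshold-averaged ROC evaluation and scenario orchestration.

A *scenario* fixes a region (panel or generator profile), a causal SNP
(MAF/OR/mode), a total sample size, and a replicate count.  Each replicate
simulates a balanced case-control dataset, scans it, profiles LD against the
top hit, and applies every requested filter over its threshold grid.  Across
replicates the per-threshold results are combined by threshold averaging:
the x-coordinate is the mean FPR (mean proportion of noncausal SNPs
retained) and the y-coordinate the TPR (proportion of replicates retaining
the causal SNP), with FPR dispersion (median, IQR, range) and binomial TPR
variance TPR(1-TPR)/n attached per threshold.  Curves are summarised by the
trapezoidal AUC and the partial AUC restricted to mean FPR <= 0.1 (maximum
10), both as percentages of the unit square.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from . import __version__ as _version
from .assoc import AssocTable, scan_region
from .filters import METHODS, FilterSpec, ReplicateOutcome, apply_filter, \
    lp_retained_count, relative_likelihoods
from .ld import LdProfile, build_ld_profile, default_tag_indices
from .panel import HaplotypePanel, MafSpectrum, RegionProfile, generate_panel
from .simulate import CausalSpec, simulate_case_control

__all__ = [
    "Scenario",
    "RocCurve",
    "ScenarioReport",
    "threshold_average",
    "auc_trapezoid",
    "tpr_variance",
    "fpr_dispersion",
    "default_threshold_grid",
    "run_scenario",
    "scenario_from_config",
]

logger = logging.getLogger(__name__)

LD_METHODS = ("gmd", "r2", "dprime", "pld")
#: offset separating the permutation RNG stream from the simulation stream
_PERM_SEED_OFFSET = 1_000_003


# ---------------------------------------------------------------------------
# elementary summaries
# ---------------------------------------------------------------------------

def tpr_variance(tpr: float, n_replicates: int) -> float:
    """Binomial variance of a TPR estimate: ``tpr (1 - tpr) / n``."""
    if not (0.0 <= tpr <= 1.0):
        raise ValueError("tpr must lie in [0, 1]")
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    return tpr * (1.0 - tpr) / n_replicates


def fpr_dispersion(fprs: Sequence[float]):
    """(median, (q25, q75), (min, max)) of per-replicate FPR values,
    quantiles by linear interpolation."""
    a = np.asarray(fprs, dtype=float)
    if a.size == 0:
        raise ValueError("need at least one FPR value")
    q25, q75 = np.quantile(a, [0.25, 0.75])
    return float(np.median(a)), (float(q25), float(q75)), \
        (float(a.min()), float(a.max()))


def auc_trapezoid(curve, fpr_max: float = 1.0) -> float:
    """Trapezoidal area under a threshold-averaged ROC curve, as a
    percentage of the unit square.

    Accepts a :class:`RocCurve` or a ``(mean_fpr, tpr)`` pair of arrays.
    The endpoints (0,0) and (1,1) are appended before integration; with
    ``fpr_max`` < 1 the curve is linearly interpolated at the boundary, so
    the maximum partial area at ``fpr_max = 0.1`` is 10.
    """
    if isinstance(curve, RocCurve):
        fpr, tpr = curve.mean_fpr, curve.tpr
    else:
        fpr, tpr = curve
    f = np.r_[np.asarray(fpr, dtype=float), 0.0, 1.0]
    t = np.r_[np.asarray(tpr, dtype=float), 0.0, 1.0]
    order = np.lexsort((t, f))
    f, t = f[order], t[order]
    if fpr_max < 1.0:
        t_b = float(np.interp(fpr_max, f, t))
        mask = f <= fpr_max
        f = np.r_[f[mask], fpr_max]
        t = np.r_[t[mask], t_b]
    return float(100.0 * np.trapezoid(t, f))


# ---------------------------------------------------------------------------
# curves
# ---------------------------------------------------------------------------

@dataclass
class RocCurve:
    """Threshold-averaged ROC curve for one filter.

    Per threshold: the mean FPR over replicates, the TPR (share of
    replicates retaining the causal SNP), the FPR dispersion and the
    binomial TPR variance.  ``replicate_fpr``/``replicate_causal`` keep the
    raw per-replicate values (thresholds x replicates) for resampling-based
    uncertainty estimates.
    """

    thresholds: list
    mean_fpr: np.ndarray
    tpr: np.ndarray
    fpr_median: np.ndarray
    fpr_q25: np.ndarray
    fpr_q75: np.ndarray
    fpr_min: np.ndarray
    fpr_max: np.ndarray
    tpr_var: np.ndarray
    n_replicates: int
    auc: float = 0.0
    pauc_01: float = 0.0
    replicate_fpr: np.ndarray | None = None
    replicate_causal: np.ndarray | None = None

    @property
    def points(self) -> np.ndarray:
        return np.column_stack([self.mean_fpr, self.tpr])


def _curve_from_arrays(thresholds, fpr_tr: np.ndarray,
                       causal_tr: np.ndarray) -> RocCurve:
    fpr_tr = np.asarray(fpr_tr, dtype=float)
    causal_tr = np.asarray(causal_tr, dtype=float)
    n_rep = fpr_tr.shape[1]
    tpr = causal_tr.mean(axis=1)
    q = np.quantile(fpr_tr, [0.25, 0.5, 0.75], axis=1)
    curve = RocCurve(
        thresholds=list(thresholds),
        mean_fpr=fpr_tr.mean(axis=1),
        tpr=tpr,
        fpr_median=q[1],
        fpr_q25=q[0],
        fpr_q75=q[2],
        fpr_min=fpr_tr.min(axis=1),
        fpr_max=fpr_tr.max(axis=1),
        tpr_var=tpr * (1 - tpr) / n_rep,
        n_replicates=n_rep,
        replicate_fpr=fpr_tr,
        replicate_causal=causal_tr,
    )
    curve.auc = auc_trapezoid(curve)
    curve.pauc_01 = auc_trapezoid(curve, fpr_max=0.1)
    return curve


def threshold_average(outcomes: Sequence[Sequence[ReplicateOutcome]],
                      thresholds: Sequence | None = None) -> RocCurve:
    """Combine per-replicate outcomes into a threshold-averaged curve.

    ``outcomes[t][r]`` is the outcome of replicate ``r`` at threshold ``t``;
    replicate counts must agree across thresholds.
    """
    if len(outcomes) == 0:
        raise ValueError("need at least one threshold")
    n_rep = len(outcomes[0])
    if n_rep == 0 or any(len(row) != n_rep for row in outcomes):
        raise ValueError("inconsistent replicate counts across thresholds")
    fpr = np.array([[o.fpr for o in row] for row in outcomes])
    causal = np.array([[o.causal_retained for o in row] for row in outcomes],
                      dtype=float)
    if thresholds is None:
        thresholds = list(range(len(outcomes)))
    return _curve_from_arrays(thresholds, fpr, causal)


# ---------------------------------------------------------------------------
# threshold grids
# ---------------------------------------------------------------------------

def default_threshold_grid(method: str, n_tags: int = 77,
                           cm_values: np.ndarray | None = None) -> np.ndarray:
    """Default sweep grid for a method, ordered strict -> relaxed."""
    if method == "pvalue":
        return np.logspace(-12, 0, 61)
    if method == "rl":
        return np.logspace(0, -6, 61)
    if method == "lp":
        return np.arange(99.0, 0.0, -1.0)
    if method in ("r2", "dprime"):
        return np.linspace(1.0, 0.0, 101)
    if method == "gmd":
        if cm_values is None:
            raise ValueError("gmd grid needs observed cM distances")
        finite = np.asarray(cm_values)[np.isfinite(cm_values)]
        return np.unique(np.r_[0.0, np.quantile(finite, np.linspace(0, 1, 51))])
    if method == "pld":
        levels = np.arange(n_tags + 1) / n_tags
        sub = np.array([0.05, 0.25, 0.5, 1.0]) / (2.0 * n_tags)
        return np.sort((levels[:, None] + sub[None, :]).ravel())
    raise ValueError(f"unknown filter method {method!r}")


def _native_values(method: str, table: AssocTable,
                   profile: LdProfile | None) -> np.ndarray:
    """Native statistic vector for a method, with degenerate SNPs pushed to
    the never/last-retained end of the scale."""
    degen = table.degenerate
    if method == "pvalue":
        p = np.where(np.isnan(table.ca_p), table.wald_p, table.ca_p)
        return np.where(degen, 1.0, p)
    if method == "rl":
        return relative_likelihoods(np.where(degen, -np.inf, table.loglik))
    if method == "lp":
        return np.where(degen, -np.inf, table.loglik)
    if profile is None:
        raise ValueError(f"method {method!r} needs an LdProfile")
    if method == "gmd":
        return np.where(degen, np.inf, profile.cm_to_top)
    if method == "r2":
        return np.where(degen, 0.0, profile.r2_to_top)
    if method == "dprime":
        return np.where(degen, 0.0, profile.dprime_to_top)
    if method == "pld":
        T = max(1, profile.n_tags)
        score = profile.pld + profile.perm_p / (2.0 * T)
        return np.where(degen, 2.0, score)
    raise ValueError(f"unknown filter method {method!r}")


_RETAIN_GEQ = {"rl", "r2", "dprime"}   # retain values >= threshold
_RETAIN_LEQ = {"pvalue", "gmd", "pld"}  # retain values <= threshold


def _sweep(method: str, values: np.ndarray, grid: np.ndarray,
           causal_index: int) -> tuple[np.ndarray, np.ndarray]:
    """(fpr, causal_retained) along a grid for one replicate (vectorised)."""
    p = len(values)
    if method == "lp":
        order = np.argsort(-values, kind="stable")
        rank = np.empty(p, dtype=int)
        rank[order] = np.arange(p)
        ks = np.array([lp_retained_count(p, q) for q in grid])
        n_ret = ks
        causal = rank[causal_index] < ks
    elif method in _RETAIN_GEQ:
        retained = values[None, :] >= grid[:, None]
        n_ret = retained.sum(axis=1)
        causal = retained[:, causal_index]
    else:
        retained = values[None, :] <= grid[:, None]
        n_ret = retained.sum(axis=1)
        causal = retained[:, causal_index]
    fpr = (n_ret - causal.astype(int)) / (p - 1)
    return fpr.astype(float), causal.astype(bool)


# ---------------------------------------------------------------------------
# scenarios
# ---------------------------------------------------------------------------

@dataclass
class Scenario:
    """A full simulation scenario: region, causal SNP, sample size,
    replicate count, and the filters to sweep."""

    causal: CausalSpec
    n_total: int
    n_replicates: int
    base_seed: int = 0
    profile: RegionProfile | None = None
    panel: HaplotypePanel | None = None
    #: reference-panel depth; default matches a European sequencing reference
    #: of ~283 individuals (566 phased haplotypes)
    n_haplotypes: int = 566
    filters: tuple[str, ...] = METHODS
    threshold_grids: Mapping[str, Sequence] | None = None
    analysis_mode: str = "additive"
    tag_target: int = 77
    tag_indices: Sequence[int] | None = None
    n_perm: int = 2000
    named_thresholds: Mapping[str, Sequence] = field(
        default_factory=lambda: {"rl": [0.01], "lp": [95.0]})
    max_failed_frac: float = 0.05
    #: null-calibration mode: score each replicate against a uniformly drawn
    #: SNP index instead of the fixed causal SNP.  Only meaningful with
    #: per_allele_or = 1, where the data distribution does not depend on the
    #: causal label; makes the evaluated SNP exactly exchangeable with the
    #: rest, so every filter's ROC concentrates on the chance line.
    randomize_causal: bool = False

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.profile is None and self.panel is None:
            raise ValueError("scenario needs a RegionProfile or a panel")
        unknown = set(self.filters) - set(METHODS)
        if unknown:
            raise ValueError(f"unknown filter method(s): {sorted(unknown)}")


@dataclass
class ScenarioReport:
    """End-to-end results of one scenario."""

    scenario: Scenario
    curves: dict[str, RocCurve]
    named_outcomes: dict[str, list[dict]]
    causal_index: int
    n_failed: int
    version: str = _version

    def summary(self) -> dict:
        out = {
            "version": self.version,
            "base_seed": self.scenario.base_seed,
            "n_replicates": self.scenario.n_replicates,
            "n_failed": self.n_failed,
            "causal_index": self.causal_index,
            "config": _scenario_echo(self.scenario),
            "filters": {},
        }
        for m, c in self.curves.items():
            out["filters"][m] = {
                "auc": c.auc,
                "pauc_01": c.pauc_01,
                "thresholds": [t if np.isscalar(t) else list(t) for t in c.thresholds],
                "mean_fpr": c.mean_fpr.tolist(),
                "tpr": c.tpr.tolist(),
                "tpr_var": c.tpr_var.tolist(),
                "fpr_median": c.fpr_median.tolist(),
                "fpr_iqr": np.column_stack([c.fpr_q25, c.fpr_q75]).tolist(),
                "fpr_range": np.column_stack([c.fpr_min, c.fpr_max]).tolist(),
            }
        out["named_outcomes"] = self.named_outcomes
        return out

    def write(self, outdir: str | Path) -> None:
        """One TSV of ROC points per filter plus a JSON summary."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for m, c in self.curves.items():
            with open(outdir / f"roc_{m}.tsv", "w") as fh:
                fh.write("threshold\tmean_fpr\ttpr\ttpr_var\tfpr_median\t"
                         "fpr_q25\tfpr_q75\tfpr_min\tfpr_max\n")
                for i, t in enumerate(c.thresholds):
                    fh.write(f"{t}\t{c.mean_fpr[i]:.6g}\t{c.tpr[i]:.6g}\t"
                             f"{c.tpr_var[i]:.6g}\t{c.fpr_median[i]:.6g}\t"
                             f"{c.fpr_q25[i]:.6g}\t{c.fpr_q75[i]:.6g}\t"
                             f"{c.fpr_min[i]:.6g}\t{c.fpr_max[i]:.6g}\n")
        with open(outdir / "summary.json", "w") as fh:
            json.dump(self.summary(), fh, indent=2)


def _scenario_echo(s: Scenario) -> dict:
    d = {
        "causal": dataclasses.asdict(s.causal),
        "n_total": s.n_total,
        "n_replicates": s.n_replicates,
        "base_seed": s.base_seed,
        "n_haplotypes": s.n_haplotypes,
        "filters": list(s.filters),
        "analysis_mode": s.analysis_mode,
        "tag_target": s.tag_target,
        "n_perm": s.n_perm,
    }
    if s.profile is not None:
        d["profile"] = dataclasses.asdict(s.profile)
    else:
        d["panel"] = "external"
    return d


def run_scenario(scenario: Scenario) -> ScenarioReport:
    """Run a scenario end to end: simulate, scan, profile, filter, average.

    Replicate ``r`` uses seed ``base_seed + r``; the run is fully
    deterministic given the scenario.  Failed replicates are logged and
    skipped; more than ``max_failed_frac`` failures aborts.
    """
    panel = scenario.panel
    if panel is None:
        panel = generate_panel(scenario.profile, scenario.n_haplotypes)

    need_ld = any(m in LD_METHODS for m in scenario.filters)
    need_perm = "pld" in scenario.filters
    tags = scenario.tag_indices
    if tags is None and need_ld:
        tags = default_tag_indices(panel.n_snps, scenario.tag_target)
    n_tags = len(tags) if tags is not None else scenario.tag_target

    grids: dict[str, np.ndarray] = {}
    for m in scenario.filters:
        if scenario.threshold_grids and m in scenario.threshold_grids:
            grids[m] = np.asarray(scenario.threshold_grids[m], dtype=float)
        elif m != "gmd":
            grids[m] = default_threshold_grid(m, n_tags=n_tags)
        # gmd grid is data-driven; fixed from the first replicate below

    fpr_rows: dict[str, list[np.ndarray]] = {m: [] for m in scenario.filters}
    causal_rows: dict[str, list[np.ndarray]] = {m: [] for m in scenario.filters}
    named: dict[str, list[dict]] = {}
    causal_index = -1
    n_failed = 0
    max_failed = int(scenario.max_failed_frac * scenario.n_replicates)

    for r in range(scenario.n_replicates):
        seed = scenario.base_seed + r
        try:
            data = simulate_case_control(panel, scenario.causal,
                                         scenario.n_total, seed)
            table = scan_region(data, scenario.analysis_mode)
            prof = None
            if need_ld:
                prof = build_ld_profile(data, table, tag_indices=tags,
                                        n_perm=scenario.n_perm,
                                        seed=seed + _PERM_SEED_OFFSET,
                                        compute_perm=need_perm)
            causal_index = data.causal_index
            if scenario.randomize_causal:
                causal_index = int(np.random.default_rng(
                    seed + 2 * _PERM_SEED_OFFSET).integers(data.n_snps))
            if "gmd" in scenario.filters and "gmd" not in grids:
                grids["gmd"] = default_threshold_grid(
                    "gmd", cm_values=prof.cm_to_top)
            for m in scenario.filters:
                values = _native_values(m, table, prof)
                fpr, causal = _sweep(m, values, grids[m], causal_index)
                fpr_rows[m].append(fpr)
                causal_rows[m].append(causal)
                for t in scenario.named_thresholds.get(m, ()):  # spot checks
                    out = apply_filter(values, FilterSpec(m, t), causal_index,
                                       perm_p=prof.perm_p if (prof is not None
                                                              and m == "pld") else None)
                    named.setdefault(f"{m}@{t}", []).append({
                        "replicate": r, "fpr": out.fpr,
                        "n_retained": out.n_retained,
                        "causal_retained": out.causal_retained,
                    })
        except Exception:
            n_failed += 1
            logger.exception("replicate %d (seed %d) failed", r, seed)
            if n_failed > max_failed:
                raise RuntimeError(
                    f"{n_failed} of {r + 1} replicates failed "
                    f"(limit {max_failed}); aborting scenario")

    curves = {
        m: _curve_from_arrays(grids[m],
                              np.column_stack(fpr_rows[m]),
                              np.column_stack(causal_rows[m]))
        for m in scenario.filters
    }
    return ScenarioReport(scenario=scenario, curves=curves,
                          named_outcomes=named, causal_index=causal_index,
                          n_failed=n_failed)


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

def _check_keys(d: Mapping, allowed: set[str], where: str) -> None:
    unknown = set(d) - allowed
    if unknown:
        raise ValueError(f"unknown key(s) in {where}: {sorted(unknown)}")


def scenario_from_config(cfg: Mapping) -> Scenario:
    """Build a Scenario from a plain configuration mapping (YAML/JSON).

    Keys mirror the Scenario fields (``profile`` and ``causal`` are nested
    mappings); unknown keys are rejected.
    """
    allowed = {"profile", "causal", "n_total", "n_replicates", "base_seed",
               "n_haplotypes", "filters", "threshold_grids", "analysis_mode",
               "tag_target", "tag_indices", "n_perm", "named_thresholds",
               "max_failed_frac", "randomize_causal"}
    _check_keys(cfg, allowed, "scenario config")
    if "causal" not in cfg or "n_total" not in cfg or "n_replicates" not in cfg:
        raise ValueError("scenario config requires causal, n_total, n_replicates")

    causal_cfg = dict(cfg["causal"])
    _check_keys(causal_cfg, {f.name for f in dataclasses.fields(CausalSpec)},
                "causal spec")
    causal = CausalSpec(**causal_cfg)

    profile = None
    if "profile" in cfg:
        pcfg = dict(cfg["profile"])
        _check_keys(pcfg, {f.name for f in dataclasses.fields(RegionProfile)},
                    "region profile")
        if "maf_spectrum" in pcfg and isinstance(pcfg["maf_spectrum"], Mapping):
            scfg = dict(pcfg["maf_spectrum"])
            _check_keys(scfg, {f.name for f in dataclasses.fields(MafSpectrum)},
                        "maf spectrum")
            pcfg["maf_spectrum"] = MafSpectrum(**scfg)
        profile = RegionProfile(**pcfg)

    kwargs = {k: cfg[k] for k in allowed & set(cfg)
              if k not in ("profile", "causal")}
    if "filters" in kwargs:
        kwargs["filters"] = tuple(kwargs["filters"])
    return Scenario(causal=causal, profile=profile, **kwargs)


def plot_roc(curves: Mapping[str, RocCurve], ax=None, fpr_max: float = 1.0):
    """Basic ROC plot of one curve per filter (requires matplotlib)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for m, c in curves.items():
        order = np.argsort(c.mean_fpr)
        ax.plot(c.mean_fpr[order], c.tpr[order], marker=".",
                label=f"{m} (AUC {c.auc:.0f}%)")
    ax.plot([0, 1], [0, 1], ls=":", c="grey", lw=0.8)
    ax.set_xlim(0, fpr_max)
    ax.set_ylim(0, 1.02)
    ax.set_xlabel("mean FPR")
    ax.set_ylabel("TPR")
    ax.legend(fontsize=8)
    return ax
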