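"""The seven SNP filters and per-replicate outcome scoring.

Methods (``FilterSpec.method``):

``pvalue``   retain SNPs with association p <= threshold (Cochran-Armitage on
             integer doses, Wald on fractional doses).
``rl``       relative likelihood: RL_i = L_i / max_j L_j = exp(l_i - max l);
             retain RL >= threshold (classically 1/100).
``lp``       likelihood percentile: retain the top-(100 - q)% of SNPs ranked
             by maximized likelihood; the retained count is fixed by q.
``gmd``      genetic map distance: retain SNPs within a cM radius of the top hit.
``r2``/``dprime``  retain SNPs whose LD with the top hit is >= threshold.
``pld``      two-step Zhu filter: retain SNPs with preferential-LD score <=
             a PLD bound and permutation p <= a companion cutoff.

Per replicate, a filter yields a retained mask; the false positive rate is
the fraction of the p-1 noncausal SNPs retained and the causal-retained flag
feeds the true positive rate across replicates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .assoc import AssocTable
from .ld import LdProfile

__all__ = [
    "METHODS",
    "FilterSpec",
    "ReplicateOutcome",
    "relative_likelihoods",
    "lp_retained_count",
    "filter_scores",
    "apply_filter",
]

METHODS = ("pvalue", "rl", "lp", "gmd", "r2", "dprime", "pld")


@dataclass(frozen=True)
class FilterSpec:
    """A filter method with its method-scaled threshold.

    ``threshold`` domains: p-value cutoff in (0, 1]; RL ratio in (0, 1];
    LP percentile in (0, 100); cM radius >= 0; LD lower bound in [0, 1];
    for ``pld`` either a PLD upper bound in [0, 1] or a tuple
    ``(pld_max, perm_p_max)``.
    """

    method: str
    threshold: float | tuple[float, float]

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"unknown filter method {self.method!r}")
        t = self.threshold
        if self.method == "pld":
            t1, t2 = t if isinstance(t, tuple) else (t, 1.0)
            if not (0.0 <= t1 <= 1.0 and 0.0 <= t2 <= 1.0):
                raise ValueError("pld thresholds must lie in [0, 1]")
        elif self.method in ("pvalue", "rl"):
            if not (0.0 < t <= 1.0):
                raise ValueError(f"{self.method} threshold must lie in (0, 1]")
        elif self.method == "lp":
            if not (0.0 < t < 100.0):
                raise ValueError("lp percentile must lie in (0, 100)")
        elif self.method == "gmd":
            if t < 0:
                raise ValueError("gmd radius must be >= 0")
        else:  # r2 / dprime
            if not (0.0 <= t <= 1.0):
                raise ValueError(f"{self.method} threshold must lie in [0, 1]")


@dataclass
class ReplicateOutcome:
    """Result of applying one filter at one threshold to one replicate."""

    retained: np.ndarray
    n_retained: int
    causal_retained: bool
    fpr: float


def relative_likelihoods(logliks: np.ndarray) -> np.ndarray:
    """RL_i = exp(l_i - max_j l_j); the top hit has RL exactly 1."""
    ll = np.asarray(logliks, dtype=float)
    finite = np.isfinite(ll)
    if not finite.any():
        raise ValueError("all log-likelihoods are degenerate sentinels")
    return np.exp(ll - ll[finite].max())


def lp_retained_count(p: int, percentile: float) -> int:
    """Number of SNPs retained by the LP filter at a given percentile.

    ``round(p * (100 - percentile) / 100)`` with half-integers rounded to
    even, floored at one SNP.  E.g. percentile 95 retains the top 5%.
    """
    if p < 1:
        raise ValueError("p must be >= 1")
    if not (0.0 < percentile < 100.0):
        raise ValueError("percentile must lie in (0, 100)")
    k = round(p * (100.0 - percentile) / 100.0)
    return max(1, k)


def filter_scores(table: AssocTable, profile: LdProfile | None,
                  method: str) -> np.ndarray:
    """Oriented score vector for a method: higher = stronger causal candidate.

    pvalue -> -log p (CA on integer doses, Wald otherwise); rl and lp -> the
    maximized log-likelihood; gmd -> -cM distance; r2/dprime -> the LD value;
    pld -> -(PLD + perm_p / (2 T)) so permutation p breaks ties within a PLD
    level without crossing levels (PLD is a multiple of 1/T, T = #tags).
    Degenerate SNPs score -inf under every method.
    """
    if method not in METHODS:
        raise ValueError(f"unknown filter method {method!r}")
    degen = table.degenerate
    if method == "pvalue":
        p = np.where(np.isnan(table.ca_p), table.wald_p, table.ca_p)
        score = -np.log(np.clip(p, 1e-300, None))
    elif method in ("rl", "lp"):
        score = table.loglik.astype(float).copy()
    else:
        if profile is None:
            raise ValueError(f"method {method!r} needs an LdProfile")
        if method == "gmd":
            score = -profile.cm_to_top
        elif method == "r2":
            score = profile.r2_to_top.copy()
        elif method == "dprime":
            score = profile.dprime_to_top.copy()
        else:  # pld
            T = max(1, profile.n_tags)
            score = -(profile.pld + profile.perm_p / (2.0 * T))
    return np.where(degen, -np.inf, score)


def apply_filter(values: np.ndarray, spec: FilterSpec, causal_index: int,
                 perm_p: np.ndarray | None = None) -> ReplicateOutcome:
    """Apply one filter at its native threshold.

    ``values`` is the method's native statistic vector: p-values for
    ``pvalue``; RL values for ``rl``; oriented scores (log-likelihoods) for
    ``lp``; cM distances for ``gmd``; LD values for ``r2``/``dprime``; PLD
    scores (with ``perm_p`` for the second Zhu step) for ``pld``.  LP
    boundary ties break to the lower SNP index so its retained count is
    exact.
    """
    values = np.asarray(values, dtype=float)
    p = len(values)
    if not (0 <= causal_index < p):
        raise ValueError("causal_index out of range")
    m = spec.method
    if m == "pvalue":
        retained = values <= spec.threshold
    elif m == "rl":
        retained = values >= spec.threshold
    elif m == "lp":
        k = lp_retained_count(p, spec.threshold)
        order = np.argsort(-values, kind="stable")  # ties -> lower index first
        # degenerate (-inf) SNPs are filtered out first and never fill the
        # fixed retained count
        order = order[np.isfinite(values[order])]
        retained = np.zeros(p, dtype=bool)
        retained[order[:k]] = True
    elif m == "gmd":
        retained = values <= spec.threshold
    elif m in ("r2", "dprime"):
        retained = values >= spec.threshold
    else:  # pld
        t = spec.threshold
        t1, t2 = t if isinstance(t, tuple) else (t, 1.0)
        retained = values <= t1
        if perm_p is not None:
            retained &= np.asarray(perm_p) <= t2
    n_ret = int(retained.sum())
    causal_ret = bool(retained[causal_index])
    fpr = (n_ret - causal_ret) / (p - 1) if p > 1 else 0.0
    return ReplicateOutcome(retained=retained, n_retained=n_ret,
                            causal_retained=causal_ret, fpr=float(fpr))
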