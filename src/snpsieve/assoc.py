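"""Per-SNP association scan: univariate logistic fits and trend tests.

For each SNP ``i`` the disease model is

    logit P(y_j = 1 | x_ij) = beta0_i + beta1_i * x_ij

with ``beta1_i`` the per-allele log odds ratio.  The scan records, per SNP,
the maximum-likelihood estimates, the maximized log-likelihood ``l_i``
(likelihood ratios downstream become log-likelihood differences), the Wald
p-value and the Cochran-Armitage trend p-value.  The "top hit" SNP_max is the
SNP with the largest maximized likelihood.

Fits use a vectorised two-parameter Newton iteration across all SNPs at once
(start (0,0); stop when the log-likelihood change is < 1e-10 or the gradient
norm < 1e-8; at most 50 iterations).  Monomorphic SNPs get the intercept-only
log-likelihood and p = 1 so every statistic ranks them last; separated or
non-converged fits are flagged degenerate with |beta1| capped at 15.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.special import expit

from .simulate import CaseControlData, encode_mode

__all__ = [
    "AssocResult",
    "AssocTable",
    "fit_snp_logistic",
    "ca_trend_test",
    "scan_region",
    "null_loglik",
]

BETA1_CAP = 15.0
MAX_ITER = 50
LL_TOL = 1e-10
GRAD_TOL = 1e-8


@dataclass(frozen=True)
class AssocResult:
    """Single-SNP logistic fit summary."""

    beta0_hat: float
    beta1_hat: float
    loglik: float
    wald_p: float
    ca_p: float
    converged: bool
    degenerate: bool


@dataclass
class AssocTable:
    """Region scan results aligned to ``snp_ids`` (column-oriented arrays)."""

    snp_ids: list[str]
    beta0: np.ndarray
    beta1: np.ndarray
    loglik: np.ndarray
    wald_p: np.ndarray
    ca_p: np.ndarray
    converged: np.ndarray
    degenerate: np.ndarray
    top_hit_index: int

    def __len__(self) -> int:
        return len(self.snp_ids)

    def __getitem__(self, i: int) -> AssocResult:
        return AssocResult(
            beta0_hat=float(self.beta0[i]), beta1_hat=float(self.beta1[i]),
            loglik=float(self.loglik[i]), wald_p=float(self.wald_p[i]),
            ca_p=float(self.ca_p[i]), converged=bool(self.converged[i]),
            degenerate=bool(self.degenerate[i]))

    @property
    def results(self) -> list[AssocResult]:
        return [self[i] for i in range(len(self))]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({
            "snp_id": self.snp_ids, "beta0": self.beta0, "beta1": self.beta1,
            "loglik": self.loglik, "wald_p": self.wald_p, "ca_p": self.ca_p,
            "converged": self.converged, "degenerate": self.degenerate,
        })


def null_loglik(y: np.ndarray) -> float:
    """Intercept-only binomial log-likelihood."""
    y = np.asarray(y, dtype=float)
    ybar = y.mean()
    if ybar in (0.0, 1.0):
        return 0.0
    n = len(y)
    return n * (ybar * np.log(ybar) + (1 - ybar) * np.log(1 - ybar))


def _newton_logistic_many(X: np.ndarray, y: np.ndarray):
    """Vectorised Newton fits of one logistic model per column of X.

    Returns (beta0, beta1, loglik, se1, converged) arrays of length p.
    Columns with zero variance must be excluded by the caller.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    b0 = np.zeros(p)
    b1 = np.zeros(p)
    ll_old = np.full(p, -np.inf)
    converged = np.zeros(p, dtype=bool)
    yc = y[:, None]

    for _ in range(MAX_ITER):
        eta = X * b1 + b0
        mu = expit(eta)
        resid = yc - mu
        g0 = resid.sum(axis=0)
        g1 = (X * resid).sum(axis=0)
        w = mu * (1.0 - mu)
        i00 = w.sum(axis=0)
        i01 = (w * X).sum(axis=0)
        i11 = (w * X * X).sum(axis=0)
        det = np.maximum(i00 * i11 - i01 * i01, 1e-300)
        d0 = (i11 * g0 - i01 * g1) / det
        d1 = (i00 * g1 - i01 * g0) / det
        ll = (y @ eta) - np.logaddexp(0.0, eta).sum(axis=0)
        newly = (np.abs(ll - ll_old) < LL_TOL) | \
                (np.maximum(np.abs(g0), np.abs(g1)) < GRAD_TOL)
        converged |= newly
        ll_old = ll
        active = ~converged
        if not active.any():
            break
        b0[active] += d0[active]
        b1[active] += d1[active]
        np.clip(b1, -BETA1_CAP, BETA1_CAP, out=b1)
        np.clip(b0, -2 * BETA1_CAP, 2 * BETA1_CAP, out=b0)

    eta = X * b1 + b0
    mu = expit(eta)
    ll = (y @ eta) - np.logaddexp(0.0, eta).sum(axis=0)
    w = mu * (1.0 - mu)
    i00 = w.sum(axis=0)
    i01 = (w * X).sum(axis=0)
    i11 = (w * X * X).sum(axis=0)
    det = np.maximum(i00 * i11 - i01 * i01, 1e-300)
    se1 = np.sqrt(i00 / det)
    return b0, b1, ll, se1, converged


def _fit_columns(X: np.ndarray, y: np.ndarray):
    """Fit every column, handling monomorphic columns and separation."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if n < 4:
        raise ValueError("need at least 4 observations")
    if y.min() == y.max():
        raise ValueError("both phenotype classes must be present")

    ll0 = null_loglik(y)
    mono = X.min(axis=0) == X.max(axis=0)
    beta0 = np.full(p, np.log(y.mean() / (1 - y.mean())))
    beta1 = np.zeros(p)
    loglik = np.full(p, ll0)
    wald_p = np.ones(p)
    converged = np.zeros(p, dtype=bool)
    degenerate = mono.copy()

    poly = ~mono
    if poly.any():
        b0, b1, ll, se1, conv = _newton_logistic_many(X[:, poly], y)
        z = np.where(se1 > 0, np.abs(b1) / np.where(se1 > 0, se1, 1.0), np.inf)
        wp = 2.0 * stats.norm.sf(z)
        capped = np.abs(b1) >= BETA1_CAP - 1e-9
        beta0[poly], beta1[poly], loglik[poly] = b0, b1, ll
        wald_p[poly] = wp
        converged[poly] = conv & ~capped
        degenerate[poly] = capped | ~conv
    return beta0, beta1, loglik, wald_p, converged, degenerate


def fit_snp_logistic(x: np.ndarray, y: np.ndarray) -> AssocResult:
    """Maximum-likelihood logistic fit for a single SNP.

    ``x`` holds encoded doses, ``y`` the 0/1 phenotype.  A monomorphic
    predictor yields a degenerate result carrying the null log-likelihood
    and p = 1.  (The Cochran-Armitage p-value is not computed here; see
    :func:`ca_trend_test` and :func:`scan_region`.)
    """
    x = np.asarray(x, dtype=float)
    b0, b1, ll, wp, conv, degen = _fit_columns(x[:, None], y)
    return AssocResult(beta0_hat=float(b0[0]), beta1_hat=float(b1[0]),
                       loglik=float(ll[0]), wald_p=float(wp[0]), ca_p=np.nan,
                       converged=bool(conv[0]), degenerate=bool(degen[0]))


def _ca_trend_many(G: np.ndarray, y: np.ndarray):
    """Vectorised Cochran-Armitage trend chi-square per column with scores
    equal to the integer doses; returns (statistic, p)."""
    G = np.asarray(G, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    r = y.sum()
    sg = G.sum(axis=0)
    sgy = y @ G
    sg2 = (G * G).sum(axis=0)
    num = n * (n * sgy - r * sg) ** 2
    den = r * (n - r) * (n * sg2 - sg * sg)
    stat = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    p = np.where(den > 0, stats.chi2.sf(stat, df=1), 1.0)
    return stat, p


def ca_trend_test(g: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Cochran-Armitage trend test with scores (0, 1, 2), 1 df.

    ``g`` must hold integer doses; fractional (imputed) doses are rejected —
    use the Wald p-value from the logistic fit instead.  A zero-variance
    dose vector gives statistic 0 and p = 1.
    """
    g = np.asarray(g, dtype=float)
    y = np.asarray(y, dtype=float)
    if y.min() == y.max():
        raise ValueError("both phenotype classes must be present")
    if not np.all(g == np.round(g)):
        raise ValueError("fractional doses: use the Wald p-value (wald_p) instead")
    stat, p = _ca_trend_many(g[:, None], y)
    return float(stat[0]), float(p[0])


def scan_region(data: CaseControlData, mode: str = "additive") -> AssocTable:
    """Fit one univariate logistic model per SNP and locate the top hit.

    ``mode`` selects the genotype encoding used in all fits (the analysis
    model, independent of the generative mode).  The Cochran-Armitage trend
    p-value is computed on the encoded doses when they are integral,
    otherwise left as NaN (fractional doses — Wald only).  The top hit is the
    non-degenerate SNP with maximal log-likelihood; ties break to the lowest
    index.
    """
    X = encode_mode(data.doses, mode)
    y = data.phenotype
    beta0, beta1, loglik, wald_p, converged, degenerate = _fit_columns(X, y)

    ca_p = np.full(len(beta0), np.nan)
    if np.all(X == np.round(X)):
        _, ca = _ca_trend_many(X, y)
        ca_p = np.where(degenerate, 1.0, ca)

    if degenerate.all():
        raise ValueError("all SNPs degenerate; no top hit")
    masked = np.where(degenerate, -np.inf, loglik)
    top = int(np.argmax(masked))

    ids = data.snp_ids or [f"snp{i:05d}" for i in range(data.n_snps)]
    return AssocTable(snp_ids=list(ids), beta0=beta0, beta1=beta1,
                      loglik=loglik, wald_p=wald_p, ca_p=ca_p,
                      converged=converged, degenerate=degenerate,
                      top_hit_index=top)
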