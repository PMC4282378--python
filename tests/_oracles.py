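"""Independent brute-force oracles used only by the test suite."""

from __future__ import annotations

import numpy as np


def logistic_loglik(x: np.ndarray, y: np.ndarray, b0: float, b1: float) -> float:
    """Direct binomial log-likelihood of the single-SNP logistic model."""
    eta = b0 + b1 * np.asarray(x, dtype=float)
    return float(np.asarray(y, float) @ eta - np.logaddexp(0.0, eta).sum())


def grid_search_logistic(x: np.ndarray, y: np.ndarray,
                         lo: float = -5.0, hi: float = 5.0) -> tuple[float, float]:
    """Logistic MLE by exhaustive grid search, coarse then refined to 1e-3.

    Deliberately knows nothing about Newton iteration; its only ingredient
    is the log-likelihood formula evaluated on a lattice.
    """
    def best_on(b0s: np.ndarray, b1s: np.ndarray) -> tuple[float, float]:
        B0, B1 = np.meshgrid(b0s, b1s, indexing="ij")
        eta = x[:, None] * B1.ravel()[None, :] + B0.ravel()[None, :]
        ll = y @ eta - np.logaddexp(0.0, eta).sum(axis=0)
        k = int(np.argmax(ll))
        return float(B0.ravel()[k]), float(B1.ravel()[k])

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    b0, b1 = best_on(np.arange(lo, hi + 0.05, 0.1), np.arange(lo, hi + 0.05, 0.1))
    for step, radius in ((0.01, 0.15), (0.001, 0.015), (0.00002, 0.0015)):
        b0, b1 = best_on(np.arange(b0 - radius, b0 + radius + step / 2, step),
                         np.arange(b1 - radius, b1 + radius + step / 2, step))
    return b0, b1


def ca_trend_from_table(case_counts, control_counts) -> float:
    """Cochran-Armitage trend chi-square from a 2x3 genotype table with
    scores (0, 1, 2), via the score-test form U^2 / Var(U)."""
    r = np.asarray(case_counts, dtype=float)
    c = np.asarray(control_counts, dtype=float)
    n = r + c
    N = n.sum()
    R = r.sum()
    s = np.arange(len(r), dtype=float)
    U = (s * r).sum() - R / N * (s * n).sum()
    var = R * (N - R) / N * ((s * s * n).sum() - (s * n).sum() ** 2 / N) / N
    return float(U * U / var) if var > 0 else 0.0


def ca_trend_permutation_p(g: np.ndarray, y: np.ndarray, n_draws: int,
                           seed: int) -> float:
    """Permutation p-value of the trend statistic by label shuffling.

    With fixed margins the statistic is a monotone function of
    ``(sum g*y - E)^2``, so each draw reduces to one dot product.
    """
    rng = np.random.default_rng(seed)
    g = np.asarray(g, dtype=float)
    y = np.asarray(y, dtype=float)
    n, r = len(y), y.sum()
    e = r * g.sum() / n
    obs = (g @ y - e) ** 2
    perms = rng.permuted(np.tile(y, (n_draws, 1)), axis=1)
    stat = (perms @ g - e) ** 2
    return float(((stat >= obs - 1e-12).sum() + 1) / (n_draws + 1))


def quantile_sort_index(a: np.ndarray, q: float) -> float:
    """Linear-interpolation quantile computed by explicit sort and index."""
    v = np.sort(np.asarray(a, dtype=float))
    h = (len(v) - 1) * q
    lo = int(np.floor(h))
    hi = min(lo + 1, len(v) - 1)
    return float(v[lo] + (h - lo) * (v[hi] - v[lo]))
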