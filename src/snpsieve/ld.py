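"""Linkage disequilibrium relative to the top hit.

Given a region scan, every SNP is profiled against SNP_max by pairwise LD
(D, D', r^2), genetic map distance in cM, and the Zhu preferential-LD (PLD)
score with its permutation p-value.  PLD_i is the proportion of tagSNPs whose
r^2 with SNP_i exceeds that between SNP_max and SNP_i; the companion
empirical p-value asks how often two random variants with the same marginal
frequencies would show an r^2 with SNP_max at least as large as SNP_i's.

LD is computed from the phased haplotypes underlying the simulated genotypes
when available (as when datasets are simulated from a panel); for dose-only
input (e.g. externally imputed data) a composite genotype-correlation
fallback is used, which agrees with the haplotype values under
Hardy-Weinberg sampling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .assoc import AssocTable
from .simulate import CaseControlData

__all__ = [
    "LdProfile",
    "pairwise_ld",
    "map_distance",
    "pld_score",
    "ld_perm_pvalue",
    "build_ld_profile",
    "default_tag_indices",
]


@dataclass
class LdProfile:
    """Per-SNP LD/distance statistics relative to the top hit.

    Monomorphic SNPs carry rank-last sentinels: r2 = 0, D' = 0, cm = +inf,
    pld = 1, perm_p = 1.  At the top hit itself r2 = D' = 1, cm = 0, pld = 0.
    """

    r2_to_top: np.ndarray
    dprime_to_top: np.ndarray
    cm_to_top: np.ndarray
    pld: np.ndarray
    perm_p: np.ndarray
    tag_indices: np.ndarray
    top_hit_index: int

    @property
    def n_tags(self) -> int:
        return len(self.tag_indices)


def pairwise_ld(hapA: np.ndarray, hapB: np.ndarray) -> tuple[float, float, float]:
    """(D, D', r^2) between two binary haplotype vectors.

    With ``pAB`` the (1,1)-haplotype frequency and ``pA``, ``pB`` the
    allele-1 frequencies: ``D = pAB - pA pB``;
    ``r2 = D^2 / (pA (1-pA) pB (1-pB))``; ``D' = |D| / Dmax`` where
    ``Dmax = min(pA (1-pB), (1-pA) pB)`` for D > 0 and
    ``min(pA pB, (1-pA)(1-pB))`` for D < 0; D = 0 gives D' = 0.
    """
    a = np.asarray(hapA, dtype=float)
    b = np.asarray(hapB, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ValueError("haplotype vectors must be equal-length 1-D with n >= 2")
    pA = a.mean()
    pB = b.mean()
    if pA in (0.0, 1.0) or pB in (0.0, 1.0):
        raise ValueError("monomorphic locus: LD undefined")
    pAB = (a * b).mean()
    D = pAB - pA * pB
    r2 = D * D / (pA * (1 - pA) * pB * (1 - pB))
    if D > 0:
        dmax = min(pA * (1 - pB), (1 - pA) * pB)
    elif D < 0:
        dmax = min(pA * pB, (1 - pA) * (1 - pB))
    else:
        return 0.0, 0.0, 0.0
    return float(D), float(abs(D) / dmax), float(r2)


def map_distance(map_cM: np.ndarray, i: int, j: int) -> float:
    """Genetic map distance |map_cM[i] - map_cM[j]| in centimorgans."""
    return float(abs(map_cM[i] - map_cM[j]))


def pld_score(r2_tags_to_i: np.ndarray, r2_top_to_i: float) -> float:
    """Proportion of tagSNPs whose r^2 with SNP_i strictly exceeds the top
    hit's r^2 with SNP_i."""
    r2_tags = np.asarray(r2_tags_to_i, dtype=float)
    if r2_tags.size == 0:
        raise ValueError("need at least one tagSNP")
    return float((r2_tags > r2_top_to_i).mean())


def ld_perm_pvalue(x_i: np.ndarray, x_top: np.ndarray, n_perm: int,
                   seed: int) -> float:
    """Empirical p-value for the r^2 between SNP_i and the top hit.

    The squared Pearson correlation of the dose vectors is compared against
    the same statistic after independently permuting ``x_i`` (preserving both
    marginal frequency spectra);
    ``p = (1 + #{perm stat >= observed}) / (n_perm + 1)``.
    A constant vector returns the p = 1 sentinel.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    xi = np.asarray(x_i, dtype=float)
    xt = np.asarray(x_top, dtype=float)
    if xi.std() == 0 or xt.std() == 0:
        return 1.0
    rng = np.random.default_rng(seed)
    xt_c = xt - xt.mean()
    xi_c = xi - xi.mean()
    denom = math.sqrt((xi_c @ xi_c) * (xt_c @ xt_c))
    obs = (xi_c @ xt_c) / denom
    obs2 = obs * obs
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(xi_c)
        r = (perm @ xt_c) / denom
        if r * r >= obs2 - 1e-15:
            hits += 1
    return (1 + hits) / (n_perm + 1)


def default_tag_indices(n_snps: int, target: int = 77) -> np.ndarray:
    """Evenly spaced tagSNP indices, about ``target`` of them.

    Stands in for the intersection with a genotyping-array tagSNP panel
    (roughly 77 array SNPs per 1 Mb region) on synthetic panels, where no
    real array manifest applies.
    """
    step = max(1, math.ceil(n_snps / target))
    return np.arange(0, n_snps, step)


def _hap_ld_to_column(hap: np.ndarray, col: np.ndarray):
    """Vectorised (r2, D') of every haplotype column against ``col``.
    Monomorphic columns get the rank-last sentinel 0."""
    H = hap.shape[0]
    pA = hap.mean(axis=0)
    pB = col.mean()
    if pB <= 0.0 or pB >= 1.0:
        z = np.zeros(hap.shape[1])
        return z, z.copy()
    pAB = (col @ hap) / H
    D = pAB - pA * pB
    poly = (pA > 0) & (pA < 1)
    denom = pA * (1 - pA) * pB * (1 - pB)
    r2 = np.where(poly, D * D / np.where(poly, denom, 1.0), 0.0)
    dmax = np.where(D > 0,
                    np.minimum(pA * (1 - pB), (1 - pA) * pB),
                    np.minimum(pA * pB, (1 - pA) * (1 - pB)))
    dprime = np.where(poly & (D != 0), np.abs(D) / np.where(dmax > 0, dmax, 1.0), 0.0)
    return np.clip(r2, 0.0, 1.0), np.clip(dprime, 0.0, 1.0)


def _dose_ld_to_column(doses: np.ndarray, col: np.ndarray):
    """Composite (Burrows-style) genotype fallback: D estimated as half the
    dose covariance, allele frequencies as half the dose means."""
    n = doses.shape[0]
    pA = doses.mean(axis=0) / 2.0
    pB = col.mean() / 2.0
    if pB <= 0.0 or pB >= 1.0:
        z = np.zeros(doses.shape[1])
        return z, z.copy()
    D = ((col @ doses) / n - doses.mean(axis=0) * col.mean()) / 2.0
    poly = (pA > 0) & (pA < 1)
    denom = pA * (1 - pA) * pB * (1 - pB)
    r2 = np.where(poly, D * D / np.where(poly, denom, 1.0), 0.0)
    dmax = np.where(D > 0,
                    np.minimum(pA * (1 - pB), (1 - pA) * pB),
                    np.minimum(pA * pB, (1 - pA) * (1 - pB)))
    dprime = np.where(poly & (D != 0), np.abs(D) / np.where(dmax > 0, dmax, 1.0), 0.0)
    return np.clip(r2, 0.0, 1.0), np.clip(dprime, 0.0, 1.0)


def _perm_pvalues_shared(doses: np.ndarray, top: int, n_perm: int,
                         rng: np.random.Generator) -> np.ndarray:
    """Permutation p-values of every SNP's r^2 with the top hit using one
    shared permutation set.

    Permuting SNP_i's doses by pi changes the cross-product with the top-hit
    column exactly as permuting the top-hit column by pi^-1 does, and
    correlation means/scales are permutation-invariant; so applying the
    shared permutations to the (centred) top-hit column scores all SNPs in a
    single matrix product.  Each SNP's p-value is marginally exact; p-values
    share permutation draws across SNPs.
    """
    X = doses - doses.mean(axis=0)
    sd = X.std(axis=0)
    t = X[:, top]
    t_norm = t / np.linalg.norm(t)
    ok = sd > 0
    denom = np.where(ok, np.linalg.norm(X, axis=0), 1.0)
    obs_r = (t_norm @ X) / denom
    obs2 = obs_r * obs_r

    perms = np.empty((len(t), n_perm))
    for k in range(n_perm):
        perms[:, k] = rng.permutation(t_norm)
    R = (X.T @ perms) / denom[:, None]          # p x n_perm correlations
    hits = (R * R >= obs2[:, None] - 1e-15).sum(axis=1)
    p = (1 + hits) / (n_perm + 1)
    return np.where(ok, p, 1.0)


def build_ld_profile(data: CaseControlData, table: AssocTable,
                     tag_indices: np.ndarray | None = None,
                     n_perm: int = 2000, seed: int = 0,
                     compute_perm: bool = True) -> LdProfile:
    """Assemble the per-SNP LD/distance profile against the top hit.

    Uses the dataset's phased haplotypes when present, else the composite
    genotype fallback.  ``compute_perm=False`` skips the (costly)
    permutation p-values, leaving the p = 1 sentinel; only the two-step
    Zhu filter consumes them.
    """
    top = table.top_hit_index
    if table.degenerate[top]:
        raise ValueError("top hit is degenerate; LD profile undefined")
    p = data.n_snps
    if tag_indices is None:
        tag_indices = default_tag_indices(p)
    tag_indices = np.asarray(tag_indices, dtype=np.int64)
    # tags monomorphic in this dataset carry no LD information
    tag_poly = data.doses[:, tag_indices].min(axis=0) != \
        data.doses[:, tag_indices].max(axis=0)
    if not tag_poly.any():
        raise ValueError("no polymorphic tagSNPs in dataset")
    tag_indices = tag_indices[tag_poly]

    if data.haplotypes is not None:
        hap = data.haplotypes.astype(float)
        r2, dprime = _hap_ld_to_column(hap, hap[:, top])
        tag_r2 = np.stack([_hap_ld_to_column(hap, hap[:, t])[0] for t in tag_indices])
    else:
        doses = data.doses.astype(float)
        r2, dprime = _dose_ld_to_column(doses, doses[:, top])
        tag_r2 = np.stack([_dose_ld_to_column(doses, doses[:, t])[0] for t in tag_indices])

    mono = data.doses.min(axis=0) == data.doses.max(axis=0)

    if data.map_cM is not None:
        cm = np.abs(data.map_cM - data.map_cM[top])
    else:
        cm = np.zeros(p)
    pld = (tag_r2 > r2[None, :]).mean(axis=0)

    if compute_perm:
        rng = np.random.default_rng(seed)
        perm_p = _perm_pvalues_shared(data.doses.astype(float), top, n_perm, rng)
    else:
        perm_p = np.ones(p)

    # sentinels and the top hit's own entries
    r2 = np.where(mono, 0.0, r2)
    dprime = np.where(mono, 0.0, dprime)
    cm = np.where(mono, np.inf, cm)
    pld = np.where(mono, 1.0, pld)
    perm_p = np.where(mono, 1.0, perm_p)
    r2[top] = 1.0
    dprime[top] = 1.0
    cm[top] = 0.0
    pld[top] = 0.0

    return LdProfile(r2_to_top=r2, dprime_to_top=dprime, cm_to_top=cm,
                     pld=pld, perm_p=perm_p, tag_indices=tag_indices,
                     top_hit_index=top)
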