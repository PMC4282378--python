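# Methods

`snpsieve` compares statistics for *filtering* SNPs in a fine-mapped
disease-association region that is assumed to contain exactly one causal
variant. A filter keeps a subset of the region's SNPs; a good filter keeps
the causal SNP (high true positive rate, TPR) while discarding as many
noncausal SNPs as possible (low false positive rate, FPR). Because any such
comparison on real data is confounded by not knowing the truth, the package
evaluates filters on simulated case-control data in which the causal SNP is
known, and summarises each filter by a threshold-averaged ROC curve over
many simulation replicates.

## Disease model and association scan

For SNP *i* with genotype dose x<sub>ij</sub> ∈ [0, 2] in subject *j*, the
per-SNP disease model is univariate logistic regression,

    logit P(y_j = 1 | x_ij) = β0_i + β1_i x_ij ,

with β1<sub>i</sub> the per-allele log odds ratio. Each SNP is fitted
separately (marginal effects only). The scan records the MLEs, the
maximized log-likelihood ℓ<sub>i</sub>, the Wald p-value, and the
Cochran–Armitage trend p-value; the SNP with the largest ℓ<sub>i</sub> is
the *top hit* (SNP<sub>max</sub>). Likelihoods are carried as
log-likelihoods throughout, so likelihood ratios become differences —
numerically exact and overflow-free.

Fitting uses a two-parameter Newton iteration, vectorised across SNPs,
started at (0, 0) and stopped when the log-likelihood change is < 1e-10 or
the gradient norm < 1e-8 (at most 50 iterations). Monomorphic SNPs are
assigned the intercept-only log-likelihood and p = 1 so that every filter
ranks them last; fits hitting the |β1| ≤ 15 cap (separation) or failing to
converge are flagged degenerate. The Cochran–Armitage statistic is computed
from sufficient sums (algebraically the 2×3-table score test with scores
0, 1, 2) and is only defined for integer doses; fractional (imputed) doses
fall back to the Wald p-value.

## The seven filters

* **p-value** — retain SNPs with trend/Wald p ≤ t. The two p-values are
  near-identical in rank (Spearman > 0.999 in our scans), so they are
  treated as one method: trend p on integer doses, Wald p on fractional.
* **RL** (relative likelihood) — RL<sub>i</sub> = exp(ℓ<sub>i</sub> − max
  ℓ); retain RL ≥ t (classically t = 1/100). The retained count varies
  across datasets.
* **LP** (likelihood percentile) — retain the top (100 − q)% of SNPs ranked
  by ℓ<sub>i</sub>; the retained count round(p(100 − q)/100) (half to even,
  floor one) is fixed by design. Boundary ties break to the lower SNP index
  so the count is exact; degenerate SNPs never fill the quota.
* **GMD** — retain SNPs within a genetic-map radius (cM) of the top hit.
* **r², D′** — retain SNPs whose pairwise LD with the top hit is ≥ t,
  computed from phased haplotypes when the data were simulated (a composite
  genotype-correlation estimate is the documented fallback for dose-only
  input; the two agree within 0.05 under Hardy–Weinberg sampling).
* **PLD** (preferential LD, two-step) — PLD<sub>i</sub> is the share of
  tagSNPs whose r² with SNP<sub>i</sub> strictly exceeds r²(SNP<sub>max</sub>,
  SNP<sub>i</sub>); a companion permutation p-value asks how often two
  random variants with the same marginal frequencies would reach the
  observed r² with the top hit (add-one estimator (1+k)/(n_perm+1), 2000
  permutations by default). Retention requires PLD ≤ t₁ and permutation
  p ≤ t₂. For a one-dimensional ROC sweep the two steps are combined
  lexicographically: score = PLD + perm_p/(2T) with T the tag count, so the
  permutation p breaks ties within a PLD level without ever crossing levels.
  On synthetic panels the tag set defaults to every ⌈p/77⌉-th SNP,
  emulating a genotyping-array intersection of ≈77 tags per 1 Mb.

Inside `build_ld_profile` the permutation p-values for all SNPs of one
replicate share a single permutation set, applied through the identity
"permuting x_i by π changes the cross-product exactly as permuting the
top-hit column by π⁻¹" — one p × n_perm matrix product instead of per-SNP
loops. Each SNP's p-value is marginally exact; p-values within a replicate
share permutation draws (they are already dependent through the common top
hit). The standalone `ld_perm_pvalue` permutes x_i directly.

## ROC evaluation

Per replicate and threshold a filter yields an FPR (fraction of the p − 1
noncausal SNPs retained) and a causal-retained flag. Curves are combined by
*threshold averaging*: at each threshold the x-coordinate is the mean FPR
over replicates and the y-coordinate the TPR (share of replicates retaining
the causal SNP), with the FPR median/IQR/range and the binomial TPR variance
TPR(1 − TPR)/n attached. AUC is the trapezoidal area with the endpoints
(0, 0) and (1, 1) appended, reported as a percentage; the partial AUC
restricts to mean FPR ≤ 0.1 with linear interpolation at the boundary
(maximum 10). Default sweep grids: p-value log-spaced 1e-12..1; RL
log-spaced 1..1e-6; LP percentiles 99..1; r²/D′ 1..0 step 0.01; GMD
quantiles of the first replicate's distance-to-top-hit distribution; PLD
the lexicographic levels above.

## Synthetic reference panels

The generator replaces resampling from an external phased reference. A
region (default 1 Mb) is split into blocks with exponential lengths (mean
`mean_block_kb`: 130 / 22 / 8 kb emulate high / mixed / low LD regions).
Within a block, `n_founders` ancestral haplotypes (default 8) with
Dirichlet(4) population weights carry each SNP's allele on a founder subset
chosen by greedy subset-sum to match a target frequency drawn from the MAF
spectrum; every output haplotype copies one founder per block, founder
choice independent across blocks, with a small per-site copy-error rate
(default 0.002). Within-block LD is therefore high and block boundaries
break it — the single controlled variable of the design. The genetic map
accumulates a 1 cM/Mb background plus a 0.05 cM hotspot at each block
boundary, co-locating hotspots with block edges as in real data.

Two aspects matter for realism of the *rare* end of the spectrum:

* target frequencies below the founder-weight granularity are realized as
  young mutations — one founder background thinned down to the target — so
  the realized spectrum is continuous down to the floor (default 0.01)
  rather than quantised at multiples of 1/n_founders;
* the default MAF spectrum, 0.01 + 0.49·Beta(0.4, 1.5), puts roughly 40%
  of sites below MAF 0.05, like a sequenced panel, and the default scenario
  panel depth is 566 haplotypes (a European sequencing reference of ~283
  individuals).

These two defaults are what make the D′ filter genuinely poor in
simulation, as it is on real panels: with few carriers, sample D′ between
unrelated loci is strongly inflated (zero haplotype cells arise by chance),
so rare noncausal SNPs crowd the top of any D′ ranking while the common
causal SNP does not — a property of the statistic, not of the association
signal. A deeper panel or a common-only spectrum hides this phenomenon.

What the generator does **not** emulate: long-range (cross-block) ancestral
haplotype sharing, mutation/recombination novelty when resampling,
population structure, genotyping error, and sex chromosomes. Passing tests
therefore demonstrate the filters' behaviour under block-structured LD with
a realistic frequency spectrum, not under every feature of real data.

## Case-control simulation

Individuals draw two panel haplotypes uniformly with replacement. Disease
status uses retrospective rejection sampling under the rare-disease
approximation: controls are population draws; a candidate becomes a case
with probability OR^e / max OR^e, where e is the mode-encoded causal
genotype (additive e = dose; dominant/recessive indicators with fractional
thresholds 0.5/1.5). The sampled case/control genotype odds are then exactly
OR^e, so the logistic scan estimates the specified per-allele logOR without
assuming a baseline prevalence. Case and control counts are always exactly
equal; replicate r uses seed base_seed + r.

## Numerical and design choices

* LP retained counts validated against the fixed-count examples
  (5 of 100 at the 95th percentile; 2469 of 2871 at the 14th).
* D′ convention: D′ = |D|/D_max with D_max = min(p_A(1−p_B), (1−p_A)p_B)
  for D > 0 and min(p_A p_B, (1−p_A)(1−p_B)) for D < 0; D = 0 gives D′ = 0.
* Degenerate SNPs always rank last (−∞ score) under every filter.
* Null calibration uses `randomize_causal`: with OR = 1 the data
  distribution is independent of the causal label, so scoring each
  replicate against a uniformly drawn SNP index makes the evaluated SNP
  exactly exchangeable and every filter's ROC concentrates on the chance
  line. With a *fixed* common causal SNP, distance- and D′-based filters
  are not null-calibrated (the causal differs from the noncausal pool in
  MAF and position) — that deviation is structural, not a bug.
* Scaled problem sizes: the package's comparison scenario uses ~300 SNPs,
  n_total 2000, 200 replicates and 200 permutations for the PLD step, with
  the causal at MAF 0.2 and per-allele OR 1.24 — the largest OR of the
  plausible-effect range, chosen so the Wald noncentrality (z ≈ 2.7)
  matches the weak-signal regime in which the filter families genuinely
  separate. At z ≳ 5 (e.g. OR 1.5 at this MAF and n) every filter is
  near-perfect and the comparison degenerates.
* Replicate failures are logged and skipped; more than 5% aborts the
  scenario. Reports serialise as one ROC-point TSV per filter plus a JSON
  summary echoing the configuration and seeds.

## Known limitations

Single causal variant only; no imputation (externally imputed dose matrices
are accepted); no functional priors or multi-SNP models; LD filters assume
the top hit is non-degenerate; permutation p-values within a replicate
share permutation draws (see above); the founder-mosaic model understates
long-range D′ sharing relative to real chromosomes.
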