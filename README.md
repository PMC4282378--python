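# snpsieve

Filtering statistics for retaining a single causal SNP in a fine-mapped
disease-association region.

After a genome-wide association study flags a region, fine-mapping has to
narrow thousands of densely genotyped SNPs down to a short list of
candidate causal variants cheap enough to follow up in the lab. Because
SNPs in a small region are highly correlated, the variant with the best
association statistic is often *not* the causal one, and different
"keep the plausible ones" rules behave very differently. `snpsieve` is a
simulation laboratory for comparing seven such filters under a known truth:

| filter | keeps SNPs with … |
|---|---|
| `pvalue` | trend/Wald association p ≤ t |
| `rl`     | relative likelihood RL_i = L_i / max_j L_j ≥ t (classically 1/100) |
| `lp`     | likelihood rank in the top (100 − q)% — fixed retained count |
| `gmd`    | genetic map distance to the top hit ≤ t cM |
| `r2`, `dprime` | pairwise LD with the top hit ≥ t |
| `pld`    | preferential-LD score ≤ t₁ and permutation p ≤ t₂ (two-step) |

Each SNP *i* is scanned with univariate logistic regression
`logit P(y=1|x) = β0_i + β1_i x_i` (β1 the per-allele log odds ratio); the
SNP with the largest maximized likelihood is the *top hit*. Filters are
evaluated over many simulated case-control replicates by
threshold-averaged ROC curves: mean FPR (share of noncausal SNPs kept)
against TPR (probability the causal SNP survives), summarised by AUC and
the partial AUC at FPR ≤ 0.1. A built-in founder-mosaic generator emulates
regions with high/mixed/low LD-block structure and a sequencing-like MAF
spectrum; real phased panels (IMPUTE hap/legend or phased VCF, plus a
recombination map) and externally imputed genotype-dose matrices are also
accepted. See `docs/methods.md` for the model details and design choices.

## Worked example

```python
import snpsieve as sv

profile = sv.RegionProfile(n_snps=200, mean_block_kb=22.0, seed=7)   # mixed LD
scenario = sv.Scenario(
    causal=sv.CausalSpec(target_maf=0.2, per_allele_or=1.24),
    n_total=2000, n_replicates=100, base_seed=1,
    profile=profile, filters=("lp", "pvalue", "rl", "r2", "dprime"),
)
report = sv.run_scenario(scenario)
for method, curve in sorted(report.curves.items(), key=lambda kv: -kv[1].auc):
    print(f"{method:>7}: AUC {curve.auc:5.1f}%   pAUC(FPR<=0.1) {curve.pauc_01:4.2f}%")
lp = report.curves["lp"]
tpr95 = lp.tpr[lp.thresholds.index(95.0)]
print(f"LP at the 95th percentile retains the causal SNP in {tpr95:.0%} of replicates")
```

prints

```
 pvalue: AUC  94.1%   pAUC(FPR<=0.1) 7.22%
     lp: AUC  93.8%   pAUC(FPR<=0.1) 7.24%
     rl: AUC  90.7%   pAUC(FPR<=0.1) 6.93%
     r2: AUC  73.0%   pAUC(FPR<=0.1) 4.76%
 dprime: AUC  68.5%   pAUC(FPR<=0.1) 1.67%
LP at the 95th percentile retains the causal SNP in 75% of replicates
```

Reading: likelihood/p-value ranking dominates LD- and distance-based
filtering by ~20 AUC points in this weak-signal regime; the fixed-count LP
filter matches the p-value method while guaranteeing how many SNPs survive,
and D′ is the weakest statistic (its partial AUC collapses because sparse
rare-SNP haplotype tables inflate D′ spuriously). At the common 95th-
percentile threshold (keep the top 5% of 200 SNPs), the causal variant
survives in three quarters of the replicates.

The same pipeline is scriptable from the shell:

```
snpsieve scenario --config scenario.yaml --seed 1 --out report/
snpsieve panel / simulate / scan / filter --help
```

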