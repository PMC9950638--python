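# bidimr

Bidirectional two-sample Mendelian randomization (MR) from GWAS summary
statistics, built for studies that screen a panel of circulating biomarkers
(e.g. 41 inflammatory cytokines) against a binary disease outcome such as
proliferative diabetic retinopathy, in both causal directions, against two
independent outcome GWAS sources.

It is aimed at genetic epidemiologists who have per-SNP association tables
(identifier, alleles, allele frequency, β, SE, p, N) for each trait and a
local LD reference, and who want a reproducible, scriptable pipeline rather
than a chain of web services.

## What it computes

Instruments for an exposure are SNPs passing a significance tier
(P < 5×10⁻⁸, relaxing to 5×10⁻⁶ when fewer than 3 independent SNPs survive),
greedily LD-clumped at r² < 0.001 within 10 Mb. Instruments missing from the
outcome GWAS are replaced by proxies at r² > 0.80; alleles are harmonized
(strand correction, sign flips, unconditional deletion of palindromic A/T
and C/G SNPs); instruments associated with common confounders at the
Bonferroni level 0.05/k are removed; strength is summarized by the mean
F-statistic (F̄ > 10 expected); and MR-Steiger filtering removes SNPs that
explain more variance in the outcome than in the exposure.

With harmonized effects (γ̂ⱼ, Γ̂ⱼ) and Wald ratios rⱼ = Γ̂ⱼ/γ̂ⱼ:

* **IVW**: β̂ = Σwⱼrⱼ / Σwⱼ with wⱼ = γ̂ⱼ²/se(Γ̂ⱼ)², i.e. the zero-intercept
  weighted regression of Γ̂ on γ̂; multiplicative random effects scale the SE
  by max(1, √(Q/(k−1))) and are chosen automatically when Cochran's Q has
  p < 0.05.
* **MR-Egger**: the same regression with a free intercept; a non-zero
  intercept estimates average directional pleiotropy.
* **Weighted median**: consistent when invalid instruments carry less than
  half the weight; SE by seeded parametric bootstrap.
* **MR-PRESSO**: resampling-based global heterogeneity (RSS) test, per-SNP
  outlier detection with Bonferroni correction, outlier-corrected IVW and a
  distortion test.

Per-source estimates are pooled by fixed-effect or DerSimonian–Laird
random-effects meta-analysis (chosen by the Q test), reported as odds ratios
per 1-SD exposure change, and classified as **strong** evidence below the
Bonferroni level (0.05/41 ≈ 0.0012 for a 41-trait panel) or **suggestive**
between that level and 0.05. The reverse direction treats the disease GWAS
of each source as the exposure and each biomarker as the outcome.

A seeded synthetic-data generator (`bidimr.simulate`) produces two-sample
summary statistics with known ground truth — causal effect, pleiotropy
regime, LD blocks, significance tiers, reverse causation — so every stage of
the pipeline is testable without any external downloads.

## Worked example

```python
from bidimr import (scenario, simulate_pair, select_instruments, clump,
                    harmonize, ivw, meta_combine, or_with_ci,
                    percent_increase_from_or)

truth = scenario("causal", seed=42)            # true effect theta = 0.1, 50 SNPs
pair = simulate_pair(truth, extra_sources={"b": (398, 2848)})

per_source = []
for name, outcome in pair.outcome_sources.items():
    snps = clump(select_instruments(pair.exposure, 5e-8), pair.ld)
    est = ivw(harmonize(snps, outcome), model="auto")
    per_source.append(est)
    print(f"source {name}: IVW beta = {est.beta:.4f} (SE {est.se:.4f}), "
          f"p = {est.pval:.2e}, {est.n_snp} SNPs, I2 = {est.I2:.2f}")

meta = meta_combine(per_source, model="auto")
or_, lo, hi = or_with_ci(meta.pooled_beta, meta.pooled_se)
print(f"pooled ({meta.model}): OR = {or_:.3f} [{lo:.3f}, {hi:.3f}], "
      f"p = {meta.pval:.2e} -> {percent_increase_from_or(or_):.1f}% risk per SD")
```

prints

```
source a: IVW beta = 0.1051 (SE 0.0100), p = 1.16e-25, 50 SNPs, I2 = 0.22
source b: IVW beta = 0.0746 (SE 0.0241), p = 1.96e-03, 50 SNPs, I2 = 0.04
pooled (fixed): OR = 1.106 [1.086, 1.126], p = 1.84e-27 -> 10.6% risk per SD
```

The per-source log-odds estimates bracket the generating effect θ = 0.1 (the
large source tightly, the 398-case source loosely); no heterogeneity is
detected between them, so the fixed-effect pooled odds ratio of 1.106 per
1-SD exposure increase — a 10.6 % higher risk — recovers the truth within
sampling error.

The MR methods are also available as scikit-learn style estimators
(`IVWEstimator`, `EggerEstimator`, `WeightedMedianEstimator`,
`MRPressoEstimator`) with `fit`, `get_params` and fitted attributes such as
`beta_`, `ci_` and `intercept_pval_`.

The same analysis runs from the shell:

```bash
bidimr simulate --scenario causal --seed 42 --out data/
bidimr run --config run.yaml        # writes results_*.tsv, meta.tsv, summary.md
```

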