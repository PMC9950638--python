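# Methods

## Model and assumptions

The package estimates the causal effect θ of an exposure X on an outcome Y
from two independent GWAS using genetic instruments. For SNP j, γⱼ denotes
the true per-allele effect on X and Γⱼ the effect on Y; a valid instrument
satisfies Γⱼ = θγⱼ. Horizontal pleiotropy adds a direct term αⱼ, giving
Γⱼ = θγⱼ + αⱼ. The estimators make progressively weaker assumptions:

* IVW assumes αⱼ = 0 for all j.
* MR-Egger allows a common directional αⱼ provided instrument strength is
  independent of the direct effects (InSiDE); the intercept estimates the
  average pleiotropy. Because the regression is not invariant to the
  arbitrary sign of γ̂ⱼ, records are oriented so γ̂ⱼ ≥ 0 before fitting.
* The weighted median is consistent while instruments carrying at least half
  the weight are valid.
* MR-PRESSO assumes pleiotropy is concentrated in a minority of outlier SNPs
  and detects them from leave-one-out residuals.

All effects are treated on the scale the input GWAS reports: SD units of an
inverse-normalized biomarker for quantitative traits, log-odds for binary
traits, so a forward estimate is log-OR per 1-SD exposure and a reverse
estimate is SD per unit log-odds.

## Estimator details and numerical choices

* IVW is computed as the zero-intercept weighted least-squares slope of Γ̂ on
  γ̂ with weights 1/se(Γ̂)², algebraically identical to the inverse-variance
  weighted mean of Wald ratios with weights γ̂²/se(Γ̂)². The sum form avoids
  dividing by γ̂ⱼ, so zero exposure effects cannot produce infinities.
* Multiplicative random effects scale the fixed SE by max(1, √(Q/(k−1))): no
  under-dispersion credit. The `auto` model uses random effects iff the
  Cochran Q p-value < 0.05, and degenerates to the Wald ratio at k = 1.
* Wald ratio SE uses the first-order delta approximation se(Γ̂)/|γ̂| (the
  common two-sample convention); the second-order term is available behind a
  flag.
* Egger SEs use the same multiplicative over-dispersion floor on the
  residual variance (RSS/(k−2) floored at 1). Two-sided p-values throughout
  are normal, the summary-data MR convention; Egger can use a t reference
  with k−2 df via `use_t=True`.
* The weighted median interpolates the cumulative weight midpoints
  pⱼ = (Σᵢ≤ⱼ wᵢ) − wⱼ/2 of the sorted ratios at 0.5. Its SE comes from a
  parametric bootstrap (default 1,000 draws) that redraws both effect sides
  from normals with their SEs; the seed is mandatory in the pipeline so
  stochastic SEs are reproducible.
* MR-PRESSO simulates the null RSS distribution by redrawing effects around
  each SNP's leave-one-out fitted value (default 1,000 simulations). All
  resampling p-values use the add-one estimator (1+#)/(n+1) so they are
  never zero. Outlier p-values are Bonferroni-corrected by k and reported
  only when the global test is significant; the distortion test compares the
  observed corrected-vs-raw shift against shifts from removing random
  subsets of the same size. The leave-one-out slopes and simulated residual
  matrices are fully vectorised, so the test costs O(n_sim × k).
* DerSimonian–Laird is the random-effects flavour for the two-source
  meta-analysis — the ubiquitous default for a handful of summary estimates;
  REML would be overkill at k = 2, where I² is reported but flagged
  unstable. 95% CIs use the conventional 1.96 multiplier everywhere.
* Clumping ties on p-value break to the lexicographically smaller SNP id,
  which makes the output invariant to input order. SNPs absent from the LD
  panel are treated as unlinked with a logged warning rather than an error,
  because summary-level reference panels are always incomplete.
* The mean F-statistic defaults to the per-SNP squared z-score form
  (β/SE)², which needs no allele frequencies; the R²-based form
  F = (n−k−1)/k · R²/(1−R²) is available behind a flag. With strong
  instruments the two differ by O(1/n).
* Steiger variance explained is approximated from summary data as
  r² = F/(F+n−2); for the binary trait this is applied on the log-odds scale
  with the effective sample size (an documented approximation — exact
  liability-scale r² would need prevalence). The removal rule is strict
  (r²_out > r²_exp), so ties are kept; the z-test on Fisher-transformed
  correlations is reported alongside.
* Palindromic SNPs are deleted unconditionally by default. The optional
  frequency rescue (`keep_if_eaf_informative`) keeps a palindromic SNP only
  when both allele frequencies are outside [0.42, 0.58] and uses their
  concordance to resolve the strand; anything ambiguous is dropped.
* Proxy substitution runs before palindromic filtering of the proxy itself:
  a palindromic proxy is rejected with a logged reason. Proxy effects are
  re-expressed for the missing SNP's alleles through the panel's phase sign,
  assuming panel alleles are given on the same strand convention as the
  summary files (complement-matching is accepted).

## Pipeline design choices

* Tier fallback: fewer than 3 post-clumping instruments at 5×10⁻⁸ triggers
  re-selection at 5×10⁻⁶, per trait; `tier_mode` can force either tier to
  reproduce primary-only or relaxed-only designs.
* The confounder screen divides α by the pre-filter instrument count and is
  applied in both directions by default (`apply_confounder_reverse=False`
  restores an asymmetric design).
* The Bonferroni denominator for evidence classification defaults to the
  number of exposures in the batch (0.05/41 ≈ 0.0012 for a 41-trait panel);
  both cut points are strict-less comparisons.
* Per-pair failures become flagged `not_estimable`/`error` rows, never
  batch-level exceptions. With a single outcome source the meta-analysis is
  skipped and classification falls back to that source's IVW p-value.
* Every stochastic component receives a deterministic seed derived from the
  run seed and the trait-pair label (CRC32 mixing), so result tables are
  byte-identical across re-runs and independent of batch composition.

## Synthetic-data generator

The generator emulates the data structure of a two-sample cytokine→disease
study: a quantitative exposure GWAS of n = 8,293, a large binary outcome
source (2,025 cases / 284,826 controls) and optionally a small one
(398 / 2,848). Per SNP, γⱼ ~ N(gamma_dist) (default mean 0.25, sd 0.05 —
squared z-scores around 200, matching the instrument strength a genome-wide
significant cytokine SNP shows at this sample size), αⱼ is zero with
probability 1−ρ and N(μ_α, σ_α) otherwise, and observed effects are drawn
from normals with se = 1/√(2·maf(1−maf)·n), using the effective sample size
4/(1/n_case + 1/n_control) for binary traits. Null filler SNPs (default 150)
make significance thresholding non-trivial; LD blocks are declared at the
summary level (partner SNPs with √r²-attenuated true effects and independent
noise, a stated approximation sufficient for clumping/proxy logic — no
haplotypes are simulated); a configurable fraction of outcome records has
swapped alleles with negated betas to exercise harmonization; exposure and
outcome samples never overlap.

Scenario presets fix the regimes the sensitivity machinery targets:

| scenario | key settings | purpose |
|---|---|---|
| null | θ=0, k=30 | type-I error calibration |
| causal | θ=0.1, k=50 | bias / coverage |
| balanced_pleiotropy | ρ=0.3, μ_α=0 | heterogeneity without bias |
| directional_pleiotropy | ρ=0.3, μ_α=0.12, k=150, γ~N(0.35,0.18) truncated at 0.05, InSiDE | Egger intercept power, median robustness |
| outliers | 2 SNPs with |α| = 10σ_α | PRESSO outlier detection |
| reverse_causation | θ=0, reverse θ=0.5 | Steiger filtering signal |
| weak_instruments | γ~N(0.055,0.01), mean F ≈ 5–15 | F̄ > 10 warning path |

The directional-pleiotropy preset uses more and more-dispersed instruments
than the others because the Egger intercept test has notoriously low power:
detecting a ρμ_α ≈ 0.036 average pleiotropy at 80 % power needs the
intercept SE that only a wide, positively-signed γ spread at k ≈ 150
provides. γ is kept positive there because sign-orientation would otherwise
convert directional pleiotropy into balanced pleiotropy. In the
reverse-causation preset the exposure association is purely transmitted from
the outcome (γ = 0.5·δ), so the true variance-explained ratio is
reverse_θ² = 0.25 and Steiger removal has unambiguous signal.

What the generator does not emulate — and hence what passing tests do not
establish about real data: realistic allele-frequency spectra and LD decay,
population stratification, sample overlap, winner's-curse selection of
instruments from the same GWAS used for estimation, mis-specified effect
distributions, and liability-scale subtleties of binary traits. Calibration
and recovery results certify the statistical machinery, not any substantive
biological claim.

## Problem sizes

Monte Carlo checks use 500 replicates for IVW calibration and recovery,
300 for the pleiotropy robustness hierarchy, 200 (with 1,000 resampling
draws each) for PRESSO null calibration, and 50 seeds for outlier/Steiger
detection rates — sizes at which the binomial noise of every rate is well
inside its acceptance band. The consistency check runs the generator at
n = 10⁶ to confirm the IVW estimate converges to θ.

## Known limitations

* No mode-based, multivariable, or contamination-mixture estimators.
* LD is summary-declared; no genotype or haplotype simulation, no liftover,
  no VCF input, no remote LD services.
* Steiger r² on the log-odds scale is an approximation for binary traits.
* I² from two sources is intrinsically unstable (flagged in output).
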