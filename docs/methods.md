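# Methods

## Model and procedure

`mrdiet` implements two-sample Mendelian randomization (MR) with GWAS
summary statistics. A genetic variant j used as an instrument carries an
exposure association γ_j (SE σγ_j) from one cohort and an outcome
association Γ_j (SE σΓ_j) from an independent cohort. Under the
instrumental-variable assumptions (relevance, independence from
confounders, exclusion restriction), each instrument yields a Wald ratio

    β_j = Γ_j / γ_j,     s_j = σΓ_j / |γ_j|   (first-order delta method),

and the estimators combine these ratios:

* **IVW** — the precision-weighted mean β̂ = Σ w_j β_j / Σ w_j with
  w_j = 1/s_j² = γ_j²/σΓ_j². Algebraically identical to the
  zero-intercept weighted least-squares slope of Γ on γ with weights
  1/σΓ² (asserted numerically to 1e-10 in the tests). Fixed-effect SE is
  (Σ w_j)^(-1/2); the multiplicative random-effects variant (mre-IVW)
  inflates it by max(1, √(Q/(J−1))) and never deflates.
* **MR-Egger** — WLS of Γ on γ *with* an intercept, weights 1/σΓ²,
  after orienting every instrument so γ_j ≥ 0 (negating γ and Γ jointly,
  which leaves every ratio unchanged). The intercept estimates average
  directional pleiotropy; the slope is the pleiotropy-adjusted causal
  effect, consistent under the InSIDE assumption. Coefficient covariance
  uses a residual-variance inflation floor max(1, RSS/(J−2)); p-values
  come from t(J−2).
* **Weighted median** — the interpolated 0.5-quantile of the ratio
  distribution under IVW weights; consistent when instruments carrying
  ≥ 50% of the weight are valid. Its SE is a parametric bootstrap
  (resample γ* ~ N(γ, σγ), Γ* ~ N(Γ, σΓ); default 1000 draws, fixed
  seed), so runs are bit-reproducible.

IVW p-values use the standard normal. These df conventions are not
universal across MR software; they are the dominant ones and are stated
in the output metadata.

## Diagnostics

* **Cochran's Q** = Σ w_j (β_j − β̂_IVW)², compared with χ²(J−1).
* **Egger intercept test** for directional pleiotropy (α = 0.05 default).
* **MR-PRESSO**: observed RSS sums leave-one-out residuals
  (Γ_j − β̂_(−j) γ_j)²/σΓ_j²; the null distribution is simulated
  parametrically (Γ* ~ N(β̂_(−j)γ_j, σΓ_j), γ* ~ N(γ_j, σγ_j), RSS
  recomputed per replicate, default 1000 replicates). The global p uses
  the add-one correction (1 + #{RSS* ≥ RSS_obs})/(n_sim + 1), so it is
  bounded below by 1/(n_sim+1) and never exactly zero. Per-SNP outlier
  p-values compare each instrument's observed contribution with its
  simulated contributions and are Bonferroni-corrected by J. The
  distortion test is out of scope (only the global p and the outlier list
  are reported downstream).
* **Leave-one-out**: fixed-effect IVW re-estimated J times. The
  "no single driver" flag requires sign stability plus mutually
  overlapping CIs. The fixed-effect IVW is used here because it is the
  primary-analysis lineage; heterogeneity sensitivity is already covered
  by Q and mre-IVW.

## Method selection

With pleiotropy defined as intercept p < α and heterogeneity as Q p < α:
pleiotropy alone → MR-Egger; heterogeneity alone → mre-IVW by default
(the weighted median is always reported in the same row and can be made
the main method by configuration); neither → fixed-effect IVW; both →
no main method (indeterminate) with MR-PRESSO outlier removal suggested.
A verdict is *positive* only when the main method's p < α **and** the
other methods' betas share its sign. No multiple-testing correction is
applied across exposures (raw p < 0.05 convention); a Bonferroni column
can be added downstream but is deliberately not part of the default
report.

## Instrument selection

Genome-wide significance is strict (p < 5e-8). Greedy LD clumping visits
variants in ascending p-value order (ties broken lexicographically by
variant id) and discards conflicting variants — same chromosome, within
the window, r² ≥ threshold (default r² 0.001). The literature phrase
"window size > 5,000 kb" is ambiguous about whether it is a lower or
upper bound; the default here is a generous upper bound of 10,000 kb,
fully configurable and recorded in the run manifest. Without an LD
table all pairs are treated as independent (r² = 0) and clumping is a
logged no-op; computing LD from a genotype panel is out of scope.
Instrument strength is the per-SNP F = (γ/σγ)² (the squared t
approximation implied by "SNP-specific F-statistics"); the mean-F > 10
guard is a flag, not a hard filter.

## Harmonization

Join on variant id (catalog files are rsID-keyed); positions are used
only for clumping windows. Allele reconciliation handles swaps (negate
beta, flip EAF), strand complements, and their combination. Palindromic
(A/T, C/G) variants are oriented by EAF concordance and dropped when
either study's EAF is missing or within 0.08 of 0.5 — a conservative
standard practice the source studies do not specify, so it is flagged in
reports and configurable. Missing EAF on non-palindromic variants is
harmless (orientation is resolvable from alleles alone). Multi-allelic
variants, liftover, and imputation-quality filtering are non-goals.

## Synthetic-data generator

`simulate_pair` emulates a pair of GWAS summary tables under the linear
IV model (see the module docstring for the full data-generating
process). What the defaults mean:

| parameter | default | rationale |
|---|---|---|
| gamma_sd | 0.1 | spread of true per-allele effects on the weekly-intake scale |
| se_gamma | 0.005 | exposure-study noise; a biobank-scale quantitative GWAS (n ≈ 3–4 × 10⁵) |
| se_Gamma | 0.05 | outcome-study noise for the flagship scenarios; a well-powered binary outcome |
| J | 50 (41/23 in the flagship presets) | instrument counts matching the two headline exposures |
| seed | mandatory | every draw is reproducible |

True γ_j are |N(0, gamma_sd)| — effects are expressed for the
exposure-increasing allele, which is what makes *directional* pleiotropy
directional after Egger's γ ≥ 0 orientation — and are resampled until
γ/σγ clears the genome-wide z, so emitted instruments pass the p < 5e-8
filter (the guarantee applies to true effects; observed effects clear it
up to one noise SD, so an end-to-end run may shed a few borderline
instruments). A `case_control_se` helper reproduces the
1/√(harmonic-mean) SE scale of a small case-control outcome study
(132 cases / 784 controls give ≈ 0.15 at EAF 0.3) for users who want
that extra realism; the presets use the fixed scales above so that
500-replicate Monte-Carlo summaries are informative at desk scale.

What the generator does **not** emulate: LD between instruments
(independent by construction; the LD path is tested with hand-written r²
tables), sample overlap between the two studies, allele-frequency–
dependent SEs, winner's-curse ascertainment of instruments, and binary-
trait non-collapsibility. Passing tests therefore validate the
estimators and decision logic under the stated model, not the quality of
any particular real GWAS pair.

### Scenario presets

`null` (β = 0, J = 50), `causal_protective` (β = −0.5, J = 41),
`directional_pleiotropy` (β = −0.5, α ~ N(0.05, 0.01), J = 41),
`heterogeneous` (balanced pleiotropy, alpha_sd = 0.1, J = 23),
`single_outlier` (one 10·σΓ shift among 20 null instruments),
`weak_instruments` (mean F ≈ 10, no significance guarantee).

A note on the directional scenario: with homoskedastic outcome SEs the
expected excess in Cochran's Q equals the squared z of the Egger
intercept test (both are (α²/σΓ²)·J·(1 − m₁²/m₂) in the γ moments), so
"intercept fires, Q does not" is intrinsically a borderline regime — the
same pattern as a real exposure with intercept p ≈ 0.003 and Q p ≈ 0.088.
Consequently the Egger branch is selected in roughly 60% of seeded runs,
and the integration tests assert that frequency rather than a
single-seed outcome.

## Numerical choices and degenerate inputs

* p-values are floored at 1e-320 to keep them in (0, 1].
* CI bounds are exp(β ± 1.96·se); log(OR) round-trips β to 1e-12.
* Clumping ties break on variant id; output is in genomic order.
* Zero-γ instruments raise a named per-instrument error (the significance
  filter removes them upstream in any real run).
* One instrument → Wald ratio reported as such; two → IVW without
  diagnostics-based selection; Egger and the weighted median need ≥ 3,
  MR-PRESSO ≥ 4. Below each threshold the corresponding diagnostic is
  absent rather than faked.
* `simulate_effects` accepts zero SEs so the noiseless limit (every
  ratio exactly β_true, zero heterogeneity) can be asserted exactly;
  emitted tables require positive SEs because the record format does.

## Problem sizes used in the validation suite

Monte-Carlo checks run at 2000 replicates for type-I error (binomial 95%
bounds around 0.05), 500 replicates for bias/recovery (Monte-Carlo SE of
the mean ≈ 0.003 on the IVW estimate, ≈ 0.0007 on the Egger intercept),
200 seeded runs for MR-PRESSO detection at n_sim = 500, and 500 random
cases for the clumping-vs-exhaustive-search oracle on ≤ 10 variants.
The whole suite completes in well under a minute.

## Known limitations

* No Steiger directionality filtering, mode-based estimators, MR-RAPS,
  multivariable or bidirectional MR.
* The MR-PRESSO distortion test is not implemented.
* LD must be supplied as precomputed r²; no reference-panel computation.
* Real GWAS catalog inputs are supported via column maps but no
  downloading is performed; the analysis of the published accessions is
  reproducible only with those files on disk.
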