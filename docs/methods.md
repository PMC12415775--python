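# Methods

## Two-sample MR model

Instruments are SNPs assumed to satisfy the core MR conditions: associated
with the exposure, independent of confounders, and affecting the outcome
only through the exposure. With summary effects γ̂ⱼ ± σ_xⱼ (exposure) and
Γ̂ⱼ ± σ_yⱼ (outcome), each SNP's Wald ratio rⱼ = Γ̂ⱼ/γ̂ⱼ estimates the
causal effect β; its first-order SE σ_yⱼ/|γ̂ⱼ| ignores σ_xⱼ, which is
adequate once the F ≥ 10 weak-instrument filter bounds σ_xⱼ/|γ̂ⱼ|. For a
binary outcome all effects are log-odds and estimates are reported as
OR = e^β with 95% CI e^(β ± 1.96·se).

### Estimators

- **IVW**: β̂ = Σwⱼrⱼ/Σwⱼ with wⱼ = 1/SE(rⱼ)². Fixed-effect SE (Σwⱼ)^−1/2;
  the default multiplicative random-effects model multiplies it by
  max(1, √(Q/(J−1))) — inflation only, never deflation. Equivalent to the
  intercept-free weighted least-squares slope of Γ̂ on γ̂ (asserted
  numerically in the tests). p-values from the normal reference.
- **MR-Egger**: instruments re-signed so γ̂ⱼ ≥ 0, then WLS of Γ̂ on γ̂ with
  a free intercept and weights 1/σ_yⱼ². The slope estimates β under InSIDE
  (instrument strength independent of direct effects); the intercept
  estimates mean directional pleiotropy. Both SEs carry the inflation
  factor max(1, √(RSS_w/(J−2))); p-values use t(J−2). A design with no
  variation in γ̂ raises an error rather than returning NaNs.
- **Weighted median**: sort ratios, form cumulative normalized weights
  sⱼ = Σᵢ≤ⱼwᵢ − wⱼ/2, linearly interpolate at 0.5. Consistent while valid
  instruments hold > 50% of the weight. Equal weights reproduce the sample
  median.
- **Modes**: Gaussian-kernel density over the ratios, bandwidth
  φ·0.9·min(sd, iqr/1.349)·J^(−1/5) (modified Silverman, φ = 1), estimate
  at the maximizing grid point (512 points spanning the ratios ± 3
  bandwidths). The weighted variant weights each kernel by normalized
  inverse ratio variance. Identical ratios short-circuit to the common
  value.
- Median/mode SEs come from a parametric bootstrap (default 1000
  replicates, mandatory seed): redraw β̂* ~ N(β̂, se) per SNP, recompute
  ratios, re-apply the point estimator with the *original* weights and
  bandwidth. Holding weights fixed matches common two-sample MR practice
  and keeps the bootstrap measuring sampling noise of the ratios rather
  than of the weights.

The significance rule is IVW-primary: `significant_consistent` requires
IVW p < 0.05 and a shared effect direction across all returned methods;
direction disagreement downgrades to `significant_inconsistent`.

### Sensitivity suite

Cochran's Q = Σwⱼ(rⱼ − β̂_fixed)² against χ²(J−1); Q always uses the
fixed-effect center even when random-effects estimates are reported. The
Egger intercept test shares the regression above (identical numbers, by
construction). Leave-one-out recomputes IVW with each SNP omitted.

**MR-PRESSO.** Observed statistic: RSS = Σⱼ wⱼ(Γ̂ⱼ − β̂₍₋ⱼ₎γ̂ⱼ)² with
β̂₍₋ⱼ₎ the leave-one-out intercept-free WLS slope and wⱼ = 1/σ_yⱼ². The
null distribution comes from n_sim (default 1000) parametric draws
γ̂* ~ N(γ̂, σ_x), Γ̂* ~ N(β̂₍₋ⱼ₎γ̂ⱼ, σ_y), with the leave-one-out fit
re-run per draw. The global p is the exceedance fraction; per-SNP
contributions give outlier p-values, Bonferroni-multiplied by J and
flagged below α = 0.05. The corrected estimate is IVW on the unflagged
subset; the distortion test compares the observed estimate displacement
against displacements from removing random subsets of the same size. All
Monte-Carlo p-values are floored at 1/(n_sim+1). Note the flagging floor:
with J instruments the smallest achievable adjusted p is J/(n_sim+1), so
n_sim must exceed ~20·J for flagging at α = 0.05 to be possible at all
(the default 1000 covers J ≤ 49).

### Harmonization conventions

Outcome rows are aligned to the exposure's effect allele: identical pairs
are kept; swapped pairs negate the outcome beta and complement its
frequency; strand-complement pairs are complemented first. Palindromic
A/T and G/C SNPs carry no orientation information in their alleles, so
after label alignment the remaining strand ambiguity is resolved by
frequency agreement — and the SNP is dropped when either frequency is
missing or falls in [0.42, 0.58] (a conventional ambiguity band). Every
per-SNP decision is recorded in `HarmonizedSet.actions`.

### LD clumping

Greedy by ascending p (ties broken by chromosome, position, SNP id): the
current index claims and removes all unclaimed same-chromosome SNPs at
center-to-center distance strictly less than the window (default
10,000 kb) with r² ≥ the threshold (default 0.01). r² comes from an
explicit pairwise lookup — from a file, or from the block generator —
because computing LD requires a genotype reference panel that summary
statistics do not provide; real-data use must supply panel-derived r².

## Mediation

Two-step MR: β₁ (exposure→mediator, IVW) times β₂ (mediator→outcome,
univariable IVW — no multivariable adjustment for the exposure) gives the
indirect effect; SE by the first-order delta method
√(β₁²se₂² + β₂²se₁²), which omits the se₁²se₂² cross term (a few percent
when both relative errors are large). The proportion mediated divides by
the total effect, with a CI that propagates the indirect-effect CI over
the total treated as fixed — a deliberate simplification that understates
uncertainty when the total effect is itself noisy; `direction_ok` flags
indirect/total sign agreement instead of guessing at negative
proportions. Mediator screening retains candidates whose two steps are
each `significant_consistent` at IVW p < 0.05 and ranks by |proportion|.

## Synthetic data

The generator simulates summary statistics directly — no individual-level
genotypes — because two-sample MR consumes only summary data, and direct
simulation keeps thousand-replicate calibration studies in seconds.

Per SNP: maf ~ U(0.05, 0.5); SE = 1/√(2·maf(1−maf)·n) (the standardized-
trait GWAS approximation); true instrument effect γⱼ = |N(0, 0.05²)|
rejection-sampled to F > 10 at the exposure sample size. Orienting γⱼ
positive is without loss of generality (allele coding is arbitrary) and
makes "directional" pleiotropy well defined in the MR-Egger frame, where
instruments are re-signed to positive exposure effects. Pleiotropy: an
exact count round(prop_invalid·J) of instruments receives
αⱼ ~ N(pleio_mean, pleio_sd²); Γⱼ = β·γⱼ + αⱼ; observed effects are
normal around the truth. An option correlates αⱼ with γⱼ to violate
InSIDE and stress MR-Egger. LD blocks assign r² = ρ² within consecutive
blocks (0 across), with block members 100 kb apart and blocks separated
beyond the default clumping window.

Mediation triplets use independent instrument sets per relation (set A
for the exposure, set B for the mediator; B has no effect on the
exposure, so reverse contamination is absent by construction). The
bidirectional generator likewise gives the downstream trait its own
instruments with no back-path.

The cohort generator draws zero-inflated log-normal relative abundances
per group (defaults: five genera at the group medians a PDD case–control
study of 28 HC / 20 PD-NC / 27 PDD would show, log-SD 1.0, 10%
zero-inflation — medians near 10⁻³–10⁻², sparse and right-skewed). MMSE
is drawn per group (HC 29.18 ± 0.90, PD-NC 28.50 ± 1.15, PDD 19.30 ±
4.10, clipped to 0–30 integers) and then blended with the standardized
abundance of a target taxon so the pooled pre-rounding correlation equals
the target (default −0.316 with *Subdoligranulum*); the achieved
post-rounding correlation is recorded in `cohort.truth`.

What the generators do **not** emulate: realistic allele-frequency
spectra or LD decay, case–control imbalance beyond a configurable n,
winner's-curse in instrument selection, sample overlap between exposure
and outcome GWAS, compositional coupling between taxa, or covariate
structure (age, sex, medication) in the cohort. Passing tests therefore
demonstrate statistical correctness of the estimators and pipeline under
the stated model, not robustness to every artifact of real microbiome
GWAS or metagenomic data.

## Numerical conventions

- p-values of exactly 0 on input are clamped to the smallest positive
  double (≈ 4.9e-324) so −log transforms stay finite; generated p-values
  are floored the same way.
- Monte-Carlo p-values are floored at 1/(n_sim+1).
- CI multiplier fixed at 1.96 throughout.
- Youden-optimal cutoffs break ties toward the lowest cutoff; marker
  direction (risk vs protective) is auto-detected from the AUC side and
  recorded. Constant scores produce a degenerate report with a warning.
- AUC is computed by the Mann–Whitney identity with ties counted half;
  its CI is a stratified bootstrap (2000 resamples, seeded) because n=75
  zero-inflated abundances generate heavy ties that break closed forms.
- The marker-combination logistic model is fitted by IRLS in-module
  (≤ 50 iterations, log-likelihood tolerance 1e-8); collinear designs are
  solved by pseudoinverse (the linear predictor, hence the ROC, stays well
  defined) and complete separation is detected and flagged.
- Kruskal–Wallis on all-identical values returns H = 0, p = 1 rather than
  the undefined tie-corrected statistic.
- All stochastic operations take explicit seeds and are bitwise
  reproducible; pipeline-level seeds are split into per-stage streams via
  `numpy.random.SeedSequence`.

## Problem sizes in the acceptance script

Null calibration uses 2000 replicates at J = 50; recovery studies use 500
replicates at J = 100 and n = 100k; MR-PRESSO rates use 150 replicates at
J = 30 with n_sim = 1000; power simulation uses 500 cohort replicates.
These counts put the Monte-Carlo SE of every reported rate well below the
effect sizes under study while the whole script stays in single-digit
seconds on one CPU.

## Known limitations

- The first-order Wald-ratio SE and the fixed-weights bootstrap slightly
  understate uncertainty for weak-ish instruments; the F ≥ 10 filter is
  what licenses both.
- The proportion-mediated CI ignores total-effect noise (see above).
- No multivariable MR, Steiger filtering, MR-RAPS or radial variants; no
  VCF summary-statistic input; no genome-build liftover; LD must be
  supplied, not computed.
- Real-data palindrome resolution by frequency fails silently when the
  two GWAS populations have genuinely different allele frequencies; the
  0.42 band mitigates but cannot eliminate this.
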