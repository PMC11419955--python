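# Methods

This note documents the statistical procedures, the defaults and why they
were chosen, the synthetic-data model the tests rely on, and the package's
known limitations.

## Two-sample MR model and assumptions

All methods operate on summary statistics: per-variant effect estimates and
standard errors from an exposure GWAS and an outcome GWAS of non-overlapping
samples drawn from the same ancestry. A variant is a valid instrument if it
is (i) associated with the exposure, (ii) independent of
exposure–outcome confounders, and (iii) affects the outcome only through the
exposure. Binary-outcome effects are log odds ratios; causal estimates for a
binary outcome are therefore log-OR per unit of (standardized) exposure.

## Instrument selection

Defaults follow common practice for molecular-trait exposures:

| parameter | default | meaning |
|---|---|---|
| `p_threshold` | 1e-5 | exposure association screen (strict `<`) |
| `window_kb` | 10,000 | clumping window, intra-chromosomal |
| `r2_max` | 0.001 | maximum pairwise LD among retained instruments |
| `maf_min` | 0.01 | minor-allele-frequency floor (strict `>`) |
| `f_min` | 10 | weak-instrument F threshold |

Clumping is greedy: candidates sorted by ascending p (ties broken by variant
id for determinism); the best remaining variant is kept and every remaining
same-chromosome variant within the window with r² above `r2_max` is
discarded. The LD matrix is an explicit input (the generator produces one);
no external reference panel is consulted. The output is invariant to input
row order.

Variance explained by one SNP is 2p(1−p)β² with p the effect-allele
frequency, treating the exposure as variance-standardized; when the
frequency is missing the standard approximation β²/(β² + N·se²) is used and
flagged. The weak-instrument filter is applied per SNP (K = 1 in the F
formula, so F₁ = R²(N−2)/(1−R²)); survivors are pooled and the set-level
R² (sum of per-SNP R², capped below 1) and F are reported. The per-SNP
reading of the F<10 removal reflects the screening being described as
removing individual SNPs.

## Harmonization

Outcome records are aligned to the exposure's effect allele: identical
allele pairs pass through; swapped pairs negate the outcome beta and mirror
its frequency; complementary-strand representations are strand-flipped
first. Palindromic variants (A/T, C/G) cannot be strand-resolved from
alleles; the default policy orients them by allele frequency and drops them
as ambiguous when either study's minor-allele frequency exceeds 0.42 (or a
frequency is missing) — mirroring the behaviour of the widely used R
two-sample-MR tooling — with `drop_all` available as a stricter policy.
Indels and multi-allelic records are rejected at load; every drop is
tallied with a reason, so retained + dropped always equals the ID
intersection.

## Estimators

With weights w_j = 1/se²_Yj:

* **IVW** — β̂ = Σw·β̂_X·β̂_Y / Σw·β̂²_X, the weighted regression through
  the origin. The default multiplicative random-effects model inflates the
  fixed-effect SE by √max(Q/(k−1), 1); it is never deflated below the
  fixed-effect SE. p-values are two-sided normal. A single instrument
  degenerates to the Wald ratio β̂_Y/β̂_X with first-order SE se_Y/|β̂_X|.
* **MR-Egger** — the same regression with a free intercept, each SNP first
  oriented so β̂_X ≥ 0. Fitted by weighted least squares (statsmodels);
  the residual standard deviation is floored at 1 (the same
  at-least-multiplicative-random convention as IVW), and p-values are
  two-sided t on k−2 df. The intercept, its SE, and its t-test constitute
  the directional-pleiotropy diagnostic.
* **Weighted median** — the interpolated weighted median of the per-SNP
  ratios with weights (β̂_X/se_Y)², consistent when ≥50% of weight comes
  from valid instruments. Its SE is a parametric bootstrap: β̂_X and β̂_Y
  are resampled from normals at their observed values/SEs, ratios
  recomputed, and the weighted median re-evaluated with the *observed*
  weights held fixed (matching the reference R implementation); the SE is
  the bootstrap standard deviation. Default 1000 replicates, explicit seed.
* **Simple / weighted mode** — the argmax of a Gaussian-kernel density over
  the ratios (uniform weights, or inverse squared first-order ratio SEs),
  bandwidth φ·0.9·min(sd, iqr/1.349)·k^(−1/5) with φ = 1 by default. The
  density is maximized over a 1024-point grid across the ratio range,
  augmented with the ratio values themselves; bootstrap replicates use a
  256-point grid. All ratios identical (zero bandwidth) returns the common
  ratio with SE 0 and a flag.

A panel run dispatches by instrument count: k = 1 Wald only, k = 2 adds
IVW, k ≥ 3 the full five methods plus Cochran's Q under both the IVW
(df = k−1) and Egger (df = k−2) references and the Egger-intercept test.
Q is computed as the weighted residual sum of squares of the reference fit
(equivalently, on the ratio scale with first-order weights). Odds ratios
and 95% CIs are exp(β̂) and exp(β̂ ± 1.96·SE) throughout.

## Mediation

Two-step MR takes the three IVW estimates — β₁ (exposure→mediator), β₂
(mediator→outcome), β_ALL (exposure→outcome) — and decomposes:
indirect = β₁β₂ with delta-method SE √(β₁²se₂² + β₂²se₁²);
direct = β_ALL − β₁β₂ (so direct + indirect = β_ALL identically, up to one
floating-point rounding); proportion = β₁β₂/β_ALL. The proportion CI
propagates se_indirect/|β_ALL| with the total treated as fixed — the
simplest defensible choice; a full first-order delta method that also
propagates se_ALL is available via `proportion_ci_method="full"`. The
indirect-effect p-value is a two-sided normal test of β₁β₂ = 0. When the
indirect and total effects disagree in sign, the result is flagged
`inconsistent_mediation` and the proportion may leave [0, 1].

β₂ is estimated from the mediator→outcome MR *without* adjusting for the
exposure (simple two-step); exposure-correlated pleiotropy of the
mediator's instruments is therefore a limitation, not something corrected.
The prerequisite that the mediator does not cause the exposure is checked
by reverse MR (mediator instruments against the exposure); failure, or an
untestable reverse direction, flags the result rather than raising.
Mediation in the study runner is attempted only for mediators on which the
selected exposure shows an IVW effect at p < 0.05 — the screen that reduces
candidate mediators to those actually downstream of the exposure.

## Screening and the reverse-MR gate

An exposure is carried forward when (i) IVW p < 0.01 (exposure screen) or
p < 0.001 (mediator screen), (ii) Egger-intercept p > 0.05, and (iii) all
available methods' effects share a direction (a zero effect counts as
inconsistent; a panel too small for the pleiotropy test cannot fail it).
No multiple-testing correction enters selection — the emulated design uses
raw thresholds — but a Benjamini–Hochberg column is emitted for
transparency. Selected exposures must pass reverse MR (outcome instruments
against the exposure, pass when IVW p ≥ 0.05; the threshold is a design
choice, the emulated analysis reports only a non-significant result). When
the outcome yields no genome-wide instruments the gate passes with an
explicit `untestable` flag. Reports are sorted by IVW p then id, and with a
fixed seed every rerun is byte-identical.

## Synthetic data

The generator realizes the diagram X → M → Y with a direct X → Y path.
Per SNP: effect-allele frequency p ~ U(maf range, default 0.05–0.5);
exposure effects from a spike-and-slab (default 10% causal); mediator true
effects θ_XM·β_X plus mediator-specific spike-and-slab effects; outcome
log-odds effects (θ_XM·θ_MY + θ_XY-direct)·β_X + θ_MY·(mediator-specific
effects) + optional per-SNP pleiotropy N(mean, sd²) + optional
outcome-specific effects, which can feed back on the exposure (θ_YX, and
θ_MX for mediator→exposure) for reverse-causation positive controls.
Observed betas add noise with se = 1/√(2p(1−p)·N), using the effective size
N_eff = 4/(1/cases + 1/controls) for the case-control outcome — so
simulated z-scores are exactly standard normal around the truth, which the
tests verify by Kolmogorov–Smirnov. The three trait-specific spike-and-slab
supports are disjoint: each trait's instruments act on the others only
through the modelled causal paths, emulating the near-disjoint architecture
of truly polygenic traits; residual instrument invalidity is injected
explicitly through the pleiotropy parameters instead. LD is a
block-diagonal r² matrix over consecutive SNPs (block members placed 10 kb
apart, blocks far outside any clumping window of each other); LD affects
selection, not the sampling correlation of the simulated estimates — a
deliberate simplification.

Default sample sizes are the emulated study's: exposure cohort 771,
mediator cohort 8,299, outcome 98 cases / 218,694 controls. The bundled
fixture (`study_shaped_fixture`, fixed design seed) sets the true effects
to ln(1.059), ln(4.295), and ln(1.962) − ln(1.059)·ln(4.295) — so the true
odds ratios equal the emulated study's three headline estimates and the
true mediated proportion is 12.40% — over a 320-SNP panel whose
architecture yields 28 exposure→mediator and 18 mediator→outcome
instruments under the default selection pipeline.

What passing tests do and do not show: the generator draws independent
Gaussian summary statistics around exact linear truths; it has no sample
overlap, no population stratification, no winner's-curse correction need,
no allele-frequency mismatch between studies, and LD does not correlate the
estimates. Recovery results on synthetic data therefore validate the
estimators and plumbing, not robustness to those real-data pathologies.

## Numerical choices and test conditions

* Bootstrap and simulation RNG: numpy `default_rng`, explicit integer seeds
  everywhere; identical seeds give byte-identical outputs.
* Floats in TSV reports are written with `%.10g` for cross-run stability.
* Clumping ties broken lexicographically by variant id; screening ordered
  by (IVW p, exposure id).
* Degenerate inputs raise typed errors (`DegenerateInputError`,
  `InsufficientInstrumentsError`, ...) rather than returning NaNs; the
  study runner collects per-exposure errors and continues.
* Test problem sizes were chosen to exercise each property at comfortable
  statistical resolution: estimator calibration at 50 instruments over
  200–1000 replicates; the mediation-recovery grid at 100 candidate SNPs,
  exposure n = 10,000, mediator n = 5,000, and a 50k/50k case-control
  outcome; reverse-MR checks at moderate outcome power (5k/5k) so that
  forward-effect SNPs stay below the genome-wide threshold in the outcome
  scan, as in the emulated design where the outcome GWAS (98 cases) is far
  too underpowered to re-discover exposure instruments.

## Limitations

* No MR-PRESSO, Steiger filtering, or multivariable MR; no Rucker model
  selection. Single mediator per decomposition.
* LD clumping requires a user-supplied r² matrix; the package does not
  compute LD from genotype panels.
* The proportion-mediated CI treats the total effect as fixed by default;
  ratios of noisy estimates can behave badly when the total effect is near
  zero (the decomposition refuses β_ALL = 0 outright).
* Figures are not rendered; the diagnostic surface is the emitted tables
  (funnel, scatter with per-method fit lines, forest/leave-one-out rows).
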