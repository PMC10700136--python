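# Methods

This note documents the models implemented in `organclocks`, their
assumptions, the tunable parameters that matter, and the design decisions
taken where the method leaves genuine freedom. Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Organ-enriched protein mapping

Tissue bulk RNA counts are normalized with median-of-ratios size factors:
for each sample, the size factor is the median over reference genes
(strictly positive in every sample) of count / per-gene geometric mean. A
matrix in which every gene has a zero somewhere has no reference set and
is rejected. Samples are then reduced per tissue (median by default, mean
configurable), and an organ's expression is the **maximum over its
subtissues** — brain is the maximum over brain regions, and the synthetic
*immune* organ is max(blood, spleen). A gene is *organ enriched* when the
top organ is at least `fold_threshold` (default 4, inclusive) times the
second-highest organ, holds the unique maximum, and exceeds a
`min_expression` floor (default 1.0 normalized units) that suppresses
ratio artifacts among noise-level genes. A zero second-highest value gives
an infinite fold change; an exact tie for the maximum gives no call.

Panel QC keeps probes with replicate CV ≤ `max_cv` (default 0.15) and
cross-assay-version correlation ≥ `min_cross_version_r` (default 0.5).
These defaults are repository defaults chosen in the range practitioners
use for aptamer panels, not values taken from any specific assay release;
probes missing QC columns pass with a logged warning.

The catalog is a partition of the QC-passing panel: mutually exclusive
organ sets (genes enriched in an in-scope organ), the *organismal* set
(genes enriched in **no** organ — a gene enriched in an out-of-scope organ
such as skin is organ-specific and therefore excluded from the
organ-nonspecific set), and the *conventional* set (everything passing
QC). The shipped tissue→organ grouping covers the 11 in-scope organs
(adipose, artery, brain, heart, immune, intestine, kidney, liver, lung,
muscle, pancreas) with a representative subtissue vocabulary; it is an
approximation for any particular upstream atlas and fully overridable.

## Bagged LASSO clocks

Features are z-scored log₁₀ protein abundances plus an unstandardized 0/1
sex indicator entering the penalty like any other coefficient.
Standardization parameters are estimated **once on the full training
cohort** and reused at prediction time (per-test-cohort restandardization
is available behind `predict_age(..., restandardize=True)`; the choice
matters when test cohorts have strong global shifts).

Each of the `n_bootstraps` (default 500) instances is fit on a
with-replacement resample of the full training size. Per instance, a
descending log-grid of `n_lambdas` (default 100) penalties spans
λ_max = max|Xᵀ(y−ȳ)|/n down to 10⁻⁴·λ_max; 5-fold CV scores each λ by
held-out R² (negative MSE configurable), and the **largest λ whose mean
CV score is ≥ 95 % of the best** is selected — the retention rule trades a
small amount of accuracy for materially sparser, more interpretable
models. If the best CV score is nonpositive the retention rule is
meaningless and the arg-max λ is taken with a warning. Folds are
re-randomized per instance, with all randomness (bootstrap draws, fold
shuffles) sub-seeded from the master seed via `SeedSequence([seed, b, k])`
counters, so results are independent of evaluation order and bit-identical
across reruns. No out-of-bag logic is used anywhere. Ensemble prediction
is the arithmetic mean over instances.

LASSO solutions come from scikit-learn's coordinate descent at tight
tolerance (1e−10); λ = 0 falls back to least squares. The test suite
cross-checks against an independent hand-written coordinate-descent oracle
and the closed-form soft-threshold solution for a single standardized
predictor.

## Age gaps

Within each cohort, a LOWESS curve (tricube weights, fraction 2/3, 3
robustifying iterations, exact fit `delta = 0`) of predicted on
chronological age estimates the population-mean prediction; the raw gap is
the vertical distance to that curve. Outside the observed age range the
curve is clamped to the boundary fit rather than extrapolated. Cohorts
smaller than `min_cohort_size` (50) use an ordinary least-squares line
with a warning — local regression is unstable there. Note that with a
2/3-span neighborhood the smoother carries curvature bias of order one
year at the extremes of a wide age range when the true prediction trend is
strongly quadratic; the calibration tests quantify this envelope.

Gaps are z-scored per (model, cohort) with the sample (n−1) SD convention,
using all subjects of the cell as the reference by default (healthy-only
reference and pooled-across-cohort standardization are flags). One SD of
organ gap corresponds to roughly four years of organ aging under the
simulator's default offset scale.

## Extreme agers and e-ageotypes

A subject is an extreme ager when any model's |z-gap| **strictly exceeds**
2. For clustering, entries with |z| below the threshold are set to zero —
the reading that preserves the extreme signal (the inverted reading, zero
the extremes, is available behind `truncate_extremes=True` for comparison
but destroys the clustering structure by construction). k-means (Euclidean,
default k = 13, 10 seeded restarts keeping the lowest inertia) clusters
the extreme agers; each cluster is labelled by the model with the largest
mean z within it. After clustering, subjects extreme in ≥ 5 models are
manually overridden to *multi-organ*. Subjects whose only extreme flags
are negative are labelled with the organ of largest |z| plus a "(youth)"
tag — the framework permits pure-youth outliers even if a given dataset
shows none. All 13 gap columns (11 organs + organismal + conventional)
enter the clustering by default.

Under independence of 13 standard-normal gap columns the expected extreme
fraction is 1 − (1 − P(|Z|>2))¹³ ≈ 45.5 %; observed fractions in real
cohorts are far lower because organ gaps are positively correlated.

## FIBA

PFI (chronological permutation importance) is the drop in Pearson r
between ensemble-mean predicted and chronological age when one probe's
column is shuffled, averaged over 5 seeded shuffles.

FIBA scores a probe's contribution to the *biological* signal. Per
bootstrap instance: predictions are computed, gaps calibrated (LOWESS) and
z-scored, and the trait association measured as the sign-oriented trait
coefficient of OLS `z_gap ~ trait + age + sex` (the t-statistic is a
flag); each probe with a nonzero coefficient is then permuted 5 times and
the FIBA score is baseline minus mean permuted association. Probes with a
zero coefficient in an instance are short-circuited to an exact 0 — no
Monte-Carlo noise. A probe is **FIBA+** when it has nonzero coefficients
in ≥ 100/500 instances (rescaled pro rata when the ensemble is smaller,
e.g. 20/100) and < 5 % of its per-instance scores are negative, both
bounds strict in the directions stated. FIBA+ probes feed
`train_cognition_model`, which retrains a clock on that subset from
trait-unimpaired subjects and prefixes the name with "Cognition".

Two methodological choices deserve emphasis; both are flags and both
defaults were chosen because the alternative provably biases the score
positive for *every* variance-carrying probe, destroying the meaning of
the <5 %-negative rule:

* **Baseline z-parameters for permuted gaps** (default). Permutation adds
  independent variance to the gap, so re-estimating the z-scale on each
  permuted vector shrinks the standardized trait coefficient regardless of
  whether the probe carries trait signal. The permuted gap is therefore
  standardized with the instance's baseline mean/SD (an affine transform
  fixed per instance); `restandardize_after_permutation=True` restores the
  re-estimating variant.
* **Per-instance evaluation resamples** (default). Evaluating all 500
  instances on one shared cohort means an inert probe's finite-sample
  trait correlation (ρ ~ N(0, 1/n)) is *identical in every instance*; the
  fraction-negative rule cannot average over it, and any probe whose
  spurious correlation aligns with its coefficient sign is called FIBA+.
  Each instance is therefore evaluated on its own seeded bootstrap
  resample of the evaluation cohort, restoring the sampling variability
  that makes the empirical one-tailed p-value meaningful;
  `resample_per_instance=False` restores shared-cohort evaluation.

Permutation and resampling seeds derive from the master seed per
(instance, probe, replicate) counters, so parallel or reordered evaluation
cannot change results. Inside the permutation loop LOWESS uses a small
interpolation window (`delta = 0.01` of the age range, measured maximum
deviation ~4×10⁻³ years from the exact fit) applied identically to
baseline and permuted gaps; user-facing gap computation remains exact.

## Downstream statistics

Trait models are OLS `z_gap ~ trait + age + sex` with classical standard
errors and listwise deletion; effects on the z scale convert to years by
multiplying with the model's raw-gap SD. Families of tests are adjusted
with Benjamini–Hochberg (each analysis batch is one family; 5 % FDR
default). Cross-cohort pooling uses inverse-variance fixed-effect
meta-analysis. Event risk uses Cox proportional hazards
`event ~ z_gap + age + sex` with Breslow tie handling (the only tie
scheme lifelines implements; the gap enters as a z-score so hazard ratios
are per SD). e-ageotype/disease associations use logistic regression
`trait ~ membership`, unadjusted by default (covariates are the caller's
choice), with perfect separation surfaced as an error.

## Synthetic data

The generator's defaults encode the reference study conditions: 1,398
subjects, ages truncated-normal mean 75 SD 12 on [27, 104] (uniform
option), sex Bernoulli(1/2), 11 organs × 20 probes plus 100 nonspecific
probes, per-subject per-organ biological-age offsets δ ~ N(0, 4² years),
and a shared "organismal" offset for nonspecific probes. A probe's log₁₀
abundance is a_j + b_j·(age + δ_organ) + ε with baseline a_j ~ N(3, 0.3),
sign-mixed slopes |b_j| ~ U(0.008, 0.012) per year, and homoscedastic
noise ε ~ N(0, 0.12²) — 0.12 equals the age-signal SD at the default
slopes (0.01/yr × 12 yr age SD), i.e. noise SD = signal SD. Reference
expression plants enriched genes at an 8× margin (configurable down to the
4× boundary) with lognormal sampling noise across 10 samples per tissue.

Traits are parameterized in SD-of-offset units: linear traits
γ·δ_organ/σ_δ + N(0,1); binary diseases Bernoulli(expit(α + β·δ/σ_δ));
survival times exponential with hazard λ₀·exp(θ·δ/σ_δ) and administrative
censoring at 15 years. *Probe-driven* traits (the planted FIBA targets)
load on the probes' measurement-specific residual — the value minus its
shared age + offset signal — sign-aligned with the assay slope; loading on
raw probe values would make every same-organ probe a genuine trait carrier
through the shared offset and leave driver identification ill-posed.

What the simulator does **not** emulate: real tissue covariance structure,
batch/plate effects, assay-version bridging, heteroscedastic or
heavy-tailed measurement noise, and correlated organ aging (offsets are
independent across organs). Passing tests therefore demonstrate that the
chain recovers planted signal under the stated noise model, not that any
particular real-data effect size will replicate.

## Problem sizes and numerical choices

Simulation-heavy tests and the acceptance script use scaled ensembles
(B = 100 of 500; 25-point λ grids of 100; two organs of eleven) — chosen
so the planted-signal structure is preserved while the whole suite runs in
minutes; the FIBA consideration threshold scales pro rata (20/100). Exact
arithmetic choices: z-scores use ddof = 1; fold-change threshold
comparisons are inclusive (≥); the FIBA negative-fraction bound and the
extreme-ager threshold are strict (<, >); k-means empty clusters are
handled by scikit-learn's re-initialization; degenerate covariates
(constant age or sex in a FIBA evaluation subsample) are dropped with a
warning; LOWESS duplicate ages collapse to their common fitted value.

## Known limitations

Clock instances are tuned per bootstrap, so training cost grows linearly
in B × folds × grid size. FIBA recomputes a LOWESS fit per (instance,
probe, permutation); for panels with hundreds of active probes this is the
dominant cost. The ensemble currently refits calibration after permutation
by default (`recalibrate_after_permutation`), which is self-consistent but
means FIBA scores fold in calibration variability. Hazard-ratio estimates
through the clock chain are attenuated by the gap–offset correlation, as
expected for a noisy exposure; no deattenuation is attempted.
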