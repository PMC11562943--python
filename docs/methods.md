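# Methods

## Setting and problem

Outpatient CBT services triage clients into high-intensity (one-on-one,
HICBT) or low-intensity (eCBT or group, LICBT) treatment, classically by
clinician judgement or stepped care.  *Stratified care* instead assigns
intensity at intake from a prognostic model of treatment response.  This
package implements and evaluates such a triage pipeline: per-instrument
prognostic models of reliable and clinically significant improvement
(RCSI) on the PHQ-9 and GAD-7, a dual-model case-complexity rule, and a
comparison of the model's recommended intensity against the clinician's
actual assignment.

## Outcome definitions

For each instrument the episode outcome is three-valued.  With initial
score `s0`, last in-window score `s1`, clinical threshold `c` and
reliable-change margin `m`:

- `below_threshold` if `s0 < c`;
- `rcsi` if `s0 >= c` and `s0 - s1 >= m`;
- `no_rcsi` otherwise.

Defaults: PHQ-9 `c = 10, m = 6` (range 0–27); GAD-7 `c = 8, m = 5`
(range 0–21).  The margins are fixed rule constants, not re-derived from
reliability coefficients.  The *last* score is the latest recorded score
within the episode's completion window.  Actual case complexity is
`Cx` iff both instrument statuses are exactly `no_rcsi`; a client below
threshold on either instrument is `St`.  (The alternative reading in
which below-threshold non-improvers also count as complex is rejected
because it is inconsistent with the standard "all else" definition; the
strict reading is implemented throughout.)

## Inclusion rules

An episode enters the analysis when each instrument has ≥ 2 dated
scores and treatment was completed: the last recorded session falls
within the delivery format's completion window — 98 days from admission
for eCBT, 147 days for group and one-on-one CBT, boundary day inclusive —
or a reliable improvement (`s0 - s >= m` on either instrument) occurred
before the window closed.  The completion rule uses the last *score*
date as the last-session proxy, since sessions without scores are not
represented in the data model.

## Prognostic model

Each instrument gets a linear probability model of RCSI fitted by
LASSO:

    min over (b0, b)  (1/2n) Σ (y_i − b0 − x_i'b)²  +  λ ‖b‖₁

with predictors standardised to unit variance before penalisation (the
intercept unpenalised) and coefficients reported back on the original
scale.  Standardisation makes the penalty scale-equivariant across
dummies and numeric covariates.  Covariates: the instrument's initial
score, age, sex, employment, living arrangement (7 levels), and the four
neighbourhood marginalization quintiles.  Reference categories: male,
employed, lives by self, 1st quintile.  Missing categorical cells (whole
dummy groups) are filled by single mean imputation with training-sample
column means — the imputed value of an indicator is the observed
category probability.  This is unbiased only under MCAR and understates
variance; it is used deliberately to mirror the deployment convention
being studied.  A logistic l1 variant (`family="logistic"`) is available
for sensitivity analysis; all pipeline results use the linear family.

### Penalty selection (.632 bootstrap)

λ is selected over a log-spaced grid, default 50 points in
[1e-4, 1e-1], by minimising

    err632(λ) = 0.368 · apparent(λ) + 0.632 · oob(λ)

where `apparent` is the full-data MSE of the full-data fit and `oob`
averages out-of-bag MSE over B bootstrap refits (default B = 1000 per
grid point; the classic .632 weights, not .632+).  The loss is the mean
squared error of the continuous score against the 0/1 outcome, matching
the least-squares objective.  Ties in the argmin resolve to the larger λ
(sparser model).  Bootstrap index draws are λ-independent and shared
across the grid, so a pointwise recomputation at the same seed is
consistent with the sweep; a draw containing every client (empty
out-of-bag set) is redrawn and logged.

## Cut-offs and stratification

The fitted score `b0 + x'b` is treated as an RCSI probability
(unclipped; the linear model can leave [0, 1]).  Two deployment policies
threshold it, with "score ≥ threshold" meaning predicted RCSI:

- **fixed_0.5** — the conventional 0.5 cut-off;
- **roc_optimal** — the training-ROC threshold maximising
  sensitivity + specificity (Youden), ties resolved toward the higher
  (more specific) threshold.

Cut-offs are derived on the training half only and applied unchanged —
the deployable convention.  The ROC enumerates every distinct score;
AUC is the Mann–Whitney concordance (ties = 1/2), with a 95% DeLong
interval (bootstrap percentile interval available).

A client is predicted complex (`Cx` → recommend HICBT) iff the initial
PHQ-9 is ≥ 10 **and** the initial GAD-7 is ≥ 8 **and** neither model
predicts RCSI; otherwise standard (`St` → LICBT).  For the clinician
comparison, observed HICBT maps to a clinician `Cx` call and LICBT or
stepped care to `St` (a stepped episode's initial assignment was
low-intensity).

## Evaluation

Confusion matrices take `Cx` as the positive class; accuracy,
sensitivity and specificity are reported at full precision and rounded
half-up to 3 decimals for presentation.  Odds ratios are the 2×2
cross-product with Wald log-scale 95% intervals; any zero cell triggers
the Haldane–Anscombe +0.5 correction (flagged).  The three arms —
clinician, fixed 0.5, ROC-optimal — are compared on the full included
sample (mirroring a whole-population deployment; this partially reuses
training clients, which the report flags by also emitting test-half-only
summaries) and instrument-level ORs of predicted vs actual RCSI are
computed on the held-out half.

## Synthetic cohort generator

Because no clinical dataset ships with the package, a seeded generator
emulates the marginal structure of a published outpatient CBT sample:
n = 953; age N(34.6, 13.11²) clipped to [16, 90]; 69% female; the
published employment, living-arrangement, marginalization-quintile and
modality (36/7/57% HICBT/stepped/LICBT) frequencies, each renormalised
to the observed (non-missing) categories; first scores
N(15.0, 5.96²) for PHQ-9 and N(13.1, 5.06²) for GAD-7, rounded and
clamped to the instrument ranges.  MCAR missingness is injected at 6%
(employment), 3% (living arrangement) and 5% (the four quintiles
jointly, since all derive from one postal code).  Last scores follow a
known linear process

    last = clip(round(first − (b0 + Σ b_j x_j) − ε), range),  ε ~ N(0, σ²)

so ground truth (latent expected change, true RCSI) is recoverable for
parameter-recovery tests.  Default coefficients put the improvement on
the initial score ({−1.0, 0.4·initial} PHQ-9; {−0.9, 0.4·initial}
GAD-7) with σ = 4.9 / 4.4, reproducing the published last-score means
(10.1 / 8.8) and approximately their SDs at the default first-score
distributions.

What the generator deliberately does **not** emulate: covariates are
independent marginals and the two instruments' outcomes are conditionally
independent given covariates, whereas real depression and anxiety scores
are strongly correlated — so the synthetic complex-case prevalence
(~17–20%) runs below the published 25%, and no fidelity to the real
joint first/last-score distribution is claimed.  There are no
session-by-session trajectories (first/last only), no informative
dropout, and stepped care is a label without step-up dynamics.  Passing
tests therefore demonstrate correctness of the pipeline's logic and
estimators under a known data-generating process, not clinical validity
on real EMR data.

## Numerical choices

- Coordinate descent via scikit-learn `lasso_path`, tol 1e-7, warm
  starts across the grid; λ = 0 falls back to least squares.  Pointwise
  refits agree with the warm-started path to solver tolerance (~1e-4
  relative), which is the equality the tests assert.
- Constant (zero-variance) columns get unit scale during
  standardisation and hence exactly zero coefficients; an all-constant
  design yields the intercept-only model `mean(y)` without error.
- Train/test split: training size is round-half-up of `n · ratio`, so
  953 at ratio 0.5 gives 477 training / 476 test.
- Seed discipline: one top-level seed; per-stage sub-seeds (simulate,
  split, per-instrument bootstrap) derived via `SeedSequence`, all
  below 2³¹ and recorded in the run manifest.  Identical config + seed
  reproduces every artifact byte for byte (timestamps live only in
  `run.log`).
- Degenerate ROC input (all scores identical) leaves a single candidate
  threshold with sensitivity + specificity = 1, which is returned.

## Problem sizes

Default study-scale runs use n = 953 with B = 1000 bootstrap iterations
per λ (≈ 15–20 s on one CPU).  The test suite exercises reduced but
structurally identical conditions (n = 150–2000, B = 10–1000, grids of
10–50 points); the parameter-recovery check runs 20 replicates at
n = 2000, B = 100 on the default 50-point grid.

## Known limitations

- The linear probability model can emit scores outside [0, 1]; this is
  inherent to the chosen family and affects the interpretation, not the
  ranking, of scores.  The logistic flag exists for sensitivity checks.
- Single mean imputation understates predictor variance; no multiple
  imputation is offered by design.
- MCAR missingness, independent-marginal covariates, and
  instrument-independent noise are simplifications of real intake data
  (see above).
- The ROC-optimal threshold is a point estimate from the training half;
  its sampling variability is not propagated into the downstream
  confusion statistics.
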