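# Methods

This note documents the models, algorithms and design choices behind
`kinetrial`: what each stage computes, which knobs matter, what the
synthetic cohort does and does not emulate, and where the package
deliberately departs from or flags the published account of the trial it
emulates.

## The kinetic model

Vocabulary retention `V(t)` (0–100 test scale) and anxiety `A(t)` (1–5
Likert scale) follow uncoupled first-order linear kinetics,

    dV/dt = k1·I(t) − k2·V,      dA/dt = k3·S(t) − k4·A,

with piecewise-constant forcing: intervention intensity `I` and stress `S`
are held constant within each weekly session and normalized to [0, 1].
Parameters, with units and defaults (the values reported for the emulated
study):

| parameter | meaning | units | default |
|---|---|---|---|
| `k1` | learning-gain rate | score · week⁻¹ · (unit intensity)⁻¹ | 0.05 |
| `k2` | forgetting rate | week⁻¹ | 0.02 |
| `k3` | stress-to-anxiety rate | Likert · week⁻¹ · (unit stress)⁻¹ | 0.03 |
| `k4` | anxiety-decay rate | week⁻¹ | 0.04 |

Assumptions: the two states are uncoupled (no V–A cross-terms are
invented), the state is continuous and unclamped (instrument-range clamping
happens only at observation), and time is measured in weeks over t ∈
[0, 12].  On each constant-forcing interval the exact solution is
`y(t) = y* + (y_start − y*)·exp(−k_decay·Δt)` with
`y* = k_gain·level/k_decay`; chaining intervals yields an exact
piecewise-exponential solution used throughout as the analytic oracle.

A scale inconsistency in the source account is deliberately left exposed:
with `k1 = 0.05` and `I ≤ 1` the vocabulary steady state is `k1/k2 = 2.5`
score points, far below observed scores, so these constants cannot generate
gains of the published magnitude on the raw 0–100 scale.  The package does
not reconcile this; see "Calibration" and "Known limitations".

## The Runge–Kutta engine

`rk_core` implements a tableau-generic explicit embedded pair.  The shipped
default is the canonical 7-stage Dormand–Prince 5(4) pair with exact
rational coefficients; `validate_tableau` checks explicitness, weight-sum
consistency, the row-sum condition `c_i = Σ_j a_ij`, distinct orders, and a
degenerate-estimator condition (identical `b` and `b*` rows make the
embedded error estimate identically zero).  Validation is exact when
coefficients are `Fraction`s and uses a 1e-12 tolerance for floats.  The
published account prints a tableau whose two weight rows are identical and
whose stage count conflicts with its own update formula; the engine
therefore defaults to the canonical pair and accepts any user-supplied
tableau from JSON (numbers may be decimal or `"p/q"` rational strings) for
users who have a complete alternative scheme.  Only two coefficients of the
alternative 6(5) scheme named in the source are printed, which is not
enough to reconstruct it; the package does not guess the rest.

Error control is a Hairer-style weighted RMS norm of the embedded
difference against `atol + rtol·max(|y|, |y_high|)` (two state scales, 0–100
and 1–5, make the mixed norm appropriate).  Steps are accepted when the
norm is ≤ 1; the next step is `h·safety·err^(−1/(p̂+1))` with safety 0.9,
growth clamped to [0.2, 5] and to `[h_min, h_max]`.  Defaults: `rtol`
1e-6, `atol` 1e-9, `h_init` 0.1 week.  Dense output steps exactly onto
requested times (no interpolant): the observation grid is weekly, and
stepping onto the forcing breakpoints is also what keeps the error model
valid across forcing discontinuities — integrating blindly across a jump
degrades accuracy by roughly an order of magnitude, which the tests
demonstrate by always evaluating on the weekly grid.  No FSAL reuse and no
PI controller: correctness over micro-performance.

Verified numerical properties: agreement with the closed form to ≤ 1e-6
relative at `rtol` 1e-8 over random ≤ 12-piece schedules; fixed-step global
error slope 5 ± 0.2 on y′ = −y (measured between 16 and 32 steps — the
asymptotic regime; coarser grids still show the higher-order transient);
tightening `rtol` never worsens the final error on the linear test problem.

## The adaptive agent

`agent` encodes the published decision rules as a pure function: accuracy
> 80% advances difficulty one level, accuracy < 60% reduces it and attaches
remedial hints, an anxiety slider > 3 switches the agent role away from the
default tutor.  Thresholds are strict (boundary values inert), difficulty
is clamped to [1, 5], and at most 3 adaptations (nonzero difficulty delta
or role change) apply per session.

Choices the source leaves open, fixed here and exposed in `AgentConfig`:

* **Role tie-break.**  A raised slider names two possible roles; the
  package switches to the empathetic *peer supporter* when the student is
  also struggling (accuracy < 60%) and to the *motivator* (who awards a
  badge) otherwise — consistent with the published role descriptions.
* **What counts as an adaptation.**  Any applied nonzero difficulty change
  or role change; a clamped no-op does not count.
* **The forcing map.**  Nothing numeric links agent state to `I`/`S` in the
  source, so the package defines a documented map:
  `I = 0.5 + 0.1·[role ≠ tutor] + 0.05·(adaptations this session)`,
  `S = difficulty/levels − 0.1·[role = peer supporter]`, both clamped to
  [0, 1].  All constants are configuration.
* The "decision-tree machine learning" of the source is realized as these
  explicit printed threshold rules; no trained model exists to reproduce.

## The synthetic cohort

`cohort_sim` emulates a two-arm, 75-per-arm, 13-timepoint (weeks 0–12)
trial.  Experimental students run the agent loop (3 decision rounds per
weekly session); control students keep fixed difficulty 3 and the tutor
role, i.e. constant forcing (0.5, 0.6).  Per student, the latent (V, A)
state advances one week at a time through the adaptive RK engine.  Quiz
accuracy is generated as `logistic((V − 60)/15)` plus Gaussian noise (a
monotone link is required to drive the accuracy thresholds; constants are
configuration), and the slider as the rounded noisy latent anxiety.

Statistical structure, chosen as the simplest forms consistent with the
published summary tables (the source states none):

* **Heterogeneity**: student rate constants are lognormal multiples of the
  population values (log-scale σ = 0.2).
* **Observation noise**: additive Gaussian (SD 2.0 score points for
  vocabulary, 0.2 Likert units for the affective scales), clamped to the
  instrument range.
* **Pre/post dependence**: shared student-level latents plus a residual
  correlation ρ = 0.5 for the three non-dynamic Likert measures
  (motivation, self-efficacy, life satisfaction), which drift linearly
  between correlated pre/post latents — the published analysis presupposes
  within-student correlation but never reports it.
* **Corruption**: completely-at-random missingness at rate 0.02 (matching
  the "< 5%" reported) and outlier injection at rate 0.01, set to the
  pooled measure × week mean + 4 SD — emulating entry errors, possibly
  outside the instrument range, that the |z| > 3.29 screen is designed to
  catch.

**Calibration.**  With `calibrate=True` (default) the week-0 and week-12
observations are affinely rescaled per arm × measure to hit the published
group means and SDs exactly (rank- and correlation-preserving; corruption
is applied afterwards).  This is what lets the pipeline reproduce the
published descriptive tables without pretending the kinetic constants can
generate them.  Calibrated endpoints and model-driven interior weeks are
therefore mutually inconsistent by construction, and fits to calibrated
cohorts are expected to be poor — the package reports them as such.
Model-validation experiments use uncalibrated data only.

What passing tests on this cohort do **not** show about real data: the
generator's distributional forms (Gaussian noise, lognormal heterogeneity,
linear drift, logistic accuracy link) are conventions, not estimates; real
trial data could depart from all of them, and the calibration device has no
real-data counterpart.

## Fitting

`fitting` implements rand/1/bin differential evolution exactly: mutant
`x_r1 + F·(x_r2 − x_r3)` with distinct random indices, binomial crossover
with one guaranteed gene, out-of-bounds genes reflected into the box,
greedy selection.  Defaults NP = 40, F = 0.8, CR = 0.9, 200 generations,
bounds [0, 1] per parameter — canonical values, all configurable; the best
trace is non-increasing by construction.  `scipy`'s implementation is used
only as an independent cross-check in tests.

`fit_kinetics` estimates (k1, k2) from vocabulary and (k3, k4) from anxiety
as two independent two-parameter problems (the model is uncoupled).  The
70/30 split is by student, arm-stratified and seeded — within-student
points are correlated, so an independent validation set must hold out whole
students.  The objective is unweighted pooled SSE between observations and
predictions started at each student's observed week-0 value (missing
baselines are filled with the cohort's week-0 mean) and driven by the
student's recorded forcing.  Holdout R² = 1 − SSE/SST with SST about the
holdout mean, evaluated on weeks 1–12 (week 0 is the initial condition and
would inflate R² by contributing zero error).

Two prediction back-ends: `"rk"` (default) advances all students jointly
through the RK engine with 4 fixed steps inside each constant-forcing week;
`"exact"` applies the closed-form weekly relaxation.  For this linear model
they agree to ≈ 1e-6 in the estimates (property-tested); the exact back-end
is used for the B = 200 student-level percentile bootstrap (reduced DE
budget per resample), where refit speed matters.  The source does not state
its split unit, DE configuration or CI construction; these are the
package's choices, documented as such.

Identifiability caveat: under near-constant forcing the gain and decay
rates trade off against each other and the gain is weakly identified from
short noisy trajectories — prediction quality (R²) is then much better
determined than the individual constants.  Recovery experiments therefore
use a linearly increasing forcing ramp (0.3 → 0.9 over 12 weeks), which
separates the two rates; on noiseless ramp trajectories DE recovers all
four constants to ≤ 1e-3.

## Trial statistics

Cleaning screens |z| > 3.29 per measure × week with arms pooled (the cutoff
is published, the stratification is not; pooled is the common reading),
then mean-imputes every absent student × week × measure cell within
arm × week × measure.  The screen-remove-impute cycle iterates to a fixed
point: a single pass is not exactly idempotent (removals shrink a cell's SD
and can push a borderline value over the threshold on re-application), and
the fixed-point form makes `clean(clean(x)) = clean(x)` hold exactly.
Round 1 is the plain single pass; later rounds rarely remove anything.
Zero-SD cells are skipped and logged.

The group × time ANOVA is implemented as a split-plot (repeated measures on
time) via the sum/difference-score decomposition with weighted (cell-size)
sums of squares, which is exact for unbalanced arms and yields two exact
identities used as internal cross-checks: interaction F equals the squared
pooled t on change scores, and the SS components sum to the total SS.
Effect size is partial η² = SS_effect/(SS_effect + SS_error-for-effect).  A
purely between-cells two-way ANOVA (via statsmodels) is available behind a
flag for comparison.  t-tests default to pooled variance — the published
baseline row (t(148) = 0.42) is reproducible only under pooled df — with
Welch behind a flag.  Cohen's d is offered both as pooled-SD standardized
difference and as change-score d (mean change / SD of changes).
Cronbach's α is the definitional formula; the simulated trial carries scale
scores, not item responses, so the report computes α only when item-level
data are supplied.  No multiple-testing correction is applied (none was in
the source); raw p-values are reported.  A linear mixed model with a class
random intercept is *not* estimated: one intact class per arm means two
clusters, so the class variance is confounded with the group effect; the
report carries an explanatory note instead.

Published statistics the pipeline reproduces exactly from published inputs:
the vocabulary baseline t row, the percent changes (30.2%/17.2%), and the
post-hoc percent differences (anxiety −25%, life satisfaction +15%,
within-arm anxiety −32.3%).  Statistics it deliberately does not reproduce,
because they are internally inconsistent with the published summary tables
under standard formulas: the post-test t values, the affective baseline t
values (several have equal printed means but nonzero printed t), the ANOVA
F/η² table, Cohen's d of 1.34/0.72, and the reliability αs.
`discrepancy_report()` recomputes each reachable one and buckets it as
consistent or discrepant; nothing is tuned to match.

## Problem sizes and tolerances

The validation stand-ins use 75 students × 13 weekly points (holdout R²)
and 20 trajectories (recovery), chosen to mirror the emulated trial's arm
size while keeping a full differential-evolution fit comfortable on a
single CPU; the test suite uses smaller cohorts (6–40 per arm) and reduced
DE budgets (NP 16–20, 30–80 generations), which the two-parameter problems
do not need more than.  Type-I error calibration uses 2000 null cohorts at
ρ = 0.5 against a ±0.02 band around the nominal 0.05.  Bootstrap coverage
is checked at 12 replicates × 80 resamples against a ≥ 0.80 floor for the
nominal 95% interval.

## Known limitations

* The two documented source inconsistencies — the degenerate printed
  tableau and the scale-inconsistent rate constants — are surfaced, not
  repaired; calibration is an explicit device with no real-data analogue.
* The agent's forcing map and the accuracy link are package conventions;
  conclusions that depend on their specific constants should treat them as
  free parameters.
* The generator does not simulate class-level clustering (a two-class
  label is carried in the data but not modelled), item-level responses, or
  any qualitative data stream.
* Gain constants are weakly identified under near-constant forcing; R²
  claims transfer to real data only insofar as real forcing varies.
* The solver is explicit and non-stiff by design; stiff extensions of the
  model would need a different integrator.
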