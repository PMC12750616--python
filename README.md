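# kinetrial

Kinetic ODE modelling and pre/post statistics for a simulated two-arm
educational intervention trial.

`kinetrial` re-implements, as a tested and reusable pipeline, the
quantitative analysis of a 12-week, two-arm (75 students per arm) trial of
an adaptive game-based vocabulary intervention for university EFL learners:
a rule-based adaptive-agent engine, a first-order kinetic model of
vocabulary retention and anxiety solved with an embedded Runge–Kutta pair
under adaptive step-size control, differential-evolution parameter fitting
with holdout validation, and the pre/post trial statistics.  Because no raw
data from the original study are available, the package ships a synthetic
cohort generator that emulates the trial's statistical structure, so every
stage of the analysis is runnable and testable end to end.

It is aimed at methodologists and students in education/behavioural
research who want a worked, fully reproducible example of coupling a
mechanistic ODE model to a pre/post trial analysis — and at anyone who
needs the individual components (a tableau-generic embedded RK solver, a
rand/1/bin differential-evolution optimizer, a split-plot ANOVA with exact
small-sample identities).

## The model

Vocabulary retention `V` (0–100 test scale) and anxiety `A` (1–5 Likert
scale) follow uncoupled linear kinetics driven by piecewise-constant
forcing derived from the adaptive agent's weekly session decisions:

```
dV/dt = k1·I(t) − k2·V        dA/dt = k3·S(t) − k4·A
```

where `I(t)` is intervention intensity and `S(t)` stress, both normalized
to [0, 1] and constant within each weekly session; `k1..k4 ≥ 0` are rate
constants (defaults `k1 = 0.05`, `k2 = 0.02`, `k3 = 0.03`, `k4 = 0.04`, the
values reported for the emulated study).  On each constant-forcing interval
the exact solution is an exponential relaxation toward the local steady
state `y* = k_gain·level/k_decay`; chaining intervals gives an exact
piecewise-exponential solution that serves as the test oracle for the
numerical engine.

The numerical engine is a tableau-generic explicit embedded Runge–Kutta
pair (default: the canonical 7-stage Dormand–Prince 5(4) with exact
rational coefficients) with Hairer-style mixed absolute/relative error
control and an elementary step-size controller.  Rate constants are
estimated with a hand-rolled rand/1/bin differential evolution on a 70/30
student-level train/holdout split; fit quality is reported as holdout R².
The trial statistics stage screens outliers at |z| > 3.29, mean-imputes
missing cells, and produces descriptives, pooled/Welch t-tests, a
split-plot (mixed) group × time ANOVA with partial η², Cohen's d, and a
low-baseline subgroup analysis.

## Worked example

```python
import kinetrial as kt
from kinetrial.config import RunConfig, FitOptions
from kinetrial.pipeline import run_pipeline

cfg = RunConfig(seed=1, de=kt.DEConfig(np_size=20, generations=80),
                fit=FitOptions(bootstrap=100))
res = run_pipeline(cfg, "readme_run")

rep = res["report"]["measures"]["vocab"]
print(rep["percent_change"])
inter = next(r for r in rep["anova"] if r["effect"] == "group:time")
print(f"group x time: F = {inter['F']:.2f}, partial eta2 = {inter['partial_eta2']:.2f}")
```

prints

```
{'control': 17.5, 'experimental': 30.2}
group x time: F = 124.60, partial eta2 = 0.46
```

The simulated experimental arm gains 30.2% in vocabulary score (60.3 →
78.5) versus 17.5% in the control arm (59.6 → 70.1), matching the trial's
published descriptive tables, to which the generator's endpoints are
calibrated (an affine, rank-preserving rescale of week-0/week-12 values).
The group × time interaction is the intervention-effect test of the
split-plot ANOVA.

Fitting the kinetic model to this *calibrated* cohort gives a low holdout
R² for vocabulary (≈ 0.10) with the gain rate pinned at its upper bound —
deliberately surfaced, not hidden: rate constants of the published
magnitude cannot produce score gains of the published magnitude on the raw
0–100 scale, so calibrated endpoints and the published constants are
mutually inconsistent.  The published R² claims are instead reproduced on
*uncalibrated* stand-in cohorts generated by the model itself (see below),
where the fit recovers the generating constants and the holdout R² exceeds
the published floors.  `discrepancy_report()` likewise recomputes every
published inferential statistic that is reachable from the published
summary tables and flags the ones that are internally inconsistent (e.g.
post-test t values and Cohen's d).

A command-line interface mirrors the library:

```
kinetrial simulate --seed 1 --out cohort/
kinetrial fit --data cohort/ --out fit.json
kinetrial stats --data cohort/ --out report.json
kinetrial run --check
```

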