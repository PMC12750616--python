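"""Synthetic two-arm longitudinal cohort generator.

Emulates the statistical structure of a 12-week, two-arm (75 students per
arm) educational intervention trial: weekly vocabulary scores on a 0-100
test scale and four affective measures on 1-5 Likert scales.  Vocabulary and
anxiety evolve according to the kinetic ODE model driven by agent-derived
piecewise-constant forcing (experimental arm runs the adaptive-agent loop;
the control arm plays static drills at fixed difficulty under the tutor
role).  Motivation, self-efficacy and life satisfaction carry no dynamic
model; they drift linearly between correlated pre/post latents.

Heterogeneity and noise:

* student-level rate constants are lognormal multiples of the population
  values (``k_dispersion`` is the log-scale sigma),
* observations add Gaussian noise and clamp to the instrument range,
* pre/post dependence comes from shared student-level latents plus a
  configurable residual correlation ``rho`` for the drift measures.

Calibration mode rescales week-0 and final-week observations per arm and
measure (an affine map, rank- and correlation-preserving) so that group
means and SDs equal the configured targets exactly — the published
descriptive tables can then be reproduced from the synthetic cohort even
though the published rate constants alone cannot generate score changes of
the published magnitude on the raw 0-100 scale.  Missing values (completely
at random) and injected outliers (mean + 4 SD) are applied after
calibration as a separate corruption step for the cleaning stage to find.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .agent import AgentConfig, AgentState, Role, SessionObservation, apply_action, decide, session_forcing
from .errors import ConfigError
from .kinetics import ForcingSchedule, ODEParams, Trajectory
from .rk_core import IntegratorConfig, dormand_prince_54, integrate_adaptive

__all__ = [
    "ARMS",
    "ANALYSIS_MEASURES",
    "SimConfig",
    "TrialDataset",
    "simulate_student",
    "simulate_cohort",
    "simulate_null_prepost",
]

ARMS = ("experimental", "control")
#: measures analysed pre/post (the instrument battery)
ANALYSIS_MEASURES = ("vocab", "motivation", "self_efficacy", "anxiety", "life_satisfaction")
#: session-process measures recorded weekly from week 1
SESSION_MEASURES = ("quiz_accuracy", "anxiety_slider", "difficulty")

# (mean, sd) per arm, baseline week 0: published pre-test summary table
_BASELINES = {
    "vocab": {"experimental": (60.2, 5.8), "control": (59.8, 6.0)},
    "motivation": {"experimental": (3.3, 0.7), "control": (3.2, 0.8)},
    "self_efficacy": {"experimental": (3.3, 0.6), "control": (3.3, 0.7)},
    "anxiety": {"experimental": (3.1, 0.5), "control": (3.1, 0.6)},
    "life_satisfaction": {"experimental": (4.0, 0.6), "control": (4.0, 0.7)},
}
# (mean, sd) per arm, final week: published post-test summaries
_POST_TARGETS = {
    "vocab": {"experimental": (78.4, 6.2), "control": (70.1, 7.1)},
    "motivation": {"experimental": (4.5, 0.6), "control": (3.9, 0.7)},
    "self_efficacy": {"experimental": (4.3, 0.5), "control": (3.7, 0.6)},
    "anxiety": {"experimental": (2.1, 0.4), "control": (2.8, 0.5)},
    "life_satisfaction": {"experimental": (4.6, 0.5), "control": (4.0, 0.6)},
}
_RANGES = {"vocab": (0.0, 100.0)}  # Likert measures default to (1, 5)
_NOISE_SD = {
    "vocab": 2.0,
    "motivation": 0.2,
    "self_efficacy": 0.2,
    "anxiety": 0.2,
    "life_satisfaction": 0.2,
}


def _measure_range(measure: str) -> tuple[float, float]:
    return _RANGES.get(measure, (1.0, 5.0))


@dataclass(frozen=True)
class SimConfig:
    """All knobs of the cohort generator (defaults = the emulated study)."""

    n_per_arm: int = 75
    weeks: int = 12
    seed: int = 0
    params: ODEParams = field(default_factory=ODEParams)
    k_dispersion: float = 0.2  # lognormal sigma on student rate constants
    rho: float = 0.5  # pre/post residual correlation, drift measures
    baselines: dict = field(default_factory=lambda: {k: dict(v) for k, v in _BASELINES.items()})
    post_targets: dict = field(default_factory=lambda: {k: dict(v) for k, v in _POST_TARGETS.items()})
    noise_sd: dict = field(default_factory=lambda: dict(_NOISE_SD))
    missing_rate: float = 0.02
    outlier_rate: float = 0.01
    calibrate: bool = True
    agent: AgentConfig = field(default_factory=AgentConfig)
    rounds_per_session: int = 3
    control_difficulty: int = 3
    quiz_link_center: float = 60.0
    quiz_link_scale: float = 15.0
    quiz_noise_sd: float = 0.05
    slider_noise_sd: float = 0.3
    solver: IntegratorConfig = field(default_factory=IntegratorConfig)

    def __post_init__(self):
        if self.n_per_arm < 2:
            raise ConfigError("n_per_arm must be >= 2")
        if self.weeks < 1:
            raise ConfigError("weeks must be >= 1")
        if not (-1.0 < self.rho < 1.0):
            raise ConfigError("rho must lie in (-1, 1)")
        for rate, name in ((self.missing_rate, "missing_rate"), (self.outlier_rate, "outlier_rate")):
            if not (0.0 <= rate <= 0.05):
                raise ConfigError(f"{name} must lie in [0, 0.05]")
        if any(sd < 0 for sd in self.noise_sd.values()) or self.k_dispersion < 0:
            raise ConfigError("noise SDs and k_dispersion must be >= 0")


@dataclass
class TrialDataset:
    """Long-format trial records plus per-student weekly forcing and metadata.

    ``records`` columns: student_id, arm, class_label, week, measure, value —
    at most one record per (student, week, measure).  ``forcing`` columns:
    student_id, arm, week, I, S, one row per student and session week
    (the level held on the interval [week-1, week]).
    """

    records: pd.DataFrame
    forcing: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def wide(self, measure: str) -> pd.DataFrame:
        """students x weeks value matrix for one measure (NaN where missing)."""
        sub = self.records[self.records["measure"] == measure]
        return sub.pivot(index="student_id", columns="week", values="value")

    def arm_of(self) -> pd.Series:
        """student_id -> arm mapping."""
        return self.records.drop_duplicates("student_id").set_index("student_id")["arm"]

    def to_csv(self, directory) -> dict[str, Path]:
        """Write records.csv, forcing.csv and meta.json into a directory."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths = {
            "records": directory / "records.csv",
            "forcing": directory / "forcing.csv",
            "meta": directory / "meta.json",
        }
        self.records.to_csv(paths["records"], index=False)
        self.forcing.to_csv(paths["forcing"], index=False)
        paths["meta"].write_text(json.dumps(self.meta, indent=2, sort_keys=True, default=str))
        return paths

    @classmethod
    def from_csv(cls, directory) -> "TrialDataset":
        directory = Path(directory)
        records = pd.read_csv(directory / "records.csv")
        forcing_path = directory / "forcing.csv"
        forcing = pd.read_csv(forcing_path) if forcing_path.exists() else pd.DataFrame(
            columns=["student_id", "arm", "week", "I", "S"]
        )
        meta_path = directory / "meta.json"
        meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
        return cls(records, forcing, meta)


def _logistic(x: np.ndarray | float) -> np.ndarray | float:
    return 1.0 / (1.0 + np.exp(-x))


def _draw_params(config: SimConfig, rng: np.random.Generator) -> ODEParams:
    base = config.params
    if config.k_dispersion == 0:
        return base
    mult = np.exp(rng.normal(0.0, config.k_dispersion, size=4))
    return ODEParams(base.k1 * mult[0], base.k2 * mult[1], base.k3 * mult[2], base.k4 * mult[3])


def simulate_student(
    arm: str, config: SimConfig, rng: np.random.Generator
) -> dict:
    """Simulate one student: latent trajectory, session records, forcing.

    Experimental students run the adaptive-agent loop (``rounds_per_session``
    decision opportunities per weekly session, adaptation count capped);
    control students keep fixed difficulty and the tutor role throughout.
    The latent (V, A) state advances one week at a time through the adaptive
    Runge-Kutta engine under the session's constant forcing.

    Returns a dict with keys ``params`` (the student's rate constants),
    ``trajectory`` (latent weekly V/A), ``sessions`` (list of per-week dicts
    with quiz_accuracy, anxiety_slider, difficulty, I, S) and ``drift``
    (latent weekly values of the three non-dynamic Likert measures).
    """
    if arm not in ARMS:
        raise ConfigError(f"unknown arm {arm!r}")
    params = _draw_params(config, rng)
    V0 = rng.normal(*config.baselines["vocab"][arm])
    A0 = rng.normal(*config.baselines["anxiety"][arm])

    tableau = dormand_prince_54()
    state = AgentState(difficulty=config.control_difficulty, role=Role.TUTOR)
    V, A = float(V0), float(A0)
    V_path, A_path = [V], [A]
    sessions = []

    def rate(_t, y, I=0.0, S=0.0):
        return np.array([params.k1 * I - params.k2 * y[0], params.k3 * S - params.k4 * y[1]])

    for _week in range(1, config.weeks + 1):
        state = dataclasses.replace(state, adaptations_this_session=0)
        obs_acc = obs_slider = None
        for rnd in range(config.rounds_per_session):
            acc = float(np.clip(
                _logistic((V - config.quiz_link_center) / config.quiz_link_scale)
                + rng.normal(0.0, config.quiz_noise_sd), 0.0, 1.0,
            ))
            slider = int(np.clip(round(A + rng.normal(0.0, config.slider_noise_sd)), 1, 5))
            if rnd == 0:
                obs_acc, obs_slider = acc, slider
            if arm == "experimental":
                action = decide(SessionObservation(acc, slider), state, config.agent)
                state = apply_action(state, action, config.agent)
        I, S = session_forcing(state, config.agent)
        sol = integrate_adaptive(
            lambda t, y: rate(t, y, I, S), 0.0, 1.0, [V, A], tableau, config.solver
        )
        V, A = float(sol.states[-1, 0]), float(sol.states[-1, 1])
        V_path.append(V)
        A_path.append(A)
        sessions.append(
            {"quiz_accuracy": obs_acc, "anxiety_slider": obs_slider,
             "difficulty": state.difficulty, "I": I, "S": S}
        )

    # non-dynamic Likert measures: correlated pre/post latents, linear drift
    drift = {}
    for measure in ("motivation", "self_efficacy", "life_satisfaction"):
        pre_m, pre_sd = config.baselines[measure][arm]
        post_m, post_sd = config.post_targets[measure][arm]
        pre = rng.normal(pre_m, pre_sd)
        z = rng.normal()
        post = post_m + config.rho * post_sd * ((pre - pre_m) / pre_sd if pre_sd > 0 else 0.0) \
            + np.sqrt(1.0 - config.rho**2) * post_sd * z
        drift[measure] = np.linspace(pre, post, config.weeks + 1)

    times = np.arange(config.weeks + 1, dtype=float)
    return {
        "params": params,
        "trajectory": Trajectory(times, np.array(V_path), np.array(A_path), V0, A0),
        "sessions": sessions,
        "drift": drift,
    }


def _observe(latent: np.ndarray, measure: str, noise_sd: float, rng: np.random.Generator) -> np.ndarray:
    lo, hi = _measure_range(measure)
    return np.clip(latent + rng.normal(0.0, noise_sd, size=latent.shape), lo, hi)


def simulate_cohort(config: SimConfig | None = None) -> TrialDataset:
    """Simulate the full two-arm cohort; reproducible given (config, seed).

    Each student receives an independent child stream of the master seed, so
    the dataset is byte-identical across runs with identical configuration.
    """
    config = config or SimConfig()
    n = config.n_per_arm
    streams = np.random.SeedSequence(config.seed).spawn(2 * n + 1)
    corruption_rng = np.random.default_rng(streams[-1])

    rows = []
    forcing_rows = []
    for a_idx, arm in enumerate(ARMS):
        for i in range(n):
            sid = f"{'E' if arm == 'experimental' else 'C'}{i + 1:03d}"
            rng = np.random.default_rng(streams[a_idx * n + i])
            sim = simulate_student(arm, config, rng)
            klass = f"class_{arm}"

            obs = {
                "vocab": _observe(sim["trajectory"].V, "vocab", config.noise_sd["vocab"], rng),
                "anxiety": _observe(sim["trajectory"].A, "anxiety", config.noise_sd["anxiety"], rng),
            }
            for measure, latent in sim["drift"].items():
                obs[measure] = _observe(latent, measure, config.noise_sd[measure], rng)
            for measure in ANALYSIS_MEASURES:
                for week in range(config.weeks + 1):
                    rows.append((sid, arm, klass, week, measure, float(obs[measure][week])))
            for week, sess in enumerate(sim["sessions"], start=1):
                for measure in SESSION_MEASURES:
                    rows.append((sid, arm, klass, week, measure, float(sess[measure])))
                forcing_rows.append((sid, arm, week, sess["I"], sess["S"]))

    records = pd.DataFrame(
        rows, columns=["student_id", "arm", "class_label", "week", "measure", "value"]
    )
    forcing = pd.DataFrame(forcing_rows, columns=["student_id", "arm", "week", "I", "S"])

    if config.calibrate:
        records = _calibrate(records, config)
    records = _corrupt(records, config, corruption_rng)

    meta = {
        "seed": config.seed,
        "n_per_arm": config.n_per_arm,
        "weeks": config.weeks,
        "calibrated": config.calibrate,
        "missing_rate": config.missing_rate,
        "outlier_rate": config.outlier_rate,
        "params": dataclasses.asdict(config.params),
        "k_dispersion": config.k_dispersion,
    }
    return TrialDataset(records, forcing, meta)


def _calibrate(records: pd.DataFrame, config: SimConfig) -> pd.DataFrame:
    """Affine-rescale week-0 and final-week values to the configured targets.

    x -> target_mean + (x - mean(x)) * target_sd / sd(x), per arm and
    measure; sample SD (ddof=1).  Exact in mean and SD, preserves ranks and
    all correlations with other weeks.
    """
    records = records.copy()
    for measure in ANALYSIS_MEASURES:
        for arm in ARMS:
            for week, targets in ((0, config.baselines), (config.weeks, config.post_targets)):
                t_mean, t_sd = targets[measure][arm]
                mask = (
                    (records["measure"] == measure)
                    & (records["arm"] == arm)
                    & (records["week"] == week)
                )
                vals = records.loc[mask, "value"]
                sd = vals.std(ddof=1)
                if sd > 0:
                    records.loc[mask, "value"] = t_mean + (vals - vals.mean()) * (t_sd / sd)
                else:
                    records.loc[mask, "value"] = t_mean
    return records


def _corrupt(records: pd.DataFrame, config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Apply MCAR missingness and outlier injection to analysis measures.

    Injected outliers are set to the pooled (both arms) measure x week mean
    plus 4 pooled SDs — emulating entry errors, which may fall outside the
    instrument range and which the downstream |z| > 3.29 screen is designed
    to catch.
    """
    if config.missing_rate == 0 and config.outlier_rate == 0:
        return records
    records = records.copy()
    analysis = records["measure"].isin(ANALYSIS_MEASURES).to_numpy()
    u = rng.random(len(records))
    drop = analysis & (u < config.missing_rate)
    u2 = rng.random(len(records))
    spike = analysis & ~drop & (u2 < config.outlier_rate)
    if spike.any():
        stats = records[analysis].groupby(["week", "measure"])["value"].agg(["mean", "std"])
        for idx in np.flatnonzero(spike):
            key = (records.iloc[idx]["week"], records.iloc[idx]["measure"])
            m, s = stats.loc[key, "mean"], stats.loc[key, "std"]
            records.iloc[idx, records.columns.get_loc("value")] = m + 4.0 * s
    return records[~drop].reset_index(drop=True)


def simulate_null_prepost(
    n_per_arm: int, rho: float = 0.5, seed: int = 0, mean: float = 60.0, sd: float = 6.0
) -> pd.DataFrame:
    """Null pre/post draws: both arms share one bivariate-normal distribution.

    Convenience generator for type-I-error calibration of the pre/post
    inferential machinery: no group effect, no time effect, no interaction;
    within-student correlation ``rho``.  Returns columns student_id, arm,
    pre, post.
    """
    rng = np.random.default_rng(seed)
    n = 2 * n_per_arm
    cov = sd**2 * np.array([[1.0, rho], [rho, 1.0]])
    draws = rng.multivariate_normal([mean, mean], cov, size=n)
    return pd.DataFrame(
        {
            "student_id": [f"S{i:04d}" for i in range(n)],
            "arm": ["experimental"] * n_per_arm + ["control"] * n_per_arm,
            "pre": draws[:, 0],
            "post": draws[:, 1],
        }
    )
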