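"""Pre/post trial statistics: cleaning, t-tests, split-plot ANOVA, effect sizes.

The analysis stage of the pipeline.  Observations are screened for outliers
(|z| > 3.29 within each measure x week cell, arms pooled), removed values
and missing cells are mean-imputed within arm x week x measure, and the
cleaned data feed descriptive tables, pooled/Welch two-sample t-tests, a
split-plot (mixed) two-way ANOVA with partial eta-squared, Cohen's d,
Cronbach's alpha, and a low-baseline subgroup analysis.

With two time points the split-plot interaction test is algebraically a
pooled t-test on per-student change scores (F = t^2); the implementation
keeps both routes and the identity is property-tested.  Cleaning iterates
(screen -> remove -> impute) to a fixed point so it is exactly idempotent.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import published
from .cohort_sim import ANALYSIS_MEASURES, TrialDataset
from .errors import InsufficientDataError, UndefinedStatisticError

__all__ = [
    "CleaningLog",
    "StatsReport",
    "clean_dataset",
    "percent_change",
    "two_sample_t",
    "split_plot_anova",
    "mixed_anova",
    "cohens_d",
    "cohens_d_change",
    "cronbach_alpha",
    "subgroup_gains",
    "compute_stats_report",
    "discrepancy_report",
]

Z_THRESHOLD = 3.29  # two-sided normal z cutting ~0.1% of mass


@dataclass
class CleaningLog:
    """Everything the cleaning stage removed, imputed or skipped."""

    z_threshold: float
    outliers_removed: list = field(default_factory=list)  # (sid, measure, week, z)
    values_imputed: list = field(default_factory=list)  # (sid, measure, week, value)
    cells_skipped: list = field(default_factory=list)  # (measure, week) zero-SD cells
    rounds: int = 0

    def to_dict(self) -> dict:
        return {
            "z_threshold": self.z_threshold,
            "n_outliers_removed": len(self.outliers_removed),
            "n_values_imputed": len(self.values_imputed),
            "outliers_removed": [list(x) for x in self.outliers_removed],
            "values_imputed": [list(x) for x in self.values_imputed],
            "cells_skipped": [list(x) for x in self.cells_skipped],
            "rounds": self.rounds,
        }


def clean_dataset(
    data: TrialDataset, z_threshold: float = Z_THRESHOLD
) -> tuple[TrialDataset, CleaningLog]:
    """Remove |z| > threshold outliers and mean-impute missing cells.

    z-scores are computed per measure x week across all students (arms
    pooled, sample SD); screening applies only to the analysis measures.
    Removal and imputation are iterated to a fixed point (the first round is
    the plain screen-then-impute pass; later rounds almost never fire), so
    applying ``clean_dataset`` to its own output is the identity.  Cells
    with zero SD are skipped and logged.  Imputed values equal the mean of
    the student's arm at that week and measure.
    """
    records = data.records.copy()
    log = CleaningLog(z_threshold)
    students = records[["student_id", "arm", "class_label"]].drop_duplicates("student_id")
    measures = [m for m in ANALYSIS_MEASURES if m in set(records["measure"])]
    analysis_weeks = sorted(
        records.loc[records["measure"].isin(measures), "week"].unique()
    )

    skipped = set()
    while True:
        # --- screen and remove (arms pooled within measure x week) ---
        drop_idx = []
        for (measure, week), cell in records[
            records["measure"].isin(measures)
        ].groupby(["measure", "week"]):
            sd = cell["value"].std(ddof=1)
            if not sd > 0:
                skipped.add((measure, int(week)))
                continue
            z = (cell["value"] - cell["value"].mean()) / sd
            out = z.abs() > z_threshold
            for idx in cell.index[out]:
                drop_idx.append(idx)
                log.outliers_removed.append(
                    (records.at[idx, "student_id"], measure, int(week), float(z[idx]))
                )
        records = records.drop(index=drop_idx)

        # --- impute every absent (student, week, measure) analysis cell ---
        new_rows = []
        for measure in measures:
            sub = records[records["measure"] == measure]
            have = set(zip(sub["student_id"], sub["week"]))
            arm_means = sub.groupby(["arm", "week"])["value"].mean()
            for _, srow in students.iterrows():
                for week in analysis_weeks:
                    if (srow["student_id"], week) in have:
                        continue
                    if (srow["arm"], week) not in arm_means.index:
                        skipped.add((measure, int(week)))
                        continue
                    value = float(arm_means[(srow["arm"], week)])
                    new_rows.append(
                        (srow["student_id"], srow["arm"], srow["class_label"],
                         int(week), measure, value)
                    )
                    log.values_imputed.append(
                        (srow["student_id"], measure, int(week), value)
                    )
        if new_rows:
            records = pd.concat(
                [records, pd.DataFrame(new_rows, columns=records.columns)],
                ignore_index=True,
            )
        log.rounds += 1
        if not drop_idx and not new_rows:
            break

    log.cells_skipped = sorted(skipped)
    records = records.sort_values(
        ["measure", "student_id", "week"], kind="mergesort"
    ).reset_index(drop=True)
    meta = dict(data.meta, cleaned=True, z_threshold=z_threshold)
    return TrialDataset(records, data.forcing, meta), log


def percent_change(pre_mean: float, post_mean: float) -> float:
    """100 * (post - pre) / pre, reported to one decimal place."""
    if pre_mean == 0:
        raise UndefinedStatisticError("percent change undefined for zero pre mean")
    return round(100.0 * (post_mean - pre_mean) / pre_mean, 1)


def two_sample_t(
    m1: float, s1: float, n1: int, m2: float, s2: float, n2: int,
    variant: str = "pooled",
) -> tuple[float, float, float]:
    """Two-sample t from summary statistics; returns (t, df, two-sided p)."""
    if n1 < 2 or n2 < 2:
        raise InsufficientDataError("need n >= 2 per group")
    if s1 == 0 and s2 == 0:
        if m1 == m2:
            raise UndefinedStatisticError("t undefined: zero variance, equal means")
        return (np.inf if m1 > m2 else -np.inf), float(n1 + n2 - 2), 0.0
    if variant == "pooled":
        sp2 = ((n1 - 1) * s1**2 + (n2 - 1) * s2**2) / (n1 + n2 - 2)
        t = (m1 - m2) / np.sqrt(sp2 * (1 / n1 + 1 / n2))
        df = float(n1 + n2 - 2)
    elif variant == "welch":
        v1, v2 = s1**2 / n1, s2**2 / n2
        t = (m1 - m2) / np.sqrt(v1 + v2)
        df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    else:
        raise ValueError("variant must be 'pooled' or 'welch'")
    p = 2.0 * sps.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def split_plot_anova(pre, post, group) -> list[dict]:
    """Split-plot ANOVA for two groups x two times on per-subject arrays.

    ``group`` holds the two between-subject labels.  Sums of squares use the
    weighted (cell-size) decomposition, which is exact for unbalanced arms:
    the between-subject part splits into group and subject-within-group
    error; the within-subject part (half the squared change scores) splits
    into time, group x time, and time x subject error.  With two time points
    the interaction F equals the squared pooled t on change scores.

    Returns rows with keys effect, ss, df, ms, F, p, partial_eta2.
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    group = np.asarray(group)
    labels = np.unique(group)
    if len(labels) != 2:
        raise ValueError("exactly two groups required")
    n_a = np.array([(group == g).sum() for g in labels])
    if (n_a < 2).any():
        raise InsufficientDataError("need >= 2 subjects per group")
    n = int(n_a.sum())

    m_s = (pre + post) / 2.0  # subject means
    d = post - pre  # change scores
    mu = (pre.sum() + post.sum()) / (2 * n)
    g_means = np.array([m_s[group == g].mean() for g in labels])
    d_means = np.array([d[group == g].mean() for g in labels])
    d_bar = d.mean()

    ss_subj = 2.0 * np.sum((m_s - mu) ** 2)
    ss_group = 2.0 * np.sum(n_a * (g_means - mu) ** 2)
    ss_err_b = ss_subj - ss_group
    ss_time = n * d_bar**2 / 2.0
    ss_int = np.sum(n_a * (d_means - d_bar) ** 2) / 2.0
    ss_err_w = sum(np.sum((d[group == g] - dm) ** 2) for g, dm in zip(labels, d_means)) / 2.0

    df_err = n - 2
    rows = []
    for effect, ss, ss_err in (
        ("group", ss_group, ss_err_b),
        ("time", ss_time, ss_err_w),
        ("group:time", ss_int, ss_err_w),
    ):
        ms, ms_err = ss / 1.0, ss_err / df_err
        F = ms / ms_err if ms_err > 0 else np.inf
        rows.append(
            {
                "effect": effect,
                "ss": float(ss),
                "df": 1,
                "ms": float(ms),
                "F": float(F),
                "p": float(sps.f.sf(F, 1, df_err)) if np.isfinite(F) else 0.0,
                "partial_eta2": float(ss / (ss + ss_err)) if (ss + ss_err) > 0 else 0.0,
            }
        )
    rows.append({"effect": "error_between", "ss": float(ss_err_b), "df": df_err,
                 "ms": float(ss_err_b / df_err), "F": None, "p": None, "partial_eta2": None})
    rows.append({"effect": "error_within", "ss": float(ss_err_w), "df": df_err,
                 "ms": float(ss_err_w / df_err), "F": None, "p": None, "partial_eta2": None})
    return rows


def _prepost(data: TrialDataset, measure: str) -> pd.DataFrame:
    """Per-student pre (week 0) and post (final week) values; listwise complete."""
    wide = data.wide(measure)
    final_week = int(wide.columns.max())
    out = pd.DataFrame(
        {"pre": wide[0], "post": wide[final_week], "arm": data.arm_of()}
    ).dropna(subset=["pre", "post"])
    return out


def mixed_anova(data: TrialDataset, measure: str, variant: str = "mixed") -> list[dict]:
    """Two-way group x time ANOVA on a trial dataset.

    ``variant="mixed"`` (default) is the split-plot analysis appropriate for
    repeated measures on the same students.  ``variant="between"`` treats
    the four group x time cells as independent samples (two-way factorial),
    provided for comparison only.
    """
    pp = _prepost(data, measure)
    if variant == "mixed":
        return split_plot_anova(pp["pre"], pp["post"], pp["arm"])
    if variant != "between":
        raise ValueError("variant must be 'mixed' or 'between'")
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    long = pd.concat(
        [
            pd.DataFrame({"value": pp["pre"], "arm": pp["arm"], "time": "pre"}),
            pd.DataFrame({"value": pp["post"], "arm": pp["arm"], "time": "post"}),
        ]
    )
    model = smf.ols("value ~ C(arm) * C(time)", data=long).fit()
    table = sm.stats.anova_lm(model, typ=2)
    ss_err = float(table.loc["Residual", "sum_sq"])
    rows = []
    for name, effect in (
        ("C(arm)", "group"), ("C(time)", "time"), ("C(arm):C(time)", "group:time"),
    ):
        ss = float(table.loc[name, "sum_sq"])
        rows.append(
            {
                "effect": effect,
                "ss": ss,
                "df": int(table.loc[name, "df"]),
                "ms": ss / float(table.loc[name, "df"]),
                "F": float(table.loc[name, "F"]),
                "p": float(table.loc[name, "PR(>F)"]),
                "partial_eta2": ss / (ss + ss_err),
            }
        )
    rows.append({"effect": "error", "ss": ss_err, "df": int(table.loc["Residual", "df"]),
                 "ms": ss_err / float(table.loc["Residual", "df"]),
                 "F": None, "p": None, "partial_eta2": None})
    return rows


def cohens_d(m1: float, s1: float, n1: int, m2: float, s2: float, n2: int) -> float:
    """Standardized mean difference with pooled SD."""
    if n1 < 2 or n2 < 2:
        raise InsufficientDataError("need n >= 2 per group")
    sp2 = ((n1 - 1) * s1**2 + (n2 - 1) * s2**2) / (n1 + n2 - 2)
    if sp2 == 0:
        raise UndefinedStatisticError("Cohen's d undefined: zero pooled spread")
    return float((m1 - m2) / np.sqrt(sp2))


def cohens_d_change(changes) -> float:
    """Within-group d: mean of per-student change scores over their SD."""
    changes = np.asarray(changes, dtype=float)
    sd = changes.std(ddof=1)
    if not sd > 0:
        raise UndefinedStatisticError("Cohen's d undefined: zero change-score spread")
    return float(changes.mean() / sd)


def cronbach_alpha(item_matrix) -> float:
    """Internal-consistency alpha: (k/(k-1)) * (1 - sum(item var)/var(total))."""
    X = np.asarray(item_matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 2:
        raise InsufficientDataError("need >= 2 students and >= 2 items")
    k = X.shape[1]
    total_var = X.sum(axis=1).var(ddof=1)
    if not total_var > 0:
        raise UndefinedStatisticError("alpha undefined: zero total-score variance")
    return float(k / (k - 1) * (1.0 - X.var(axis=0, ddof=1).sum() / total_var))


def subgroup_gains(
    data: TrialDataset, baseline_threshold: float = 60.0, measure: str = "vocab"
) -> dict:
    """Gains among students whose baseline is below ``baseline_threshold``.

    Percent gains are computed per student (100 * (post - pre)/pre) and
    averaged per arm; the two arms' per-student gains are compared with a
    pooled two-sample t.
    """
    pp = _prepost(data, measure)
    low = pp[pp["pre"] < baseline_threshold].copy()
    counts = low["arm"].value_counts()
    if len(counts) < 2 or counts.min() < 2:
        raise InsufficientDataError(
            f"fewer than 2 low-baseline students in some arm (threshold {baseline_threshold})"
        )
    low["gain_pct"] = 100.0 * (low["post"] - low["pre"]) / low["pre"]
    arm_gain = {
        arm: round(float(g["gain_pct"].mean()), 1) for arm, g in low.groupby("arm")
    }
    ge = low.loc[low["arm"] == "experimental", "gain_pct"]
    gc = low.loc[low["arm"] == "control", "gain_pct"]
    t, df, p = two_sample_t(
        ge.mean(), ge.std(ddof=1), len(ge), gc.mean(), gc.std(ddof=1), len(gc)
    )
    return {
        "threshold": baseline_threshold,
        "gain_pct": arm_gain,
        "n": {arm: int(c) for arm, c in counts.items()},
        "t": t, "df": df, "p": p,
    }


_LMM_NOTE = (
    "A linear mixed model with a random intercept for class is not estimated: "
    "the design carries only one intact class per arm, so the class random "
    "effect is confounded with the group effect and its variance is not "
    "identifiable from two clusters. The split-plot ANOVA above is the "
    "primary inferential analysis."
)


def compute_stats_report(
    data: TrialDataset,
    cleaning_log: CleaningLog | None = None,
    t_variant: str = "pooled",
    anova_variant: str = "mixed",
) -> dict:
    """Full descriptive + inferential report mirroring the published tables.

    Per measure: pre/post mean (SD) per arm, percent change per arm,
    between-group t at pre and post, the ANOVA table, and Cohen's d
    (between-group at post; within-group on change scores per arm).  A
    low-baseline subgroup analysis is attached for the vocabulary measure.
    Cronbach's alpha needs item-level responses, which scale-score datasets
    do not carry; the report notes this rather than inventing items.
    """
    report: dict = {"measures": {}, "notes": {"lmm": _LMM_NOTE}}
    if cleaning_log is not None:
        report["cleaning"] = cleaning_log.to_dict()
    for measure in ANALYSIS_MEASURES:
        pp = _prepost(data, measure)
        block: dict = {"descriptives": {}, "percent_change": {}}
        summaries = {}
        for arm, g in pp.groupby("arm"):
            desc = {
                "n": len(g),
                "pre_mean": float(g["pre"].mean()), "pre_sd": float(g["pre"].std(ddof=1)),
                "post_mean": float(g["post"].mean()), "post_sd": float(g["post"].std(ddof=1)),
            }
            block["descriptives"][arm] = desc
            block["percent_change"][arm] = percent_change(desc["pre_mean"], desc["post_mean"])
            summaries[arm] = desc
        e, c = summaries["experimental"], summaries["control"]
        for when in ("pre", "post"):
            t, df, p = two_sample_t(
                e[f"{when}_mean"], e[f"{when}_sd"], e["n"],
                c[f"{when}_mean"], c[f"{when}_sd"], c["n"], variant=t_variant,
            )
            block[f"t_{when}"] = {"t": t, "df": df, "p": p}
        block["anova"] = mixed_anova(data, measure, variant=anova_variant)
        block["cohens_d_between_post"] = cohens_d(
            e["post_mean"], e["post_sd"], e["n"], c["post_mean"], c["post_sd"], c["n"]
        )
        block["cohens_d_change"] = {
            arm: cohens_d_change(g["post"] - g["pre"]) for arm, g in pp.groupby("arm")
        }
        report["measures"][measure] = block
    try:
        report["subgroup_vocab"] = subgroup_gains(data)
    except InsufficientDataError as exc:
        report["subgroup_vocab"] = {"error": str(exc)}
    report["notes"]["cronbach_alpha"] = (
        "Alpha requires item-level responses; this dataset carries scale "
        "scores only, so no alpha is computed."
    )
    return report


def discrepancy_report() -> dict:
    """Recompute printed inferential statistics from printed summaries.

    For each published inferential number that standard formulas can reach
    from the published summary tables (pooled t, percent change, Cohen's d),
    recompute it and flag whether the published value matches at its printed
    precision.  This documents which published statistics are internally
    consistent; the mismatches are reported, not reconciled.
    """
    n = published.N_PER_ARM
    out: dict = {"consistent": {}, "discrepant": {}}

    for measure, (t_rep, p_rep) in published.BASELINE_T.items():
        (me, se), (mc, sc) = (
            published.BASELINE[measure]["experimental"],
            published.BASELINE[measure]["control"],
        )
        t, _, p = two_sample_t(me, se, n, mc, sc, n)
        entry = {
            "reported": {"t": t_rep, "p": p_rep},
            "recomputed": {"t": round(t, 2), "p": round(p, 2)},
        }
        bucket = "consistent" if round(t, 2) == t_rep else "discrepant"
        out[bucket][f"baseline_t_{measure}"] = entry

    for measure, t_rep in published.POST_T.items():
        (me, se), (mc, sc) = (
            published.POST[measure]["experimental"],
            published.POST[measure]["control"],
        )
        t, _, _ = two_sample_t(me, se, n, mc, sc, n)
        entry = {"reported": {"t": t_rep}, "recomputed": {"t": round(t, 2)}}
        bucket = "consistent" if round(t, 2) == t_rep else "discrepant"
        out[bucket][f"post_t_{measure}"] = entry

    for arm, pct_rep in published.PERCENT_CHANGE.items():
        pre = published.BASELINE["vocab"][arm][0]
        post = published.POST["vocab"][arm][0]
        pct = percent_change(pre, post)
        bucket = "consistent" if pct == pct_rep else "discrepant"
        out[bucket][f"percent_change_{arm}"] = {"reported": pct_rep, "recomputed": pct}

    for arm, d_rep in published.COHENS_D_CHANGE.items():
        pre_m, pre_sd = published.BASELINE["vocab"][arm]
        post_m, post_sd = published.POST["vocab"][arm]
        # pooled-SD standardization of the pre->post difference; the
        # change-score SD is unpublished so this is the only summary route
        d = cohens_d(post_m, post_sd, n, pre_m, pre_sd, n)
        entry = {"reported": d_rep, "recomputed_pooled": round(d, 2)}
        bucket = "consistent" if round(d, 2) == d_rep else "discrepant"
        out[bucket][f"cohens_d_change_{arm}"] = entry

    return out
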