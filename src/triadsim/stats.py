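"""Group-comparison statistics for the paradigm's analysis pipeline.

Implements the tests the paradigm's read-outs are analysed with: extreme-
outlier exclusion by the 3 x IQR rule, chi-square tests of independence
(Yates-corrected for 2 x 2 tables), Student two-sample t-tests with Cohen's
d, one-way ANOVA with partial eta squared (computable from raw data or from
printed group summaries), Kruskal-Wallis with the eta-squared-H effect size,
two-way mixed repeated-measures ANOVA with Greenhouse-Geisser correction,
and Holm and family-wise Bonferroni p-value adjustment.

Cohen's d uses the average-variance denominator
``sqrt((s1^2 + s2^2)/2)`` (equal to the pooled SD for equal group sizes),
which is the convention of the R routines this pipeline mirrors; the t
statistic itself is the Student pooled-variance form with n1 + n2 - 2
degrees of freedom.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GroupSummary",
    "StatResult",
    "extreme_outlier_mask",
    "chi_square_independence",
    "t_test_two_sample",
    "anova_oneway",
    "kruskal_wallis",
    "mixed_rm_anova",
    "gg_epsilon",
    "holm_adjust",
    "bonferroni_family",
    "analysis_report",
]


@dataclass(frozen=True)
class GroupSummary:
    """Printed per-group summary: label, n, mean, sd."""

    label: str
    n: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("group n must be >= 2")
        if self.sd < 0:
            raise ValueError("sd must be >= 0")


@dataclass(frozen=True)
class StatResult:
    """A named test statistic with df, p, effect size, and correction."""

    test: str
    statistic: float
    df: tuple  # one or two entries
    p: float
    effect_kind: str  # partial_eta2 | eta2_H | cohen_d | X2_none
    effect: float | None
    epsilon_gg: float | None = None
    correction: str = "none"
    label: str = ""


# ---------------------------------------------------------------------------
# outlier rule
# ---------------------------------------------------------------------------

def extreme_outlier_mask(values) -> np.ndarray:
    """Inclusion mask for the extreme-outlier rule: keep values inside
    ``[Q1 - 3*IQR, Q3 + 3*IQR]`` with type-7 (linear interpolation)
    quartiles.  NaNs are excluded from the fences and masked out."""
    values = np.asarray(values, dtype=float)
    finite = values[np.isfinite(values)]
    if finite.size < 4:
        raise ValueError("need at least 4 finite values for the outlier rule")
    q1, q3 = np.percentile(finite, [25, 75], method="linear")
    iqr = q3 - q1
    lo, hi = q1 - 3 * iqr, q3 + 3 * iqr
    return np.isfinite(values) & (values >= lo) & (values <= hi)


# ---------------------------------------------------------------------------
# chi-square
# ---------------------------------------------------------------------------

def chi_square_independence(table, continuity: bool | None = None) -> StatResult:
    """Pearson chi-square test of independence on a counts matrix.

    Yates continuity correction defaults to on for 2 x 2 tables and off
    otherwise (the convention of ``chisq.test`` in R).
    """
    table = np.asarray(table, dtype=float)
    if table.ndim != 2 or min(table.shape) < 2:
        raise ValueError("table must be at least 2 x 2")
    if np.any(table < 0):
        raise ValueError("counts must be non-negative")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("table has a zero marginal")
    if continuity is None:
        continuity = table.shape == (2, 2)
    stat, p, dof, _ = sps.chi2_contingency(table, correction=continuity)
    return StatResult(
        test="chi_square",
        statistic=float(stat),
        df=(dof,),
        p=float(p),
        effect_kind="X2_none",
        effect=None,
        correction="yates" if continuity else "none",
    )


# ---------------------------------------------------------------------------
# t-test (raw data or printed summaries)
# ---------------------------------------------------------------------------

def _as_summaries(groups) -> list[GroupSummary]:
    out = []
    for i, g in enumerate(groups):
        if isinstance(g, GroupSummary):
            out.append(g)
        else:
            arr = np.asarray(g, dtype=float)
            if arr.size < 2:
                raise ValueError("each group needs n >= 2")
            out.append(
                GroupSummary(
                    label=f"g{i + 1}", n=int(arr.size),
                    mean=float(arr.mean()), sd=float(arr.std(ddof=1)),
                )
            )
    return out


def t_test_two_sample(groups) -> StatResult:
    """Student (pooled-variance) independent-samples t-test with Cohen's d.

    ``groups`` is a pair of raw arrays, a pair of :class:`GroupSummary`, or a
    mix; both paths give identical results when the raw data match the
    summaries.
    """
    g1, g2 = _as_summaries(groups)
    n1, n2 = g1.n, g2.n
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * g1.sd**2 + (n2 - 1) * g2.sd**2) / df
    diff = g1.mean - g2.mean
    d_denom = math.sqrt((g1.sd**2 + g2.sd**2) / 2)
    if sp2 == 0:
        if diff == 0:
            return StatResult("t_test", 0.0, (df,), 1.0, "cohen_d", 0.0)
        return StatResult("t_test", math.inf, (df,), 0.0, "cohen_d", math.inf)
    t = diff / math.sqrt(sp2 * (1 / n1 + 1 / n2))
    p = 2 * sps.t.sf(abs(t), df)
    d = diff / d_denom
    return StatResult(
        test="t_test", statistic=float(t), df=(df,), p=float(p),
        effect_kind="cohen_d", effect=float(d),
    )


# ---------------------------------------------------------------------------
# one-way ANOVA (raw data or printed summaries)
# ---------------------------------------------------------------------------

def anova_oneway(groups) -> StatResult:
    """One-way between-subjects ANOVA with partial eta squared; the sums of
    squares are recovered exactly from per-group (n, mean, sd)."""
    summaries = _as_summaries(groups)
    if len(summaries) < 2:
        raise ValueError("need at least two groups")
    k = len(summaries)
    N = sum(g.n for g in summaries)
    grand = sum(g.n * g.mean for g in summaries) / N
    ssb = sum(g.n * (g.mean - grand) ** 2 for g in summaries)
    ssw = sum((g.n - 1) * g.sd**2 for g in summaries)
    df1, df2 = k - 1, N - k
    if ssw == 0:
        f = 0.0 if ssb == 0 else math.inf
        p = 1.0 if ssb == 0 else 0.0
    else:
        f = (ssb / df1) / (ssw / df2)
        p = float(sps.f.sf(f, df1, df2))
    eta = ssb / (ssb + ssw) if (ssb + ssw) > 0 else 0.0
    return StatResult(
        test="anova_oneway", statistic=float(f), df=(df1, df2), p=p,
        effect_kind="partial_eta2", effect=float(eta),
    )


# ---------------------------------------------------------------------------
# Kruskal-Wallis
# ---------------------------------------------------------------------------

def kruskal_wallis(groups) -> StatResult:
    """Kruskal-Wallis H (tie-corrected) with the eta-squared-H effect size
    ``(H - k + 1) / (N - k)`` (can be negative for tiny H; reported as-is)."""
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("need at least two groups")
    k = len(arrays)
    N = sum(a.size for a in arrays)
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        h, p = 0.0, 1.0
    else:
        h, p = sps.kruskal(*arrays)
    eta_h = (h - k + 1) / (N - k)
    return StatResult(
        test="kruskal_wallis", statistic=float(h), df=(k - 1,), p=float(p),
        effect_kind="eta2_H", effect=float(eta_h),
    )


# ---------------------------------------------------------------------------
# mixed repeated-measures ANOVA
# ---------------------------------------------------------------------------

def gg_epsilon(cov: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon from a within-subject covariance matrix."""
    cov = np.asarray(cov, dtype=float)
    k = cov.shape[0]
    if k < 2:
        raise ValueError("need at least two within-subject levels")
    row = cov.mean(axis=0, keepdims=True)
    col = cov.mean(axis=1, keepdims=True)
    grand = cov.mean()
    dc = cov - row - col + grand  # double-centred
    num = np.trace(dc) ** 2
    den = (k - 1) * np.sum(dc**2)
    if den == 0:
        return 1.0
    return float(np.clip(num / den, 1.0 / (k - 1), 1.0))


def mixed_rm_anova(
    data: pd.DataFrame,
    subject: str,
    between: str,
    within: str,
    value: str,
    gg_correct: bool = True,
) -> dict:
    """Two-way mixed ANOVA: one between-subjects factor, one within-subjects
    factor; unequal group sizes supported.

    Subjects missing any within-level (or with a non-finite value) are
    dropped listwise; the dropped count is returned.  With more than two
    within-levels, Greenhouse-Geisser correction is applied to the within
    and interaction tests (epsilon from the pooled within-group covariance);
    with two levels sphericity holds trivially and epsilon is exactly 1.

    Returns a dict with keys ``between``, ``within``, ``interaction``
    (each a :class:`StatResult`), ``n_dropped`` and ``n_used``.
    """
    df = data[[subject, between, within, value]].copy()
    levels = sorted(df[within].unique())
    b = len(levels)
    if b < 2:
        raise ValueError("within factor needs at least two levels")

    # listwise deletion: a subject must have one finite value per level
    wide = df.pivot_table(
        index=subject, columns=within, values=value, aggfunc="mean", dropna=False
    )
    n_total = df[subject].nunique()
    wide = wide.dropna()
    wide = wide[np.isfinite(wide).all(axis=1)]
    n_used = wide.shape[0]
    n_dropped = n_total - n_used
    if n_used < 3:
        raise ValueError("too few complete subjects for the mixed ANOVA")

    group_of = df.groupby(subject)[between].first()
    groups = group_of.loc[wide.index].to_numpy()
    group_labels = sorted(set(groups))
    a = len(group_labels)
    if a < 2:
        raise ValueError("between factor needs at least two levels")
    Y = wide.to_numpy()  # subjects x levels
    N = Y.shape[0]

    grand = Y.mean()
    subj_means = Y.mean(axis=1)
    level_means = Y.mean(axis=0)

    ss_total_between_subj = b * np.sum((subj_means - grand) ** 2)
    ss_within_subj = np.sum((Y - subj_means[:, None]) ** 2)

    n_g = np.array([np.sum(groups == g) for g in group_labels])
    group_means = np.array([Y[groups == g].mean() for g in group_labels])
    ss_group = b * np.sum(n_g * (group_means - grand) ** 2)
    ss_err_between = ss_total_between_subj - ss_group

    ss_time = N * np.sum((level_means - grand) ** 2)
    cell_means = np.array([Y[groups == g].mean(axis=0) for g in group_labels])
    ss_inter = float(
        np.sum(
            n_g[:, None]
            * (cell_means - group_means[:, None] - level_means[None, :] + grand) ** 2
        )
    )
    ss_err_within = ss_within_subj - ss_time - ss_inter

    df_group, df_err_b = a - 1, N - a
    df_time, df_inter = b - 1, (a - 1) * (b - 1)
    df_err_w = (N - a) * (b - 1)

    ms_err_b = ss_err_between / df_err_b
    ms_err_w = ss_err_within / df_err_w

    def _f(ss, df1, ms_err):
        return (ss / df1) / ms_err if ms_err > 0 else (0.0 if ss == 0 else math.inf)

    f_group = _f(ss_group, df_group, ms_err_b)
    f_time = _f(ss_time, df_time, ms_err_w)
    f_inter = _f(ss_inter, df_inter, ms_err_w)

    eps = 1.0
    if b > 2 and gg_correct:
        # pooled within-group covariance of the level scores
        pooled = np.zeros((b, b))
        for g in group_labels:
            sub = Y[groups == g]
            if sub.shape[0] > 1:
                pooled += (sub.shape[0] - 1) * np.cov(sub, rowvar=False)
        pooled /= (N - a)
        eps = gg_epsilon(pooled)

    p_group = float(sps.f.sf(f_group, df_group, df_err_b)) if np.isfinite(f_group) else 0.0
    p_time = float(sps.f.sf(f_time, eps * df_time, eps * df_err_w)) if np.isfinite(f_time) else 0.0
    p_inter = float(sps.f.sf(f_inter, eps * df_inter, eps * df_err_w)) if np.isfinite(f_inter) else 0.0

    def _eta(ss, ss_err):
        tot = ss + ss_err
        return float(ss / tot) if tot > 0 else 0.0

    results = {
        "between": StatResult(
            "rm_anova", float(f_group), (df_group, df_err_b), p_group,
            "partial_eta2", _eta(ss_group, ss_err_between), None, "none", between,
        ),
        "within": StatResult(
            "rm_anova", float(f_time), (df_time, df_err_w), p_time,
            "partial_eta2", _eta(ss_time, ss_err_within),
            eps if b > 2 else None, "gg" if (b > 2 and gg_correct) else "none", within,
        ),
        "interaction": StatResult(
            "rm_anova", float(f_inter), (df_inter, df_err_w), p_inter,
            "partial_eta2", _eta(ss_inter, ss_err_within),
            eps if b > 2 else None, "gg" if (b > 2 and gg_correct) else "none",
            f"{between} x {within}",
        ),
        "n_dropped": n_dropped,
        "n_used": n_used,
    }
    return results


# ---------------------------------------------------------------------------
# multiplicity control
# ---------------------------------------------------------------------------

def holm_adjust(p_values) -> np.ndarray:
    """Step-down Holm adjustment with monotonicity enforcement."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p values must be in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(m)
    running_max = 0.0
    for rank, idx in enumerate(order):
        candidate = min(1.0, (m - rank) * p[idx])
        running_max = max(running_max, candidate)
        adjusted[idx] = running_max
    return adjusted


def bonferroni_family(p_values, m: int) -> np.ndarray:
    """Family-wise Bonferroni: ``min(1, p * m)`` for a declared family size
    ``m`` (which must cover at least the tests supplied)."""
    p = np.asarray(p_values, dtype=float)
    if m < p.size:
        raise ValueError(f"family size m={m} smaller than number of tests {p.size}")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p values must be in [0, 1]")
    return np.minimum(1.0, p * m)


# ---------------------------------------------------------------------------
# full analysis report
# ---------------------------------------------------------------------------

def _mask_extreme(frame: pd.DataFrame, column: str, by=None) -> pd.DataFrame:
    """Blank (NaN) values failing the extreme-outlier rule for ``column``.

    Fences are computed within each group defined by ``by`` (the box-plot
    convention: one box per design cell); in the mixed ANOVAs the affected
    subjects then drop out listwise, which is how the exclusion enters the
    repeated-measures analyses."""
    frame = frame.copy()

    def blank(sub: pd.Series) -> pd.Series:
        values = sub.to_numpy(dtype=float)
        if np.isfinite(values).sum() >= 4:
            return sub.where(extreme_outlier_mask(values))
        return sub

    if by:
        frame[column] = frame.groupby(by, group_keys=False)[column].apply(blank)
    else:
        frame[column] = blank(frame[column])
    return frame


def _empty_mixed_result() -> dict:
    nan_res = StatResult("rm_anova", math.nan, (math.nan, math.nan), math.nan,
                         "partial_eta2", math.nan)
    return {"between": nan_res, "within": nan_res, "interaction": nan_res,
            "n_dropped": 0, "n_used": 0}


def _result_row(res: StatResult, **extra) -> dict:
    row = {
        "test": res.test,
        "statistic": res.statistic,
        "df1": res.df[0],
        "df2": res.df[1] if len(res.df) > 1 else math.nan,
        "p_raw": res.p,
        "effect_kind": res.effect_kind,
        "effect": res.effect,
        "epsilon_gg": res.epsilon_gg,
        "correction": res.correction,
    }
    row.update(extra)
    return row


def analysis_report(
    participant_df: pd.DataFrame,
    block_df: pd.DataFrame,
    study_id: int = 2,
) -> pd.DataFrame:
    """Assemble the full group-comparison report for a simulated experiment.

    Families (family-wise Bonferroni within each):

    * ``acute`` -- ratings and RT under acute stress (helplessness,
      exhaustion, [frustration in the original variant], mean RT);
    * ``affect`` -- pre/post questionnaire totals (combined
      anxiety-depression, positive affect, negative affect), group x time
      mixed ANOVAs;
    * ``escape`` -- escape-test indices (exploration, escapes, efficiency);
      in the two-block variant these are group x block mixed ANOVAs.

    Manipulation-check rows (aversiveness, perceived control) are reported
    uncorrected.  Extreme outliers (3 x IQR rule) are excluded per variable;
    each row carries the exclusion count.  Deterministic given the inputs.
    """
    conditions = sorted(participant_df["condition"].unique())
    rows: list[dict] = []

    def groups_of(column: str, frame: pd.DataFrame, cond=None):
        values = frame[column].to_numpy(dtype=float)
        if np.isfinite(values).sum() >= 4:
            keep = extreme_outlier_mask(values)
        else:
            keep = np.isfinite(values)
        kept = frame[keep]
        return (
            [kept.loc[kept["condition"] == c, column].to_numpy(dtype=float)
             for c in (cond or conditions)],
            int((~keep).sum()),
        )

    def compare_groups(column: str, family: str, label: str,
                       frame: pd.DataFrame | None = None):
        frame = participant_df if frame is None else frame
        cond = sorted(frame["condition"].unique())
        data, n_excluded = groups_of(column, frame.dropna(subset=[column]), cond)
        if any(len(g) < 2 for g in data):
            # a design cell too small to test (tiny demo runs): report the
            # row with missing statistics rather than failing the report
            res = StatResult("t_test" if len(cond) == 2 else "anova_oneway",
                             math.nan, (math.nan,), math.nan, "none", math.nan)
        elif len(cond) == 2:
            res = t_test_two_sample(data)
        elif column.startswith("rating_"):
            # Likert means are ordinal-ish; rank-based test for 3+ groups
            res = kruskal_wallis(data)
        else:
            res = anova_oneway(data)
        rows.append(
            _result_row(res, family=family, variable=label, effect_name="group",
                        n_excluded=n_excluded,
                        n_used=int(sum(len(g) for g in data)))
        )

    # manipulation checks: only stress-exposed groups can rate the stressor
    if "rating_aversiveness" in participant_df:
        stress_only = participant_df[participant_df["condition"] != "CC"]
        compare_groups("rating_aversiveness", "manipulation", "aversiveness",
                       frame=stress_only)
    if "rating_control" in participant_df:
        compare_groups("rating_control", "manipulation", "perceived_control")

    # acute-phase family
    acute_vars = [("rating_helplessness", "helplessness"),
                  ("rating_exhaustion", "exhaustion")]
    if "rating_frustration" in participant_df and study_id == 1:
        acute_vars.append(("rating_frustration", "frustration"))
    acute_vars.append(("mean_rt", "mean_rt"))
    start = len(rows)
    for column, label in acute_vars:
        compare_groups(column, "acute", label)
    _apply_family(rows, start, len(rows))

    # affect family: group x time mixed ANOVAs on pre/post totals
    start = len(rows)
    for score, label in (("stadi_total", "anxiety_depression"),
                         ("panas_pos", "positive_affect"),
                         ("panas_neg", "negative_affect")):
        pre, post = f"{score}_pre", f"{score}_post"
        if pre not in participant_df:
            continue
        long = participant_df.melt(
            id_vars=["participant_id", "condition"],
            value_vars=[pre, post], var_name="time", value_name="score",
        )
        long["time"] = long["time"].str.endswith("_post").map({False: "pre", True: "post"})
        long = _mask_extreme(long, "score", by=["condition", "time"])
        try:
            res = mixed_rm_anova(long, "participant_id", "condition", "time", "score")
        except ValueError:
            res = _empty_mixed_result()
        for effect_name in ("between", "within", "interaction"):
            rows.append(
                _result_row(res[effect_name], family="affect", variable=label,
                            effect_name=effect_name, n_excluded=res["n_dropped"],
                            n_used=res["n_used"])
            )
    _apply_family(rows, start, len(rows))

    # escape-test family
    start = len(rows)
    multi_block = block_df["block"].nunique() > 1
    for column in ("exploration_per_min", "escapes", "efficiency"):
        if multi_block:
            masked = _mask_extreme(
                block_df[["participant_id", "condition", "block", column]], column,
                by=["condition", "block"],
            )
            try:
                res = mixed_rm_anova(
                    masked, "participant_id", "condition", "block", column
                )
            except ValueError:
                res = _empty_mixed_result()
            for effect_name in ("between", "within", "interaction"):
                rows.append(
                    _result_row(res[effect_name], family="escape", variable=column,
                                effect_name=effect_name, n_excluded=res["n_dropped"],
                                n_used=res["n_used"])
                )
        else:
            frame = block_df.dropna(subset=[column])
            data, n_excluded = groups_of(column, frame)
            res = anova_oneway(data)
            rows.append(
                _result_row(res, family="escape", variable=column,
                            effect_name="group", n_excluded=n_excluded,
                            n_used=int(sum(len(g) for g in data)))
            )
    _apply_family(rows, start, len(rows))

    report = pd.DataFrame(rows)
    report["p_adj"] = report["p_adj"].fillna(report["p_raw"])
    return report


def _apply_family(rows: list[dict], start: int, end: int) -> None:
    """Family-wise Bonferroni over the distinct variables of a family; every
    effect row of a variable inherits the family size."""
    variables = {rows[i]["variable"] for i in range(start, end)}
    m = len(variables)
    for i in range(start, end):
        rows[i]["family_size"] = m
        rows[i]["p_adj"] = float(min(1.0, rows[i]["p_raw"] * m))
    # rows outside any family keep raw p
    for row in rows:
        row.setdefault("family_size", 1)
        row.setdefault("p_adj", None)
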