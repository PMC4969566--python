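"""Cohort aggregation and repeated-measures state comparisons.

Per-segment summaries are stacked into a long-format cohort table keyed by
(subject, state, segment, delta_t, metric). Pairs of consciousness states
are compared with a repeated-measures ANOVA: a two-way fixed-effects
decomposition with state as the grouping factor, subject as the repeated
blocking factor, and segments as replicates, using sequential (Type-I)
sums of squares with state entered first. Families of comparisons are
Bonferroni-corrected.

The printed F statistics depend on which segments enter the table; with
unbalanced designs (subjects missing a state) the sequential decomposition
on observed cells is used and the imbalance is logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm

from .errors import DegenerateDataError, InputError, ParameterError

log = logging.getLogger(__name__)

METRICS = ("kappa_avg", "low_it_fraction", "significant_power")

_COHORT_COLUMNS = [
    "subject_id",
    "state",
    "segment_id",
    "delta_t_s",
    "metric_name",
    "metric_value",
]


@dataclass(frozen=True)
class AnovaResult:
    f_stat: float
    df_num: int
    df_den: int
    p_raw: float
    p_adjusted: float | None
    state_a: str
    state_b: str
    delta_t_s: float
    metric: str


@dataclass(frozen=True)
class ComparisonReport:
    """Grid of pairwise ANOVA results plus per-state descriptive stats."""

    results: pd.DataFrame  # one row per (state pair, delta_t, metric)
    group_stats: pd.DataFrame  # mean/sd/n per (state, delta_t, metric)


class CohortTable:
    """Long-format per-segment metric table feeding the group statistics."""

    def __init__(self, frame: pd.DataFrame):
        missing = [c for c in _COHORT_COLUMNS if c not in frame.columns]
        if missing:
            raise InputError(f"cohort table missing columns: {missing}")
        frame = frame[_COHORT_COLUMNS].copy()
        keys = frame[_COHORT_COLUMNS[:5]]
        if keys.duplicated().any():
            dup = keys[keys.duplicated()].iloc[0].tolist()
            raise InputError(f"duplicate cohort key: {dup}")
        if frame.empty:
            raise InputError("empty cohort table")
        self.frame = frame

    @classmethod
    def from_summary_frame(
        cls, summary: pd.DataFrame, metrics: tuple[str, ...] | None = None
    ) -> "CohortTable":
        """Melt a wide per-segment summary table into long metric rows."""
        if metrics is None:
            metrics = tuple(m for m in METRICS if m in summary.columns)
        if not metrics:
            raise InputError("summary table holds none of the known metrics")
        long = summary.melt(
            id_vars=["subject_id", "state", "segment_id", "delta_t_s"],
            value_vars=list(metrics),
            var_name="metric_name",
            value_name="metric_value",
        ).dropna(subset=["metric_value"])
        return cls(long)

    @classmethod
    def read_tsv(cls, path, metrics: tuple[str, ...] | None = None) -> "CohortTable":
        try:
            df = pd.read_csv(path, sep="\t")
        except Exception as exc:
            raise InputError(f"cannot read cohort table {path}: {exc}") from exc
        if "metric_name" in df.columns:
            return cls(df)
        return cls.from_summary_frame(df, metrics)

    def states(self) -> list[str]:
        return sorted(self.frame["state"].unique())

    def delta_ts(self) -> list[float]:
        return sorted(self.frame["delta_t_s"].unique())

    def metrics(self) -> list[str]:
        return sorted(self.frame["metric_name"].unique())

    def subset(self, states, delta_t_s: float, metric: str) -> pd.DataFrame:
        f = self.frame
        return f[
            f["state"].isin(states)
            & np.isclose(f["delta_t_s"], delta_t_s)
            & (f["metric_name"] == metric)
        ]


def _sanitize_f(ss_state: float, ss_error: float, f: float, p: float):
    total = ss_state + ss_error
    if total <= 0 or ss_state <= 1e-12 * max(total, 1e-300):
        return 0.0, 1.0
    if ss_error <= 1e-12 * total:
        return float("inf"), 0.0
    return float(f), float(p)


def rm_anova(
    table: CohortTable,
    state_a: str,
    state_b: str,
    delta_t_s: float,
    metric: str,
) -> AnovaResult:
    """Repeated-measures comparison of one metric between two states.

    Fits metric ~ state + subject on segment-level values by sequential
    Type-I sums of squares (state first); F = MS_state / MS_error with
    df = (1, N - 1 - 1 - (n_subjects - 1)).
    """
    sub = table.subset([state_a, state_b], delta_t_s, metric)
    for st in (state_a, state_b):
        if not (sub["state"] == st).any():
            raise DegenerateDataError(
                f"state {st!r} has no data for metric {metric!r} at "
                f"delta_t = {delta_t_s} s"
            )
    in_both = (
        sub.groupby("subject_id")["state"].nunique().pipe(lambda s: s[s == 2]).index
    )
    if len(in_both) < 2:
        raise DegenerateDataError(
            "repeated-measures comparison needs >= 2 subjects present in both states"
        )
    only_one = sorted(set(sub["subject_id"]) - set(in_both))
    if only_one:
        log.warning(
            "unbalanced design: subjects %s appear in only one of (%s, %s); "
            "retained under sequential SS on observed cells",
            only_one,
            state_a,
            state_b,
        )
    df = sub.rename(columns={"metric_value": "y"})
    fit = smf.ols("y ~ C(state) + C(subject_id)", data=df).fit()
    tab = anova_lm(fit, typ=1)
    ss_state = float(tab.loc["C(state)", "sum_sq"])
    ss_error = float(tab.loc["Residual", "sum_sq"])
    df_den = int(tab.loc["Residual", "df"])
    if df_den < 1:
        raise DegenerateDataError("no residual degrees of freedom")
    f, p = _sanitize_f(
        ss_state, ss_error, tab.loc["C(state)", "F"], tab.loc["C(state)", "PR(>F)"]
    )
    return AnovaResult(
        f_stat=f,
        df_num=1,
        df_den=df_den,
        p_raw=p,
        p_adjusted=None,
        state_a=state_a,
        state_b=state_b,
        delta_t_s=float(delta_t_s),
        metric=metric,
    )


def bonferroni(results: list[AnovaResult], m: int | str = "auto") -> list[AnovaResult]:
    """p_adjusted = min(1, m * p_raw); ``m='auto'`` uses the family size."""
    if m == "auto":
        m = len(results)
    m = int(m)
    if m < 1:
        raise ParameterError(f"Bonferroni m must be >= 1, got {m}")
    return [replace(r, p_adjusted=min(1.0, m * r.p_raw)) for r in results]


def group_statistics(table: CohortTable) -> pd.DataFrame:
    """Mean, SD and n of every metric per (state, delta_t)."""
    g = (
        table.frame.groupby(["state", "delta_t_s", "metric_name"])["metric_value"]
        .agg(mean="mean", sd="std", n="size")
        .reset_index()
    )
    return g


def compare_all(
    table: CohortTable,
    baseline_state: str,
    other_states: list[str] | None = None,
    delta_ts: list[float] | None = None,
    metrics: list[str] | None = None,
    bonferroni_m: int | str = "auto",
) -> ComparisonReport:
    """Baseline-vs-each-state ANOVA grid with per-family Bonferroni.

    The correction family is one (state pair, metric) across all time
    scales, so ``bonferroni_m='auto'`` gives m = len(delta_ts). Cells whose
    ANOVA fails (missing state, too few shared subjects) are kept as NaN
    rows and logged; the remaining cells are still computed.
    """
    if baseline_state not in table.states():
        raise DegenerateDataError(f"baseline state {baseline_state!r} has no data")
    if other_states is None:
        other_states = [s for s in table.states() if s != baseline_state]
    if delta_ts is None:
        delta_ts = table.delta_ts()
    if metrics is None:
        metrics = table.metrics()

    stats = group_statistics(table)

    def _ms(state, dt, metric):
        row = stats[
            (stats["state"] == state)
            & np.isclose(stats["delta_t_s"], dt)
            & (stats["metric_name"] == metric)
        ]
        if row.empty:
            return np.nan, np.nan
        return float(row["mean"].iloc[0]), float(row["sd"].iloc[0])

    rows = []
    for other in other_states:
        for metric in metrics:
            family: list[AnovaResult | None] = []
            for dt in delta_ts:
                try:
                    family.append(rm_anova(table, baseline_state, other, dt, metric))
                except (DegenerateDataError, InputError) as exc:
                    log.warning(
                        "skipping cell (%s vs %s, dt=%s, %s): %s",
                        baseline_state,
                        other,
                        dt,
                        metric,
                        exc,
                    )
                    family.append(None)
            done = [r for r in family if r is not None]
            corrected = iter(bonferroni(done, bonferroni_m)) if done else iter(())
            for dt, r in zip(delta_ts, family):
                mean_a, sd_a = _ms(baseline_state, dt, metric)
                mean_b, sd_b = _ms(other, dt, metric)
                if r is None:
                    rec = dict(F=np.nan, df_num=np.nan, df_den=np.nan,
                               p_raw=np.nan, p_adjusted=np.nan)
                else:
                    c = next(corrected)
                    rec = dict(F=c.f_stat, df_num=c.df_num, df_den=c.df_den,
                               p_raw=c.p_raw, p_adjusted=c.p_adjusted)
                rows.append(
                    {
                        "comparison": f"{baseline_state} vs {other}",
                        "delta_t_s": dt,
                        "metric": metric,
                        "mean_a": mean_a,
                        "sd_a": sd_a,
                        "mean_b": mean_b,
                        "sd_b": sd_b,
                        **rec,
                    }
                )
    results = pd.DataFrame(
        rows,
        columns=[
            "comparison", "delta_t_s", "metric", "mean_a", "sd_a",
            "mean_b", "sd_b", "F", "df_num", "df_den", "p_raw", "p_adjusted",
        ],
    )
    return ComparisonReport(results=results, group_stats=stats)
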