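"""Survival estimation and group statistics, implemented from first principles.

Kaplan-Meier product-limit curves and the two-sample log-rank test operate
on per-cell ``(group, time, event)`` records produced by the fate
classifier; one-/two-way ANOVA (type-II sums of squares) with Tukey HSD
post-hoc comparisons serve the foci and uptake summaries.  Only the point
estimate and counts are promised for KM curves — no confidence bands.

Tie convention: at equal times, deaths are processed before censorings.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SurvivalRecord",
    "KMCurve",
    "LogRankResult",
    "records_to_dataframe",
    "km_estimate",
    "logrank_test",
    "pairwise_logrank",
    "anova_tukey",
    "AnovaTukeyResult",
]


@dataclass
class SurvivalRecord:
    """One cell's outcome: event=1 is death, event=0 censoring."""

    cell_id: int
    group: str
    time_h: float
    event: int
    death_mode: str = "none"

    def __post_init__(self) -> None:
        if self.time_h < 0:
            raise ValueError("time_h must be nonnegative")
        if self.event not in (0, 1):
            raise ValueError("event must be 0 or 1")


def records_to_dataframe(records: list[SurvivalRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "cell_id": r.cell_id,
                "group": r.group,
                "time_h": r.time_h,
                "event": r.event,
                "death_mode": r.death_mode,
            }
            for r in records
        ],
        columns=["cell_id", "group", "time_h", "event", "death_mode"],
    )


def _coerce(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        df = records
    else:
        df = records_to_dataframe(list(records))
    if df.empty:
        return df
    if (df["time_h"] < 0).any():
        raise ValueError("negative event times")
    return df


@dataclass
class KMCurve:
    """Product-limit estimate: S(t) right-continuous step function.

    ``times`` are the distinct event (death) times; ``survival[i]`` is
    S(times[i]); ``at_risk[i]`` and ``deaths[i]`` the risk-set size and
    death count at that time.  S(0)=1 and S is non-increasing.
    """

    group: str
    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    deaths: np.ndarray
    n_total: int

    def survival_at(self, t: float | np.ndarray) -> np.ndarray | float:
        """S(t) for scalar or vector t (right-continuous)."""
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.times, t, side="right") - 1
        s = np.where(idx < 0, 1.0, np.r_[1.0, self.survival][idx + 1])
        return float(s) if s.ndim == 0 else s

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "group": self.group,
                "time_h": self.times,
                "survival": self.survival,
                "at_risk": self.at_risk,
                "deaths": self.deaths,
            }
        )


def km_estimate(records, group: str | None = None) -> KMCurve:
    """Kaplan-Meier product-limit estimator for one group.

    S(t) = prod over event times t_i <= t of (1 - d_i / n_i), with
    censored cells at a death time still counted in that time's risk set
    (deaths before censorings at ties).
    """
    df = _coerce(records)
    if group is not None:
        df = df[df["group"] == group]
    if df.empty:
        raise ValueError(f"no records for group {group!r}")
    times = df["time_h"].to_numpy(dtype=float)
    events = df["event"].to_numpy(dtype=int)

    event_times = np.unique(times[events == 1])
    n = len(df)
    surv, at_risk, deaths = [], [], []
    s = 1.0
    for t in event_times:
        n_i = int(np.sum(times >= t))  # censored-at-t remain at risk
        d_i = int(np.sum((times == t) & (events == 1)))
        s *= 1.0 - d_i / n_i
        surv.append(s)
        at_risk.append(n_i)
        deaths.append(d_i)
    return KMCurve(
        group=group if group is not None else "",
        times=event_times,
        survival=np.asarray(surv),
        at_risk=np.asarray(at_risk, dtype=int),
        deaths=np.asarray(deaths, dtype=int),
        n_total=n,
    )


@dataclass
class LogRankResult:
    chi2: float
    df: int
    p_value: float
    observed_a: float = 0.0
    expected_a: float = 0.0


def logrank_test(records, group_a: str, group_b: str) -> LogRankResult:
    """Two-sample log-rank test under the pooled-risk null.

    At each distinct death time the observed deaths in group A are
    compared with their hypergeometric expectation given the pooled risk
    set; the squared standardized sum is chi-square with 1 df.
    """
    df = _coerce(records)
    df = df[df["group"].isin([group_a, group_b])]
    if (df["group"] == group_a).sum() == 0 or (df["group"] == group_b).sum() == 0:
        raise ValueError("both groups must be nonempty")
    if int(df["event"].sum()) == 0:
        raise ValueError("log-rank test undefined with zero events")

    times = df["time_h"].to_numpy(dtype=float)
    events = df["event"].to_numpy(dtype=int)
    in_a = (df["group"] == group_a).to_numpy()

    o_minus_e = 0.0
    var = 0.0
    obs_a = 0.0
    exp_a = 0.0
    for t in np.unique(times[events == 1]):
        at_risk = times >= t
        n = int(at_risk.sum())
        n_a = int((at_risk & in_a).sum())
        d = int(((times == t) & (events == 1)).sum())
        d_a = int(((times == t) & (events == 1) & in_a).sum())
        e_a = d * n_a / n
        o_minus_e += d_a - e_a
        obs_a += d_a
        exp_a += e_a
        if n > 1:
            var += d * (n_a / n) * (1 - n_a / n) * (n - d) / (n - 1)
    if var == 0:
        chi2 = 0.0
    else:
        chi2 = o_minus_e**2 / var
    p = float(stats.chi2.sf(chi2, df=1))
    return LogRankResult(
        chi2=float(chi2), df=1, p_value=p,
        observed_a=obs_a, expected_a=exp_a,
    )


def pairwise_logrank(
    records, control: str, bonferroni: bool = False
) -> pd.DataFrame:
    """Log-rank of every non-control group against the control arm.

    Reported unadjusted by default (per-curve reporting); ``bonferroni``
    multiplies p-values by the number of comparisons (capped at 1).
    """
    df = _coerce(records)
    others = [g for g in pd.unique(df["group"]) if g != control]
    rows = []
    for g in others:
        res = logrank_test(df, control, g)
        p = min(1.0, res.p_value * len(others)) if bonferroni else res.p_value
        rows.append(
            {"group": g, "vs": control, "chi2": res.chi2, "p_value": p}
        )
    return pd.DataFrame(rows, columns=["group", "vs", "chi2", "p_value"])


# ---------------------------------------------------------------------------
# ANOVA + Tukey HSD
# ---------------------------------------------------------------------------


@dataclass
class AnovaTukeyResult:
    """ANOVA table (one row per effect) plus Tukey HSD tables per factor."""

    anova: pd.DataFrame
    tukey: dict[str, pd.DataFrame] = field(default_factory=dict)


def _design(levels: pd.Series) -> np.ndarray:
    """Treatment-coded (drop-first) indicator columns for a factor."""
    cats = pd.unique(levels)
    return np.column_stack(
        [(levels == c).to_numpy(dtype=float) for c in cats[1:]]
    ) if len(cats) > 1 else np.empty((len(levels), 0))


def _rss(y: np.ndarray, x: np.ndarray) -> tuple[float, int]:
    """Residual sum of squares and model rank from least squares."""
    coef, _, rank, _ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ coef
    return float(resid @ resid), int(rank)


def _tukey_table(
    y: np.ndarray, levels: pd.Series, mse: float, df_resid: int, k_total: int
) -> pd.DataFrame:
    """Tukey-Kramer pairwise comparisons of level means."""
    cats = list(pd.unique(levels))
    means = {c: float(y[(levels == c).to_numpy()].mean()) for c in cats}
    ns = {c: int((levels == c).sum()) for c in cats}
    q_crit = float(stats.studentized_range.ppf(0.95, k_total, df_resid))
    rows = []
    for a, b in combinations(cats, 2):
        diff = means[a] - means[b]
        se = np.sqrt(mse / 2.0 * (1.0 / ns[a] + 1.0 / ns[b]))
        q = abs(diff) / se if se > 0 else np.inf
        p = float(stats.studentized_range.sf(q, k_total, df_resid))
        rows.append(
            {
                "level_a": a,
                "level_b": b,
                "mean_diff": diff,
                "ci_low": diff - q_crit * se,
                "ci_high": diff + q_crit * se,
                "p_value": p,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["level_a", "level_b", "mean_diff", "ci_low", "ci_high", "p_value"],
    )


def anova_tukey(
    values,
    factor1,
    factor2=None,
) -> AnovaTukeyResult:
    """One-way, or two-way with interaction, ANOVA with Tukey HSD.

    Two-way designs use type-II sums of squares (each main effect tested
    against the model containing the other main effect, the interaction
    against the additive model), which reduce to the classical
    decomposition for balanced data.  Tukey-Kramer comparisons are made
    on the (marginal) level means using the full-model mean square error.

    Raises when a factor has fewer than 2 levels, when any factor level
    (or, for two-way designs, any design cell) has fewer than 2
    observations.
    """
    y = np.asarray(values, dtype=float)
    f1 = pd.Series(factor1).reset_index(drop=True).astype(str)
    if len(y) != len(f1):
        raise ValueError("values and factor1 must have equal length")

    if f1.nunique() < 2:
        raise ValueError("factor1 needs >= 2 levels")
    if f1.value_counts().min() < 2:
        raise ValueError("every factor1 level needs >= 2 observations")

    n = len(y)
    intercept = np.ones((n, 1))
    x1 = _design(f1)

    if factor2 is None:
        x_full = np.hstack([intercept, x1])
        rss_full, rank_full = _rss(y, x_full)
        rss_null, rank_null = _rss(y, intercept)
        df_effect = rank_full - rank_null
        df_resid = n - rank_full
        if df_resid <= 0:
            raise ValueError("no residual degrees of freedom")
        ss = rss_null - rss_full
        mse = rss_full / df_resid
        f_stat = (ss / df_effect) / mse if mse > 0 else (0.0 if ss == 0 else np.inf)
        p = float(stats.f.sf(f_stat, df_effect, df_resid)) if np.isfinite(f_stat) else 0.0
        table = pd.DataFrame(
            {
                "sum_sq": [ss, rss_full],
                "df": [df_effect, df_resid],
                "F": [f_stat, np.nan],
                "p_value": [p, np.nan],
            },
            index=["factor1", "residual"],
        )
        tukey = {
            "factor1": _tukey_table(y, f1, mse, df_resid, f1.nunique())
        }
        return AnovaTukeyResult(anova=table, tukey=tukey)

    f2 = pd.Series(factor2).reset_index(drop=True).astype(str)
    if len(f2) != n:
        raise ValueError("values and factor2 must have equal length")
    if f2.nunique() < 2:
        raise ValueError("factor2 needs >= 2 levels")
    if f2.value_counts().min() < 2:
        raise ValueError("every factor2 level needs >= 2 observations")
    cell_counts = pd.crosstab(f1, f2)
    if (cell_counts.to_numpy() < 2).any():
        raise ValueError("every design cell needs >= 2 observations")

    x2 = _design(f2)
    x12 = np.column_stack(
        [a * b for a in x1.T for b in x2.T]
    ) if x1.shape[1] and x2.shape[1] else np.empty((n, 0))

    x_full = np.hstack([intercept, x1, x2, x12])
    x_add = np.hstack([intercept, x1, x2])
    x_b = np.hstack([intercept, x2])
    x_a = np.hstack([intercept, x1])

    rss_full, rank_full = _rss(y, x_full)
    rss_add, rank_add = _rss(y, x_add)
    rss_b, rank_b = _rss(y, x_b)
    rss_a, rank_a = _rss(y, x_a)

    df_resid = n - rank_full
    if df_resid <= 0:
        raise ValueError("no residual degrees of freedom")
    mse = rss_full / df_resid

    effects = {
        "factor1": (rss_b - rss_add, rank_add - rank_b),
        "factor2": (rss_a - rss_add, rank_add - rank_a),
        "interaction": (rss_add - rss_full, rank_full - rank_add),
    }
    rows = {}
    for name, (ss, dfe) in effects.items():
        ss = max(ss, 0.0)
        if dfe <= 0:
            continue
        f_stat = (ss / dfe) / mse if mse > 0 else (0.0 if ss == 0 else np.inf)
        p = float(stats.f.sf(f_stat, dfe, df_resid)) if np.isfinite(f_stat) else 0.0
        rows[name] = {"sum_sq": ss, "df": dfe, "F": f_stat, "p_value": p}
    rows["residual"] = {
        "sum_sq": rss_full, "df": df_resid, "F": np.nan, "p_value": np.nan
    }
    table = pd.DataFrame.from_dict(rows, orient="index")
    tukey = {
        "factor1": _tukey_table(y, f1, mse, df_resid, f1.nunique()),
        "factor2": _tukey_table(y, f2, mse, df_resid, f2.nunique()),
    }
    return AnovaTukeyResult(anova=table, tukey=tukey)
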