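"""Time-course statistics for repeated color-adaptation experiments.

Stages, in the order an analysis runs them:

1. :func:`summarize_tests` — one hue value per 5-min test (mean of all
   blocks, mean of the first block, or the very first setting).
2. :func:`baseline_correct` — subtract each day's morning pre-glasses value.
3. :func:`session_slope` — OLS slope of the five on-glasses tests, °/hr.
4. :func:`daily_trend` — cross-day linear trend with 95% CI (pooled OLS by
   default; day-mean and per-observer-slope conventions reported alongside,
   since the unit of analysis changes the CI but not the slope under a
   balanced design).
5. :func:`decay_fit` — post-removal exponential decay, bounded tau,
   multi-start least squares.
6. :func:`slope_anova` — one-way ANOVA of session slopes across sessions.
7. :func:`retention_fraction`, :func:`retest_correlation`,
   :func:`paired_day_comparison` — follow-up statistics.

:func:`analyze_cohort` chains everything into a single report dictionary.
Missing test cells are carried as explicit NaN rows; estimators use
available cases and report n.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "STATISTIC_KINDS",
    "TrendFit",
    "DecayFit",
    "AnovaResult",
    "TTestResult",
    "CorrelationResult",
    "RetentionResult",
    "summarize_tests",
    "baseline_correct",
    "session_slope",
    "grand_average_slope",
    "daily_trend",
    "decay_fit",
    "slope_anova",
    "retention_fraction",
    "retest_correlation",
    "paired_day_comparison",
    "analyze_cohort",
]

STATISTIC_KINDS = ("mean_all_blocks", "first_block_mean", "first_setting")

_KEYS = ["observer_id", "followup", "day", "session", "phase", "test_minute"]


class MissingBaselineError(ValueError):
    """A day lacks the morning pre-glasses test needed for correction."""


# --------------------------------------------------------------------- results
@dataclass(frozen=True)
class TrendFit:
    """Linear trend of a quantity across days."""

    slope: float
    intercept: float
    ci_low: float
    ci_high: float
    t_stat: float
    p_value: float
    n_points: int
    df: int
    model_form: str
    alternatives: dict = field(default_factory=dict, compare=False)


@dataclass(frozen=True)
class DecayFit:
    """Exponential fit hue(t) = asymptote + amplitude * exp(-t / tau)."""

    amplitude: float
    tau: float
    asymptote: float
    rmse: float
    converged: bool
    n_points: int


@dataclass(frozen=True)
class AnovaResult:
    f_stat: float
    df1: int
    df2: int
    p_value: float


@dataclass(frozen=True)
class TTestResult:
    t_stat: float
    df: int
    p_value: float
    mean_diff: float
    degenerate: bool = False


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p_value: float
    n: int
    degenerate: bool = False


@dataclass(frozen=True)
class RetentionResult:
    fraction: float
    day1: float
    day5: float
    followup: float
    degenerate: bool = False


# ----------------------------------------------------------------- aggregation
def summarize_tests(records: pd.DataFrame, statistic_kind: str = "mean_all_blocks") -> pd.DataFrame:
    """Collapse individual matches to one hue value per test.

    Returns one row per observer × day × session × phase × test, with NaN
    rows (n_matches 0) for cells absent from the input, so missingness is
    explicit rather than silent.
    """
    if statistic_kind not in STATISTIC_KINDS:
        raise ValueError(f"statistic_kind must be one of {STATISTIC_KINDS}")
    df = records.copy()
    if "followup" not in df:
        df["followup"] = False

    if statistic_kind == "first_block_mean":
        first_block = df.groupby(_KEYS, sort=False)["block"].transform("min")
        sel = df[df["block"] == first_block]
    elif statistic_kind == "first_setting":
        sel = df.sort_values(["block", "match_index"]).groupby(_KEYS, sort=False).head(1)
    else:
        sel = df
    agg = sel.groupby(_KEYS, sort=False)["hue_angle_deg"].agg(["mean", "size"]).reset_index()
    agg = agg.rename(columns={"mean": "hue_value", "size": "n_matches"})

    # explicit-missing completion: every observer crossed with every test cell
    cells = df[_KEYS[1:]].drop_duplicates()
    observers = df[["observer_id"]].drop_duplicates()
    full = observers.merge(cells, how="cross")
    out = full.merge(agg, on=_KEYS, how="left")
    out["n_matches"] = out["n_matches"].fillna(0).astype(int)
    out["statistic_kind"] = statistic_kind
    return out.sort_values(_KEYS, ignore_index=True)


def baseline_correct(summaries: pd.DataFrame, am_session: str | None = None) -> pd.DataFrame:
    """Subtract each day's morning pre-glasses value from that day's settings.

    The follow-up session (day 0) is corrected by its own pre-glasses test.
    Corrected morning baselines are exactly zero.  Raises
    :class:`MissingBaselineError` listing any day without a usable baseline.
    """
    df = summaries.copy()
    if am_session is None:
        am_session = sorted(df["session"].unique())[0]  # "AM" before "PM"
    pre = df[(df["session"] == am_session) & (df["phase"] == "pre")]
    pre = pre.sort_values("test_minute").groupby(["observer_id", "followup", "day"], sort=False).head(1)
    base = pre.set_index(["observer_id", "followup", "day"])["hue_value"]

    idx = pd.MultiIndex.from_frame(df[["observer_id", "followup", "day"]])
    baseline = base.reindex(idx).to_numpy()
    missing = df.loc[np.isnan(baseline), ["observer_id", "day"]].drop_duplicates()
    if len(missing):
        listing = ", ".join(f"{o} day {d}" for o, d in missing.itertuples(index=False))
        raise MissingBaselineError(f"no morning pre-glasses baseline for: {listing}")
    df["baseline_value"] = baseline
    df["hue_value"] = df["hue_value"] - baseline
    return df


# ---------------------------------------------------------------------- slopes
def _ols_line(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Slope and intercept of a least-squares line (closed form)."""
    xm, ym = x.mean(), y.mean()
    sxx = float(np.sum((x - xm) ** 2))
    slope = float(np.sum((x - xm) * (y - ym)) / sxx)
    return slope, ym - slope * xm


def session_slope(summaries: pd.DataFrame, min_points: int = 3) -> pd.DataFrame:
    """Within-session slope of the on-glasses tests, °/hr, per observer-session.

    Sessions with fewer than ``min_points`` available tests yield NaN slopes
    (missing, not dropped).
    """
    on = summaries[(summaries["phase"] == "on") & summaries["hue_value"].notna()]
    rows = []
    for (oid, followup, day, session), grp in on.groupby(
        ["observer_id", "followup", "day", "session"], sort=True
    ):
        if len(grp) < min_points:
            slope = np.nan
        else:
            slope, _ = _ols_line(grp["test_minute"].to_numpy() / 60.0, grp["hue_value"].to_numpy())
        rows.append((oid, followup, day, session, slope, len(grp)))
    return pd.DataFrame(
        rows, columns=["observer_id", "followup", "day", "session", "slope", "n_tests"]
    )


def grand_average_slope(slopes: pd.DataFrame, include_followup: bool = False) -> float:
    """Unweighted mean session slope over observers × sessions, °/hr."""
    df = slopes if include_followup else slopes[~slopes["followup"]]
    return float(df["slope"].mean())


# ---------------------------------------------------------------------- trends
def _linregress_ci(x: np.ndarray, y: np.ndarray, df_: int) -> tuple[float, float, float, float, float]:
    """OLS slope with CI/t/p computed at the given residual df."""
    slope, intercept = _ols_line(x, y)
    resid = y - (intercept + slope * x)
    sxx = float(np.sum((x - x.mean()) ** 2))
    if df_ <= 0:
        return slope, intercept, np.nan, np.nan, np.nan
    se = float(np.sqrt(np.sum(resid**2) / df_ / sxx))
    if se == 0.0:
        tval = float(np.inf) * np.sign(slope) if slope != 0.0 else 0.0
        return slope, intercept, 0.0, tval, (0.0 if slope != 0.0 else 1.0)
    tval = slope / se
    p = 2.0 * stats.t.sf(abs(tval), df_)
    half = stats.t.ppf(0.975, df_) * se
    return slope, intercept, se, tval, p


def daily_trend(
    values: pd.DataFrame,
    value_col: str = "value",
    day_col: str = "day",
    observer_col: str = "observer_id",
    model_form: str = "pooled",
) -> TrendFit:
    """Cross-day linear trend of per-observer daily values.

    ``model_form`` picks the convention whose CI is reported as primary:
    ``pooled`` (one OLS over all observer-day points), ``day_means`` (OLS on
    the 5 cohort day means), or ``observer_slopes`` (one slope per observer,
    t interval on their mean).  Under a balanced design the three slopes
    coincide; their CIs do not, and all are returned in ``alternatives``.
    """
    df = values[[observer_col, day_col, value_col]].dropna()
    days = np.sort(df[day_col].unique())
    if len(days) < 2:
        raise ValueError("a trend needs at least two distinct days")
    x = df[day_col].to_numpy(dtype=float)
    y = df[value_col].to_numpy(dtype=float)

    results: dict[str, tuple] = {}
    slope, intercept, se, tval, p = _linregress_ci(x, y, len(x) - 2)
    half = stats.t.ppf(0.975, len(x) - 2) * se if len(x) > 2 else np.nan
    results["pooled"] = (slope, intercept, slope - half, slope + half, tval, p, len(x), len(x) - 2)

    means = df.groupby(day_col)[value_col].mean()
    xm, ym = means.index.to_numpy(dtype=float), means.to_numpy()
    if len(xm) > 2:
        s2, i2, se2, t2, p2 = _linregress_ci(xm, ym, len(xm) - 2)
        half2 = stats.t.ppf(0.975, len(xm) - 2) * se2
        results["day_means"] = (s2, i2, s2 - half2, s2 + half2, t2, p2, len(xm), len(xm) - 2)

    per_obs = []
    for _, grp in df.groupby(observer_col):
        if grp[day_col].nunique() >= 2:
            per_obs.append(_ols_line(grp[day_col].to_numpy(dtype=float), grp[value_col].to_numpy())[0])
    if len(per_obs) >= 3:
        arr = np.asarray(per_obs)
        se3 = arr.std(ddof=1) / np.sqrt(len(arr))
        if se3 > 0:
            t3 = arr.mean() / se3
            p3 = 2.0 * stats.t.sf(abs(t3), len(arr) - 1)
        else:
            t3, p3 = (np.inf if arr.mean() else 0.0), 0.0
        half3 = stats.t.ppf(0.975, len(arr) - 1) * se3
        results["observer_slopes"] = (
            arr.mean(), np.nan, arr.mean() - half3, arr.mean() + half3,
            t3, p3, len(arr), len(arr) - 1,
        )

    if model_form not in results:
        raise ValueError(f"model_form {model_form!r} unavailable for this design")
    s, i, lo, hi, tv, pv, n, dof = results[model_form]
    return TrendFit(
        slope=float(s), intercept=float(i), ci_low=float(lo), ci_high=float(hi),
        t_stat=float(tv), p_value=float(pv), n_points=int(n), df=int(dof),
        model_form=model_form,
        alternatives={
            k: {"slope": float(v[0]), "ci_low": float(v[2]), "ci_high": float(v[3]), "df": int(v[7])}
            for k, v in results.items()
        },
    )


# ----------------------------------------------------------------------- decay
def decay_fit(
    minutes: Iterable[float],
    values: Iterable[float],
    baseline: float,
    tau_bounds: tuple[float, float] = (0.1, 500.0),
    tau_starts: tuple[float, ...] = (5.0, 15.0, 60.0),
) -> DecayFit:
    """Fit the post-removal aftereffect decay by bounded least squares.

    The asymptote is initialised at the day's baseline; three tau starts
    guard against local minima.  ``converged`` reflects optimiser success on
    the best start.
    """
    t = np.asarray(list(minutes), dtype=float)
    y = np.asarray(list(values), dtype=float)
    ok = ~np.isnan(y)
    t, y = t[ok], y[ok]
    if len(t) < 4:
        raise ValueError("decay fit needs at least four post-removal time points")

    def model(tt, amp, tau, asym):
        return asym + amp * np.exp(-tt / tau)

    best = None
    amp0 = float(y[0] - baseline)
    if amp0 == 0.0:
        amp0 = 1e-6
    for tau0 in tau_starts:
        try:
            popt, _ = optimize.curve_fit(
                model, t, y,
                p0=(amp0, tau0, baseline),
                bounds=([-np.inf, tau_bounds[0], -np.inf], [np.inf, tau_bounds[1], np.inf]),
                maxfev=5000,
            )
        except RuntimeError:
            continue
        sse = float(np.sum((y - model(t, *popt)) ** 2))
        if best is None or sse < best[1]:
            best = (popt, sse)
    if best is None:
        return DecayFit(np.nan, np.nan, np.nan, np.nan, converged=False, n_points=len(t))
    (amp, tau, asym), sse = best
    return DecayFit(
        amplitude=float(amp), tau=float(tau), asymptote=float(asym),
        rmse=float(np.sqrt(sse / len(t))), converged=True, n_points=len(t),
    )


# ----------------------------------------------------------------------- tests
def slope_anova(slopes: pd.DataFrame) -> AnovaResult:
    """One-way fixed-effects ANOVA of session slopes with session as factor."""
    df = slopes.loc[~slopes["followup"].astype(bool)].dropna(subset=["slope"])
    groups = [g["slope"].to_numpy() for _, g in df.groupby(["day", "session"], sort=True)]
    if any(len(g) < 2 for g in groups) or len(groups) < 2:
        raise ValueError("each session needs at least two slopes for the ANOVA")
    df1 = len(groups) - 1
    df2 = sum(len(g) for g in groups) - len(groups)
    grand = np.concatenate(groups).mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    if ss_between == 0.0:  # no between-session variation at all
        return AnovaResult(0.0, df1, df2, 1.0)
    f, p = stats.f_oneway(*groups)
    return AnovaResult(float(f), df1, df2, float(p))


def retention_fraction(day1: float, day5: float, followup: float) -> RetentionResult:
    """Fraction of the 5-day learning retained at follow-up, on cohort means."""
    denom = day5 - day1
    if denom == 0.0:
        return RetentionResult(np.nan, day1, day5, followup, degenerate=True)
    return RetentionResult(float((followup - day1) / denom), day1, day5, followup)


def retest_correlation(delta_day5: Iterable[float], delta_followup: Iterable[float]) -> CorrelationResult:
    """Pearson correlation of per-observer learning deltas (test-retest)."""
    a = np.asarray(list(delta_day5), dtype=float)
    b = np.asarray(list(delta_followup), dtype=float)
    if a.shape != b.shape or len(a) < 3:
        raise ValueError("need matched deltas for at least three observers")
    if a.std() == 0.0 or b.std() == 0.0:
        return CorrelationResult(np.nan, np.nan, len(a), degenerate=True)
    r, p = stats.pearsonr(a, b)
    return CorrelationResult(float(r), float(p), len(a))


def paired_day_comparison(values_a: Iterable[float], values_b: Iterable[float]) -> TTestResult:
    """Paired two-sided t test of condition A against condition B."""
    a = np.asarray(list(values_a), dtype=float)
    b = np.asarray(list(values_b), dtype=float)
    if a.shape != b.shape or len(a) < 3:
        raise ValueError("paired comparison needs at least three matched pairs")
    d = a - b
    if d.std(ddof=1) == 0.0:
        t = 0.0 if d.mean() == 0.0 else float(np.inf) * np.sign(d.mean())
        return TTestResult(t, len(d) - 1, 0.0 if d.mean() else 1.0, float(d.mean()), degenerate=True)
    t, p = stats.ttest_rel(a, b)
    return TTestResult(float(t), len(d) - 1, float(p), float(d.mean()))


# ---------------------------------------------------------------- full report
def _per_day_value(corrected: pd.DataFrame, phase: str, minute_pick: str) -> pd.DataFrame:
    """Per observer per day: the first/last on-phase test value, AM/PM averaged."""
    df = corrected[(corrected["phase"] == phase) & corrected["hue_value"].notna()]
    pick = df.groupby(["observer_id", "followup", "day", "session"], sort=True).apply(
        lambda g: g.loc[g["test_minute"].idxmin() if minute_pick == "first" else g["test_minute"].idxmax(), "hue_value"],
        include_groups=False,
    )
    pick = pick.rename("value").reset_index()
    return (
        pick.groupby(["observer_id", "followup", "day"], sort=True)["value"]
        .mean()
        .reset_index()
    )


def analyze_cohort(
    records: pd.DataFrame,
    statistic_kind: str = "mean_all_blocks",
    model_form: str = "pooled",
    include_decay: bool = True,
) -> dict:
    """Run the full statistics pipeline and return a report dictionary.

    Keys: ``grand_slope`` (°/hr), ``slope_anova``, ``baseline_trend``,
    ``rapid_trend``, ``total_trend``, ``aftereffect_trend``, ``decay`` (per
    day, cohort mean), ``decay_anova`` (session taus), ``retention``,
    ``retest``, ``followup_vs_day1``, ``followup_vs_day5``, plus the
    intermediate tables under ``tables``.
    """
    summaries = summarize_tests(records, statistic_kind)
    corrected = baseline_correct(summaries)
    slopes = session_slope(summaries)

    main = ~summaries["followup"]
    report: dict = {}
    report["grand_slope"] = grand_average_slope(slopes)
    report["slope_anova"] = slope_anova(slopes)

    baseline = summaries[
        main & (summaries["phase"] == "pre")
        & (summaries["session"] == sorted(summaries["session"].unique())[0])
    ].rename(columns={"hue_value": "value"})
    report["baseline_trend"] = daily_trend(baseline, model_form=model_form)

    rapid = _per_day_value(corrected, "on", "first")
    total = _per_day_value(corrected, "on", "last")
    after = _per_day_value(corrected, "post", "first")
    report["rapid_trend"] = daily_trend(rapid[~rapid["followup"]], model_form=model_form)
    report["total_trend"] = daily_trend(total[~total["followup"]], model_form=model_form)
    report["aftereffect_trend"] = daily_trend(after[~after["followup"]], model_form=model_form)

    # aftereffect decay: cohort-mean time course per day
    decay = {}
    post = corrected[main & (corrected["phase"] == "post")]
    if not include_decay:
        post = post.iloc[0:0]
    for day, grp in post.groupby("day"):
        curve = grp.groupby("test_minute")["hue_value"].mean()
        try:
            decay[int(day)] = decay_fit(curve.index, curve.to_numpy(), baseline=0.0)
        except ValueError:
            continue
    report["decay"] = decay

    # per observer-session taus for the cross-session ANOVA of decay constants
    taus = []
    for (oid, day, session), grp in post.groupby(["observer_id", "day", "session"]):
        curve = grp.dropna(subset=["hue_value"])
        if len(curve) < 4:
            continue
        fit = decay_fit(curve["test_minute"], curve["hue_value"], baseline=0.0)
        if fit.converged:
            taus.append((oid, False, day, session, fit.tau))
    taus = pd.DataFrame(taus, columns=["observer_id", "followup", "day", "session", "slope"])
    try:
        report["decay_anova"] = slope_anova(taus)
    except ValueError:
        report["decay_anova"] = None

    # follow-up statistics on the rapid-adjustment values
    if rapid["followup"].any():
        wide = rapid.pivot_table(index="observer_id", columns=["followup", "day"], values="value")
        d1 = wide[(False, 1)]
        d5 = wide[(False, rapid.loc[~rapid["followup"], "day"].max())]
        fu = wide[(True, 0)]
        report["retention"] = retention_fraction(
            float(d1.mean()), float(d5.mean()), float(fu.mean())
        )
        report["retest"] = retest_correlation(d5 - d1, fu - d1)
        report["followup_vs_day1"] = paired_day_comparison(d1, fu)
        report["followup_vs_day5"] = paired_day_comparison(d5, fu)
    report["tables"] = {
        "summaries": summaries,
        "corrected": corrected,
        "session_slopes": slopes,
        "rapid_by_day": rapid,
        "total_by_day": total,
        "aftereffect_by_day": after,
    }
    report["statistic_kind"] = statistic_kind
    return report
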