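"""Relative cone gain k = L/M and the color-constancy fraction.

A unique-yellow setting is taken to mark the balance point of L- and M-cone
signals, L = k·M, so the physical light at the eye determines the relative
gain k = L/M directly.  Settings made through the glasses are evaluated on
the filtered spectrum.  Perfect constancy predicts that the day-1 baseline
pixels, viewed through the glasses, still look unique yellow: its k is the
reference line, and the constancy fraction locates an observed setting
between no compensation (k_baseline) and full compensation (k_perfect).

k is computed with peak-normalised fundamentals; its absolute level is a
convention of that normalisation, but differences and fractions of k are
what carry the analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import colorspace as cs
from .display import FilterModel, MonitorModel, apply_filter, render_setting, rgb_to_spectrum
from .fundamentals import ConeFundamentalSet, gain_fundamentals

__all__ = [
    "GainResult",
    "ConstancyResult",
    "cone_gain_k",
    "perfect_constancy_k",
    "constancy_fraction",
    "daily_constancy",
]


@dataclass(frozen=True)
class GainResult:
    """Relative cone gain of one setting under a stated viewing condition."""

    k: float
    condition: str  # "glasses_on" | "glasses_off"
    setting: cs.HueSetting


@dataclass(frozen=True)
class ConstancyResult:
    fraction: float
    k_baseline: float
    k_setting: float
    k_perfect: float
    degenerate: bool = False

    @property
    def percent(self) -> float:
        return 100.0 * self.fraction


def cone_gain_k(
    setting: cs.HueSetting,
    mon: MonitorModel,
    filt: FilterModel | None = None,
    fund: ConeFundamentalSet | None = None,
) -> GainResult:
    """k = L/M of the light reaching the eye for a rendered hue setting.

    With ``filt`` supplied the setting is evaluated through the glasses
    (condition ``glasses_on``); stimuli themselves are always rendered
    unfiltered, as in the task.
    """
    fund = fund or gain_fundamentals()
    if fund.normalization != "peak_one":
        raise ValueError("cone gain uses peak-normalised fundamentals")
    spec = rgb_to_spectrum(render_setting(setting, mon), mon)
    if filt is not None:
        spec = apply_filter(spec, filt)
    lms = cs.cone_absorptions(spec, fund)
    if lms.m == 0:
        raise ZeroDivisionError("M-cone absorption is zero; k undefined")
    return GainResult(
        k=lms.l / lms.m,
        condition="glasses_on" if filt is not None else "glasses_off",
        setting=setting,
    )


def perfect_constancy_k(
    day1_baseline: cs.HueSetting,
    mon: MonitorModel,
    filt: FilterModel,
    fund: ConeFundamentalSet | None = None,
) -> float:
    """k of the day-1 baseline pixels seen through the glasses.

    The reference line of the constancy analysis: the physical color deemed
    unique yellow at baseline, unchanged, filtered by the glasses.
    """
    return cone_gain_k(day1_baseline, mon, filt=filt, fund=fund).k


def constancy_fraction(k_baseline: float, k_setting: float, k_perfect: float) -> ConstancyResult:
    """Distance ratio |k_setting − k_baseline| / |k_perfect − k_baseline|.

    0 means the setting stayed at baseline (no constancy); 1 means it reached
    the perfect-constancy reference.  Degenerate when the reference equals
    the baseline.
    """
    denom = abs(k_perfect - k_baseline)
    if denom == 0.0:
        return ConstancyResult(np.nan, k_baseline, k_setting, k_perfect, degenerate=True)
    return ConstancyResult(
        abs(k_setting - k_baseline) / denom, k_baseline, k_setting, k_perfect
    )


def daily_constancy(
    summaries: pd.DataFrame,
    mon: MonitorModel,
    filt: FilterModel,
    fund: ConeFundamentalSet | None = None,
    order: str = "mean_settings",
    am_session: str | None = None,
) -> pd.DataFrame:
    """Constancy fraction of the first on-glasses test, per day.

    ``order`` selects whether k is computed on cohort-mean hue settings
    (``mean_settings``) or per observer with fractions averaged afterwards
    (``per_observer``); both orders answer the same question and are reported
    because the aggregation order is a genuine analysis choice.

    Expects *uncorrected* test summaries (absolute hue angles).
    """
    if order not in ("mean_settings", "per_observer"):
        raise ValueError("order must be 'mean_settings' or 'per_observer'")
    df = summaries[~summaries["followup"]]
    if am_session is None:
        am_session = sorted(df["session"].unique())[0]

    def first_on(g: pd.DataFrame) -> float:
        on = g[g["phase"] == "on"].dropna(subset=["hue_value"])
        return float(on.loc[on["test_minute"].idxmin(), "hue_value"])

    def day1_pre(g: pd.DataFrame) -> float:
        pre = g[(g["phase"] == "pre") & (g["day"] == 1) & (g["session"] == am_session)]
        return float(pre["hue_value"].dropna().iloc[0])

    def fraction_for(baseline_angle: float, setting_angle: float) -> ConstancyResult:
        base = cs.HueSetting(baseline_angle)
        k_b = cone_gain_k(base, mon, fund=fund).k
        k_p = perfect_constancy_k(base, mon, filt, fund=fund)
        k_s = cone_gain_k(cs.HueSetting(setting_angle), mon, filt=filt, fund=fund).k
        return constancy_fraction(k_b, k_s, k_p)

    days = sorted(df.loc[df["phase"] == "on", "day"].unique())
    rows = []
    if order == "mean_settings":
        base_angle = df.groupby("observer_id").apply(day1_pre, include_groups=False).mean()
        for day in days:
            sel = df[(df["day"] == day) & (df["session"] == am_session)]
            setting = sel.groupby("observer_id").apply(first_on, include_groups=False).mean()
            res = fraction_for(float(base_angle), float(setting))
            rows.append((day, res.fraction, res.k_baseline, res.k_setting, res.k_perfect))
    else:
        for day in days:
            fracs, kb, ks, kp = [], [], [], []
            for oid, g in df.groupby("observer_id"):
                res = fraction_for(
                    day1_pre(g), first_on(g[(g["day"] == day) & (g["session"] == am_session)])
                )
                fracs.append(res.fraction)
                kb.append(res.k_baseline)
                ks.append(res.k_setting)
                kp.append(res.k_perfect)
            rows.append((day, float(np.mean(fracs)), float(np.mean(kb)),
                         float(np.mean(ks)), float(np.mean(kp))))
    out = pd.DataFrame(rows, columns=["day", "fraction", "k_baseline", "k_setting", "k_perfect"])
    out["percent"] = 100.0 * out["fraction"]
    out["order"] = order
    return out
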