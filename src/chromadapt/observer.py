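"""Synthetic observers for the repeated color-adaptation experiment.

The generative model mirrors the structure of the measured time courses:

* a per-day baseline that drifts slowly greener across days,
* a "rapid adjustment" on donning the glasses — an immediate greenward offset
  whose magnitude shrinks (hue settings rise) day by day as mode switching is
  learned, capped so compensation never overshoots the baseline,
* a constant within-session adaptation ramp toward red while the glasses are
  worn (°/hr),
* an exponentially decaying redward aftereffect after the glasses come off,
* a follow-up session a month later that retains a fraction of the 5-day
  learning,
* per-observer random effects (with one latent "learning ability" factor
  shared by learning rate and retention) and per-match Gaussian noise.

Default population means are the study's estimands: baseline drift
−0.94 °/day, rapid-adjustment trend +4.06 °/day (day-1 value −72.64°, i.e.
4.06·t − 76.7 at t = 1), within-session slope 13.30 °/hr, retention 0.66,
with 11 observers, 5 days × 2 sessions × 10 tests × 5 one-minute blocks plus
a follow-up.  The per-match noise SD (3°) and the aftereffect shape
(amplitude 10°, time constant 12 min) are free generative choices not printed
by the study; see the methods note.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, fields

import numpy as np
import pandas as pd

from .colorspace import GREEN_ENDPOINT, RED_ENDPOINT

__all__ = [
    "ScheduleConfig",
    "ObserverParams",
    "CohortParams",
    "expected_hue",
    "simulate_cohort",
    "simulate_adjustment_trace",
    "AdjustmentTrace",
    "PHASES",
]

PHASES = ("pre", "on", "post")


@dataclass(frozen=True)
class ScheduleConfig:
    """Timing skeleton of one experiment (times in minutes within a session)."""

    n_days: int = 5
    sessions: tuple[str, ...] = ("AM", "PM")
    pre_test_minutes: tuple[float, ...] = (-5.0,)
    glasses_on_test_minutes: tuple[float, ...] = (0.0, 10.0, 25.0, 40.0, 55.0)
    post_removal_test_minutes: tuple[float, ...] = (0.0, 10.0, 20.0, 30.0)
    blocks_per_test: int = 5
    block_duration_s: float = 60.0
    include_followup: bool = True
    followup_delay_days: float = 36.0

    def __post_init__(self) -> None:
        if self.n_days < 1 or self.blocks_per_test < 1 or not self.sessions:
            raise ValueError("counts must be >= 1")
        for minutes in (
            self.pre_test_minutes,
            self.glasses_on_test_minutes,
            self.post_removal_test_minutes,
        ):
            if len(minutes) == 0 or np.any(np.diff(minutes) <= 0):
                raise ValueError("test minutes must be nonempty and strictly increasing")

    def tests(self):
        """Yield (phase, test_minute) in chronological order for one session."""
        for m in self.pre_test_minutes:
            yield "pre", m
        for m in self.glasses_on_test_minutes:
            yield "on", m
        for m in self.post_removal_test_minutes:
            yield "post", m


@dataclass(frozen=True)
class ObserverParams:
    """Generative parameters of one observer (angles in degrees of hue)."""

    baseline0: float = 297.36        # day-1 AM pre-glasses mean
    baseline_drift: float = -0.94    # °/day, negative = greener
    rapid_day1: float = -72.64       # day-1 first on-glasses offset from baseline
    rapid_learn_rate: float = 4.06   # °/day shrinkage of the rapid offset
    gradual_slope: float = 13.30     # °/hr toward red while glasses worn
    aftereffect_amp: float = 10.0    # ° redward immediately after removal
    decay_tau: float = 12.0          # min, aftereffect time constant
    retention: float = 0.66          # fraction of 5-day learning kept at follow-up
    noise_sd: float = 3.0            # ° per individual match
    matches_per_block_mean: float = 3.0
    pm_offset: float = 0.0           # optional PM shift of the rapid offset

    def __post_init__(self) -> None:
        if self.decay_tau <= 0:
            raise ValueError("decay_tau must be positive")
        if not (0.0 <= self.retention <= 1.0):
            raise ValueError("retention must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.matches_per_block_mean < 1:
            raise ValueError("matches_per_block_mean must be >= 1")


def _rapid(params: ObserverParams, day: int) -> float:
    """Rapid-adjustment offset on a given day, capped at full compensation."""
    return min(0.0, params.rapid_day1 + params.rapid_learn_rate * (day - 1))


def expected_hue(
    params: ObserverParams,
    day: int,
    session: str,
    phase: str,
    minutes: float,
    followup: bool = False,
    n_days: int = 5,
) -> float:
    """Deterministic mean hue angle for one test.

    ``followup=True`` evaluates the follow-up session: the rapid offset is
    the day-1 value plus ``retention`` of the learning accrued by day
    ``n_days``; the baseline holds at its last-day value (the within-
    experiment drift is not extrapolated over the retention month).
    """
    if phase not in PHASES:
        raise ValueError(f"unknown phase {phase!r}; expected one of {PHASES}")
    if followup:
        base_day = n_days
        rapid = _rapid(params, 1) + params.retention * (
            _rapid(params, n_days) - _rapid(params, 1)
        )
    else:
        base_day = day
        rapid = _rapid(params, day)
    baseline = params.baseline0 + params.baseline_drift * (base_day - 1)
    if phase == "pre":
        return baseline
    if phase == "on":
        off = params.pm_offset if session == "PM" else 0.0
        return baseline + rapid + off + params.gradual_slope * minutes / 60.0
    return baseline + params.aftereffect_amp * float(np.exp(-minutes / params.decay_tau))


# population SDs paired with one latent learning-ability factor; the latent
# loading and the retention SD are calibrated so the generative test-retest
# correlation of the learning deltas is ~0.8
@dataclass(frozen=True)
class CohortParams:
    """Population-level generative parameters."""

    n_observers: int = 11
    means: ObserverParams = field(default_factory=ObserverParams)
    sd_baseline0: float = 4.0
    sd_baseline_drift: float = 0.3
    sd_rapid_day1: float = 10.0
    sd_rapid_learn_rate: float = 1.6
    # zero between-observer variance in the gradual slope: with the same
    # observers in every session, observer slope heterogeneity would deflate
    # the one-way session ANOVA far below the near-unity F the study reports
    sd_gradual_slope: float = 0.0
    sd_aftereffect_amp: float = 3.0
    sd_decay_tau: float = 3.0
    sd_retention: float = 0.20
    latent_loading: float = 0.3  # shared factor on learn rate and retention (corr units)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_observers < 2:
            raise ValueError("need at least two observers")
        for f in fields(self):
            if f.name.startswith("sd_") and getattr(self, f.name) < 0:
                raise ValueError(f"{f.name} must be nonnegative")
        if not (-1.0 <= self.latent_loading <= 1.0):
            raise ValueError("latent_loading must lie in [-1, 1]")


def _draw_observers(cohort: CohortParams, rng: np.random.Generator) -> list[ObserverParams]:
    n = cohort.n_observers
    m = cohort.means
    z = rng.standard_normal(n)  # latent learning ability
    lam = cohort.latent_loading
    resid = np.sqrt(1.0 - lam**2)

    def mixed(mean, sd):
        return mean + sd * (lam * z + resid * rng.standard_normal(n))

    learn = mixed(m.rapid_learn_rate, cohort.sd_rapid_learn_rate)
    retention = np.clip(mixed(m.retention, cohort.sd_retention), 0.0, 1.0)
    draws = {
        "baseline0": m.baseline0 + cohort.sd_baseline0 * rng.standard_normal(n),
        "baseline_drift": m.baseline_drift + cohort.sd_baseline_drift * rng.standard_normal(n),
        "rapid_day1": m.rapid_day1 + cohort.sd_rapid_day1 * rng.standard_normal(n),
        "rapid_learn_rate": learn,
        "gradual_slope": m.gradual_slope + cohort.sd_gradual_slope * rng.standard_normal(n),
        "aftereffect_amp": np.maximum(
            0.0, m.aftereffect_amp + cohort.sd_aftereffect_amp * rng.standard_normal(n)
        ),
        "decay_tau": np.maximum(
            0.5, m.decay_tau + cohort.sd_decay_tau * rng.standard_normal(n)
        ),
        "retention": retention,
    }
    out = []
    for i in range(n):
        out.append(
            dataclasses.replace(
                m, **{k: float(v[i]) for k, v in draws.items()}
            )
        )
    return out


def simulate_cohort(
    cohort: CohortParams | None = None,
    sched: ScheduleConfig | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Simulate a complete settings table for a cohort.

    Returns a tidy frame with one row per individual match, columns
    ``observer_id, day, session, phase, test_minute, block, match_index,
    hue_angle_deg, glasses_on, followup``.  The follow-up session is coded
    ``day = 0`` with ``followup = True``.  Ground truth is attached in
    ``DataFrame.attrs`` (per-observer parameters, seed).  The same seed and
    configuration reproduce the table exactly.
    """
    cohort = cohort or CohortParams()
    sched = sched or ScheduleConfig()
    rng = np.random.default_rng(cohort.seed if seed is None else seed)
    observers = _draw_observers(cohort, rng)

    tests = list(sched.tests())
    day_codes = list(range(1, sched.n_days + 1)) + ([0] if sched.include_followup else [])
    rows = []
    for i, params in enumerate(observers):
        oid = f"O{i + 1:02d}"
        for day in day_codes:
            followup = day == 0
            sessions = sched.sessions[:1] if followup else sched.sessions
            for session in sessions:
                for phase, minute in tests:
                    mu = expected_hue(
                        params, day, session, phase, minute,
                        followup=followup, n_days=sched.n_days,
                    )
                    for block in range(1, sched.blocks_per_test + 1):
                        n_matches = 1 + int(rng.poisson(params.matches_per_block_mean - 1.0))
                        vals = mu + params.noise_sd * rng.standard_normal(n_matches)
                        vals = np.clip(vals, GREEN_ENDPOINT, RED_ENDPOINT)
                        for j, v in enumerate(vals, start=1):
                            rows.append(
                                (oid, day, session, phase, minute, block, j,
                                 float(v), phase == "on", followup)
                            )
    df = pd.DataFrame(
        rows,
        columns=[
            "observer_id", "day", "session", "phase", "test_minute",
            "block", "match_index", "hue_angle_deg", "glasses_on", "followup",
        ],
    )
    df.attrs["seed"] = int(cohort.seed if seed is None else seed)
    df.attrs["truth"] = pd.DataFrame([dataclasses.asdict(p) for p in observers]).assign(
        observer_id=[f"O{i + 1:02d}" for i in range(len(observers))]
    )
    df.attrs["cohort"] = dataclasses.asdict(cohort)
    df.attrs["schedule"] = dataclasses.asdict(sched)
    return df


@dataclass(frozen=True)
class AdjustmentTrace:
    """Button-press record of one simulated adjustment."""

    trace: tuple[float, ...]  # hue angle after each press, starting position first
    final: float
    n_presses: int
    elapsed_s: float
    accepted: bool


def simulate_adjustment_trace(
    target: float,
    seed: int | None = None,
    start: float | None = None,
    sigma_percept: float = 2.0,
    coarse_step: float = 5.0,
    fine_step: float = 1.0,
    coarse_threshold: float = 6.0,
    press_interval_s: float = 0.75,
    max_duration_s: float = 20.0,
) -> AdjustmentTrace:
    """Micro-simulation of the 5°/1° button-press adjustment.

    The controller holds a noisy percept of the target (target + N(0, σ)),
    presses coarse 5° steps while far from it, fine 1° steps when close, and
    accepts within half a fine step.  Presses have no effect beyond the 200°
    and 360° endpoints.  The trial ends at acceptance or at the 20 s cap;
    presses are charged 0.75 s each (the 1.5 s cadence of the task is the
    stimulus presentation interval, two presses per presentation).
    """
    if not (GREEN_ENDPOINT <= target <= RED_ENDPOINT):
        raise ValueError(f"target {target} outside [{GREEN_ENDPOINT}, {RED_ENDPOINT}]")
    rng = np.random.default_rng(seed)
    if start is None:
        start = float(rng.uniform(290.0 - 45.0, 290.0 + 45.0))
    perceived = target + (sigma_percept * float(rng.standard_normal()) if sigma_percept else 0.0)
    perceived = float(np.clip(perceived, GREEN_ENDPOINT, RED_ENDPOINT))

    max_presses = int(max_duration_s / press_interval_s)
    current = float(start)
    trace = [current]
    accepted = False
    while True:
        err = perceived - current
        if abs(err) <= fine_step / 2.0:
            accepted = True  # space bar; not a charged press
            break
        if len(trace) - 1 >= max_presses:
            break  # 20 s cap reached
        step = coarse_step if abs(err) > coarse_threshold else fine_step
        current = float(np.clip(current + np.sign(err) * step, GREEN_ENDPOINT, RED_ENDPOINT))
        trace.append(current)
    n_presses = len(trace) - 1
    return AdjustmentTrace(
        trace=tuple(trace),
        final=current,
        n_presses=n_presses,
        elapsed_s=n_presses * press_interval_s,
        accepted=accepted,
    )
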