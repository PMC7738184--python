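"""Settings-table I/O, run configuration, and the end-to-end pipeline runner.

The canonical settings schema is one row per individual match::

    observer_id, day, session, phase, test_minute, block, match_index,
    hue_angle_deg, glasses_on, followup

Externally produced tables (e.g. per-figure source-data exports with their
own headers) are ingested through a column map from canonical names to the
file's names; missing optional columns (``followup``, ``match_index``) are
filled with defaults.  Validation rejects hue angles outside the task range
and phase/glasses inconsistencies, naming the offending rows.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .colorspace import GREEN_ENDPOINT, RED_ENDPOINT, HueSetting
from .display import default_monitor, monitor_gamut, synth_red_glasses
from .gain import daily_constancy
from .observer import CohortParams, ObserverParams, ScheduleConfig, simulate_cohort
from .pipeline import analyze_cohort

__all__ = [
    "REQUIRED_COLUMNS",
    "SettingsValidationError",
    "read_settings",
    "write_settings",
    "RunConfig",
    "run_pipeline",
]

log = logging.getLogger("chromadapt")

REQUIRED_COLUMNS = (
    "observer_id", "day", "session", "phase", "test_minute",
    "block", "hue_angle_deg", "glasses_on",
)
OPTIONAL_DEFAULTS = {"match_index": 1, "followup": False}


class SettingsValidationError(ValueError):
    """A settings table violates the schema; message lists offenders."""


def _validate(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SettingsValidationError(f"missing required columns: {missing}")
    for col, default in OPTIONAL_DEFAULTS.items():
        if col not in df.columns:
            df[col] = default
    bad_hue = df.index[
        (df["hue_angle_deg"] < GREEN_ENDPOINT) | (df["hue_angle_deg"] > RED_ENDPOINT)
        | df["hue_angle_deg"].isna()
    ]
    if len(bad_hue):
        raise SettingsValidationError(
            f"hue_angle_deg outside [{GREEN_ENDPOINT}, {RED_ENDPOINT}] "
            f"in rows {list(bad_hue[:20])}"
        )
    df["glasses_on"] = df["glasses_on"].astype(bool)
    df["followup"] = df["followup"].astype(bool)
    inconsistent = df.index[df["glasses_on"] != (df["phase"] == "on")]
    if len(inconsistent):
        raise SettingsValidationError(
            f"glasses_on inconsistent with phase in rows {list(inconsistent[:20])}"
        )
    return df


def read_settings(path: str | Path, column_map: dict[str, str] | None = None) -> pd.DataFrame:
    """Load and validate a settings CSV.

    ``column_map`` maps canonical column names to the file's column names,
    which lets deposited source-data dialects load without rewriting.
    """
    df = pd.read_csv(path)
    if column_map:
        rename = {src: canon for canon, src in column_map.items() if src in df.columns}
        df = df.rename(columns=rename)
    return _validate(df)


def write_settings(df: pd.DataFrame, path: str | Path) -> Path:
    """Write a settings table plus a ``.meta`` YAML sidecar with provenance."""
    path = Path(path)
    df.to_csv(path, index=False)
    meta: dict = {"version": __version__, "n_rows": int(len(df))}
    if "seed" in df.attrs:
        meta["seed"] = df.attrs["seed"]
    if "cohort" in df.attrs:
        meta["cohort"] = _plain(df.attrs["cohort"])
    if "schedule" in df.attrs:
        meta["schedule"] = _plain(df.attrs["schedule"])
    if "truth" in df.attrs:
        meta["truth"] = df.attrs["truth"].to_dict(orient="records")
    path.with_suffix(path.suffix + ".meta").write_text(yaml.safe_dump(meta, sort_keys=True))
    return path


# ------------------------------------------------------------------ run config
@dataclass(frozen=True)
class RunConfig:
    """Everything a reproducible pipeline run depends on."""

    input_settings: str | None = None   # None -> simulate
    column_map: dict | None = None
    output_dir: str = "chromadapt_out"
    statistic_kind: str = "mean_all_blocks"
    model_form: str = "pooled"
    baseline_correction: bool = True
    schedule: dict = field(default_factory=dict)   # ScheduleConfig overrides
    cohort: dict = field(default_factory=dict)     # CohortParams overrides
    glasses: dict = field(default_factory=dict)    # synth_red_glasses overrides
    monitor: dict = field(default_factory=dict)    # default_monitor overrides
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def hash(self) -> str:
        """Stable digest of the configuration; changes iff any field changes."""
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _plain(obj):
    """Recursively convert numpy/dataclass values to YAML-safe builtins."""
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _plain(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="records")
    if isinstance(obj, float) and not np.isfinite(obj):
        return str(obj)
    return obj


def _report_to_text(report: dict) -> str:
    lines = ["chromadapt pipeline report", "=" * 30]
    lines.append(f"statistic kind: {report['statistic_kind']}")
    lines.append(f"grand within-session slope: {report['grand_slope']:.2f} deg/hr")
    a = report["slope_anova"]
    lines.append(
        f"slope ANOVA: F({a.df1},{a.df2}) = {a.f_stat:.2f}, p = {a.p_value:.3f}"
    )
    for key, label in [
        ("baseline_trend", "baseline trend"),
        ("rapid_trend", "rapid-adjustment trend"),
        ("total_trend", "total-adaptation trend"),
        ("aftereffect_trend", "aftereffect trend"),
    ]:
        tfit = report[key]
        lines.append(
            f"{label}: {tfit.slope:+.2f} deg/day "
            f"[{tfit.ci_low:.2f}, {tfit.ci_high:.2f}], t = {tfit.t_stat:.2f}, "
            f"p = {tfit.p_value:.2g} ({tfit.model_form}, df = {tfit.df})"
        )
    if "retention" in report:
        r = report["retention"]
        lines.append(f"retention at follow-up: {100 * r.fraction:.0f}%")
        c = report["retest"]
        lines.append(f"test-retest r: {c.r:.2f} (p = {c.p_value:.3g}, n = {c.n})")
        t1 = report["followup_vs_day1"]
        lines.append(f"follow-up vs day 1: t({t1.df}) = {t1.t_stat:.2f}, p = {t1.p_value:.2g}")
        t5 = report["followup_vs_day5"]
        lines.append(f"follow-up vs day 5: t({t5.df}) = {t5.t_stat:.2f}, p = {t5.p_value:.2g}")
    return "\n".join(lines) + "\n"


def run_pipeline(config: RunConfig) -> dict:
    """Simulate (optionally), analyse, and write the report bundle.

    Writes per-stage CSVs, ``report.yaml`` + ``report.txt``, and
    ``run.log`` carrying the seed, package version and config hash, into
    ``config.output_dir``.  A rerun with the same config reproduces the
    bundle exactly.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(config.log_level)
    try:
        log.info("chromadapt %s, config hash %s, seed %d", __version__, config.hash(), config.seed)
        if config.input_settings:
            records = read_settings(config.input_settings, config.column_map)
            log.info("loaded %d matches from %s", len(records), config.input_settings)
        else:
            sched = ScheduleConfig(**config.schedule)
            cohort_kwargs = dict(config.cohort)
            mean_overrides = cohort_kwargs.pop("means", {})
            cohort = CohortParams(
                means=ObserverParams(**mean_overrides), seed=config.seed, **cohort_kwargs
            )
            records = simulate_cohort(cohort, sched)
            write_settings(records, outdir / "settings.csv")
            log.info("simulated %d matches (seed %d)", len(records), config.seed)

        report = analyze_cohort(records, config.statistic_kind, config.model_form)

        mon = default_monitor(**config.monitor)
        filt = synth_red_glasses(**config.glasses)
        constancy = daily_constancy(report["tables"]["summaries"], mon, filt)
        report["constancy"] = constancy

        tables = report["tables"]
        tables["summaries"].to_csv(outdir / "summaries.csv", index=False)
        tables["corrected"].to_csv(outdir / "summaries_corrected.csv", index=False)
        tables["session_slopes"].to_csv(outdir / "session_slopes.csv", index=False)
        constancy.to_csv(outdir / "constancy.csv", index=False)
        pd.DataFrame(monitor_gamut(mon), columns=["x", "y"]).to_csv(
            outdir / "gamut_unfiltered.csv", index=False
        )
        pd.DataFrame(monitor_gamut(mon, filt), columns=["x", "y"]).to_csv(
            outdir / "gamut_filtered.csv", index=False
        )

        machine = {
            k: _plain(v) for k, v in report.items() if k != "tables"
        }
        machine["meta"] = {
            "version": __version__, "seed": config.seed, "config_hash": config.hash(),
            "config": _plain(dataclasses.asdict(config)),
        }
        (outdir / "report.yaml").write_text(yaml.safe_dump(machine, sort_keys=True))
        (outdir / "report.txt").write_text(_report_to_text(report))
        log.info("report bundle written to %s", outdir)
        return report
    finally:
        log.removeHandler(handler)
        handler.close()
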