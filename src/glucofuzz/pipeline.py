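"""End-to-end analysis pipeline.

Given a measurement table (a CSV on disk, a packaged fixture, or an
in-memory DataFrame), the pipeline estimates glucose from the channel
voltages (or passes the device estimate through), classifies every
(reference, estimate) pair on the Clarke grid, computes the continuous
severity score, runs the Mamdani system to predict a relative error, and
converts that to an absolute ± interval around the estimate.  The result
is an augmented per-row table, a zone report, and a deterministic summary.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import calibration as cal
from . import ceg
from .errors import InputFormatError, InvalidInputError
from .fixtures import load_fixture
from .fuzzy import FuzzySystemSpec, default_system, predict_error

logger = logging.getLogger(__name__)

RESULT_COLUMNS = cal.SCHEMA_COLUMNS + [
    "estimated_glucose",
    "zone",
    "severity",
    "predicted_error_percent",
    "interval_low",
    "interval_high",
]

#: Convention for converting the % error into a ± interval half-width.
ERROR_CONVENTION = "relative"  # half-width = estimate * error / 100


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    input_path: Optional[str] = None
    fixture: Optional[str] = None
    channels: tuple[str, ...] = ("finger",)
    target: str = "reference_glucose"
    passthrough: bool = False
    fuzzy_spec: Optional[FuzzySystemSpec] = None
    axis_max: float = ceg.DEFAULT_AXIS_MAX
    out_dir: Optional[str] = None

    def __post_init__(self) -> None:
        if (self.input_path is None) == (self.fixture is None):
            raise InvalidInputError("provide exactly one of input_path or fixture")
        if self.input_path is not None and not Path(self.input_path).exists():
            raise InvalidInputError(f"input path {self.input_path!r} does not exist")


@dataclass
class AnalysisResult:
    """Augmented rows, zone occupancy and a JSON-serialisable summary."""

    rows: pd.DataFrame
    report: ceg.ZoneReport
    summary: dict
    model: Optional[cal.CalibrationModel] = None


def _load_input(config: RunConfig) -> pd.DataFrame:
    if config.fixture is not None:
        df = load_fixture(config.fixture)
        if config.fixture == "table2":
            # table2 lacks demographics; pad to the common schema
            df = df.assign(age=np.nan, gender="", diabetic=False, fasting=False)
        return cal.normalize_table(df[cal.SCHEMA_COLUMNS])
    return cal.read_measurements_csv(config.input_path)


def run_analysis(config: RunConfig) -> AnalysisResult:
    """Run calibration → Clarke classification → fuzzy error prediction."""
    df = _load_input(config)
    if df.empty:
        raise InvalidInputError("input table is empty")
    logger.info("loaded %d measurement rows", len(df))

    model: Optional[cal.CalibrationModel] = None
    if config.passthrough:
        if df["device_glucose"].isna().any():
            raise InputFormatError("passthrough requires device_glucose on every row")
        estimates = df["device_glucose"].to_numpy(dtype=float)
    else:
        model = cal.fit(df, channels=config.channels, target=config.target)
        estimates = model.predict_many(df)
        logger.info(
            "fit calibration on %s: intercept=%.3f coefficients=%s",
            ",".join(config.channels),
            model.intercept,
            model.coefficients,
        )

    spec = config.fuzzy_spec or default_system()
    zones, severities, errors = [], [], []
    refs = df["reference_glucose"].to_numpy(dtype=float)
    volts = df["v_finger"].to_numpy(dtype=float)
    for ref_val, est, v in zip(refs, estimates, volts):
        pair = ceg.GlucosePair(float(ref_val), float(est))
        zones.append(ceg.classify(pair))
        sev = ceg.severity(pair, axis_max=config.axis_max)
        severities.append(sev)
        errors.append(predict_error(spec, float(v), sev))

    rows = df.copy()
    rows["estimated_glucose"] = estimates
    rows["zone"] = zones
    rows["severity"] = severities
    rows["predicted_error_percent"] = errors
    half = rows["estimated_glucose"] * rows["predicted_error_percent"] / 100.0
    rows["interval_low"] = rows["estimated_glucose"] - half
    rows["interval_high"] = rows["estimated_glucose"] + half
    logger.info("classified %d rows; zones: %s", len(rows), pd.Series(zones).value_counts().to_dict())

    report = ceg.zone_report(
        list(zip(rows["reference_glucose"], rows["estimated_glucose"]))
    )
    summary = {
        "n": report.n,
        "zone_counts": report.counts,
        "zone_percents": report.percents,
        "error_convention": ERROR_CONVENTION,
        "mean_predicted_error_percent": float(np.mean(errors)),
        "max_predicted_error_percent": float(np.max(errors)),
        "channels": list(config.channels),
        "passthrough": config.passthrough,
        "calibration": None
        if model is None
        else {
            "intercept": model.intercept,
            "coefficients": model.coefficients,
            "target": model.target,
            "residual_mean_abs": model.residual_mean_abs,
        },
    }

    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        rows.round(6).to_csv(out / "results.csv", index=False)
        report.to_csv(out / "zone_report.csv")
        (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return AnalysisResult(rows=rows, report=report, summary=summary, model=model)


def format_interval(estimate: float, error_percent: float) -> str:
    """Display form of an estimate with its predicted ± half-width in mg/dL."""
    half = round(estimate * error_percent / 100.0)
    return f"{round(estimate)} ± {half:.0f}"


def summarize_group_ranges(records: pd.DataFrame) -> dict[str, Optional[tuple[float, float]]]:
    """Fingertip-voltage (min, max) per diabetic/healthy group.

    Accepts raw fixture frames (``Pos``/``Neg`` flags) or normalised ones.
    An absent group is reported as ``None`` with a warning.
    """
    if records.empty:
        raise InvalidInputError("no records")
    if "diabetic" not in records.columns or "v_finger" not in records.columns:
        raise InputFormatError("records need diabetic and v_finger columns")
    flags = records["diabetic"].map(cal.coerce_flag)
    out: dict[str, Optional[tuple[float, float]]] = {}
    for name, mask in (("healthy", ~flags), ("diabetic", flags)):
        if mask.any():
            v = records.loc[mask, "v_finger"].astype(float)
            out[name] = (float(v.min()), float(v.max()))
        else:
            logger.warning("group %s absent from records", name)
            out[name] = None
    return out
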