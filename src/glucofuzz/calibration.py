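"""Voltage → glucose calibration.

The photodetector chain outputs an analog voltage proportional to received
light, so the minimal calibration consistent with the hardware is affine in
the channel voltages.  Models can use the fingertip channel, the tear
channel, or a joint two-channel fit (glucose ~ 1 + v_finger + v_tear);
fitting is ordinary least squares against either the reference-device
glucose (default) or the device's own displayed estimate.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, asdict
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateFitError, InputFormatError, InvalidInputError

logger = logging.getLogger(__name__)

CHANNELS = ("finger", "tear")
CHANNEL_COLUMNS = {"finger": "v_finger", "tear": "v_tear"}

#: Fixed CSV schema for measurement tables (one row per reading).
SCHEMA_COLUMNS = [
    "reference_glucose",
    "v_finger",
    "v_tear",
    "age",
    "device_glucose",
    "gender",
    "diabetic",
    "fasting",
]

_TRUTHY = {"true", "yes", "pos", "1", "t", "y"}
_FALSY = {"false", "no", "neg", "0", "f", "n"}


@dataclass(frozen=True)
class MeasurementRecord:
    """One measurement row: reference glucose, channel voltages, demographics."""

    reference_glucose: float
    v_finger: float
    v_tear: float
    age: float
    gender: str
    diabetic: bool
    fasting: bool
    device_glucose: Optional[float] = None

    def __post_init__(self) -> None:
        if not (math.isfinite(self.reference_glucose) and self.reference_glucose > 0):
            raise InvalidInputError(
                f"reference_glucose must be > 0, got {self.reference_glucose}"
            )
        for name in ("v_finger", "v_tear"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v >= 0):
                raise InvalidInputError(f"{name} must be >= 0 V, got {v}")
        if self.device_glucose is not None and not (
            math.isfinite(self.device_glucose) and self.device_glucose > 0
        ):
            raise InvalidInputError(
                f"device_glucose must be > 0, got {self.device_glucose}"
            )


def coerce_flag(value) -> bool:
    """Parse a diabetic/fasting flag from bool or Pos/Neg, Yes/No, True/False."""
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    s = str(value).strip().lower()
    if s in _TRUTHY:
        return True
    if s in _FALSY:
        return False
    raise InputFormatError(f"cannot parse boolean flag from {value!r}")


def normalize_table(df: pd.DataFrame) -> pd.DataFrame:
    """Validate the fixed schema and coerce flag columns to booleans."""
    missing = [c for c in SCHEMA_COLUMNS if c not in df.columns]
    if missing:
        raise InputFormatError(f"missing columns: {missing}")
    out = df.copy()
    for col in ("diabetic", "fasting"):
        out[col] = out[col].map(coerce_flag)
    for col in ("reference_glucose", "v_finger", "v_tear", "age", "device_glucose"):
        out[col] = pd.to_numeric(out[col], errors="coerce")
    return out


def read_measurements_csv(path) -> pd.DataFrame:
    """Read a measurement table CSV and validate/normalise its schema."""
    return normalize_table(pd.read_csv(path))


def write_measurements_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, columns=SCHEMA_COLUMNS)


def records_from_frame(df: pd.DataFrame) -> list[MeasurementRecord]:
    df = normalize_table(df)
    out = []
    for row in df.itertuples(index=False):
        dg = getattr(row, "device_glucose")
        out.append(
            MeasurementRecord(
                reference_glucose=float(row.reference_glucose),
                v_finger=float(row.v_finger),
                v_tear=float(row.v_tear),
                age=float(row.age),
                gender=str(row.gender),
                diabetic=bool(row.diabetic),
                fasting=bool(row.fasting),
                device_glucose=None if pd.isna(dg) else float(dg),
            )
        )
    return out


@dataclass(frozen=True)
class CalibrationModel:
    """Affine voltage→glucose map with its fit-residual summary.

    ``coefficients`` holds one slope (mg/dL per volt) per included channel,
    keyed by ``"finger"``/``"tear"``.
    """

    intercept: float
    coefficients: dict[str, float]
    target: str = "reference_glucose"
    residual_mean_abs: float = float("nan")
    residual_max_abs: float = float("nan")

    def __post_init__(self) -> None:
        if not self.coefficients:
            raise InvalidInputError("model needs at least one channel")
        bad = set(self.coefficients) - set(CHANNELS)
        if bad:
            raise InvalidInputError(f"unknown channels {sorted(bad)}")
        if not all(math.isfinite(v) for v in self.coefficients.values()):
            raise InvalidInputError("non-finite coefficient")

    def predict(
        self, v_finger: Optional[float] = None, v_tear: Optional[float] = None
    ) -> float:
        """Estimated glucose (mg/dL), clipped below at 1 mg/dL."""
        volts = {"finger": v_finger, "tear": v_tear}
        g = self.intercept
        for ch, coef in self.coefficients.items():
            if volts[ch] is None:
                raise InvalidInputError(f"model requires channel {ch!r}")
            g += coef * float(volts[ch])
        if g < 1.0:
            logger.warning("prediction %.3g mg/dL clipped to 1 mg/dL", g)
            return 1.0
        return float(g)

    def predict_many(self, df: pd.DataFrame) -> np.ndarray:
        g = np.full(len(df), self.intercept, dtype=float)
        for ch, coef in self.coefficients.items():
            g += coef * df[CHANNEL_COLUMNS[ch]].to_numpy(dtype=float)
        n_clip = int((g < 1.0).sum())
        if n_clip:
            logger.warning("%d predictions clipped to 1 mg/dL", n_clip)
        return np.maximum(g, 1.0)

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, text: str) -> "CalibrationModel":
        return cls(**json.loads(text))


def fit(
    records: pd.DataFrame | Sequence[MeasurementRecord],
    channels: Iterable[str] = ("finger",),
    target: str = "reference_glucose",
) -> CalibrationModel:
    """Ordinary-least-squares affine fit of glucose on channel voltages.

    Requires at least ``len(channels) + 2`` rows and a full-rank design
    (constant voltages raise :class:`DegenerateFitError`).
    """
    channels = tuple(channels)
    if not channels or any(ch not in CHANNELS for ch in channels):
        raise InvalidInputError(f"channels must be a subset of {CHANNELS}")
    if target not in ("reference_glucose", "device_glucose"):
        raise InvalidInputError(f"unknown fit target {target!r}")

    if not isinstance(records, pd.DataFrame):
        records = pd.DataFrame([asdict(r) for r in records])
    y = pd.to_numeric(records[target], errors="coerce").to_numpy(dtype=float)
    cols = [CHANNEL_COLUMNS[ch] for ch in channels]
    X = np.column_stack(
        [np.ones(len(records))]
        + [records[c].to_numpy(dtype=float) for c in cols]
    )
    keep = np.isfinite(y) & np.isfinite(X).all(axis=1)
    X, y = X[keep], y[keep]

    n, p = X.shape
    if n < len(channels) + 2:
        raise DegenerateFitError(
            f"need at least {len(channels) + 2} rows, got {n}"
        )
    if np.linalg.matrix_rank(X) < p:
        raise DegenerateFitError("rank-deficient design (constant voltages?)")

    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return CalibrationModel(
        intercept=float(beta[0]),
        coefficients={ch: float(b) for ch, b in zip(channels, beta[1:])},
        target=target,
        residual_mean_abs=float(np.mean(np.abs(resid))),
        residual_max_abs=float(np.max(np.abs(resid))),
    )
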