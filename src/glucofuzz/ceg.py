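"""Clarke Error Grid (CEG) zone analysis.

The Clarke error grid partitions the (reference glucose, estimated glucose)
plane into five zones grading the clinical consequence of a measurement
error: A (clinically accurate: within 20% of the reference, or both
readings in the hypoglycaemic band below 70 mg/dL), B (benign deviation),
and C, D, E (increasingly dangerous misreadings).  This module classifies
reading pairs, derives the continuous "severity" score in [0, 1] that the
fuzzy error model uses as its second input (0 on the identity line, 1 deep
in zone E), and summarises zone occupancy for a set of pairs.

Zone inequalities follow the standard 1987 formulation.  They are evaluated
in the fixed order A, E, C, D, else B with non-strict comparisons, so exact
boundary points classify deterministically.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import InvalidInputError

ZONES = ("A", "B", "C", "D", "E")
ZONE_INDEX = {z: i for i, z in enumerate(ZONES)}

#: Upper bound of the estimate axis used for severity normalisation (mg/dL).
DEFAULT_AXIS_MAX = 600.0

#: Sanity bound on glucose values (mg/dL); values above are rejected.
GLUCOSE_SANITY_MAX = 1000.0


@dataclass(frozen=True)
class GlucosePair:
    """One (reference, estimate) glucose reading pair in mg/dL."""

    reference: float
    estimate: float

    def __post_init__(self) -> None:
        for field in ("reference", "estimate"):
            v = getattr(self, field)
            if not (isinstance(v, (int, float)) and math.isfinite(v)):
                raise InvalidInputError(f"{field} must be finite, got {v!r}")
            if v <= 0:
                raise InvalidInputError(f"{field} must be > 0 mg/dL, got {v}")
            if v > GLUCOSE_SANITY_MAX:
                raise InvalidInputError(
                    f"{field} = {v} mg/dL exceeds the sanity bound "
                    f"{GLUCOSE_SANITY_MAX}"
                )


def _as_pair(pair: GlucosePair | tuple[float, float]) -> GlucosePair:
    if isinstance(pair, GlucosePair):
        return pair
    return GlucosePair(*pair)


def classify(pair: GlucosePair | tuple[float, float]) -> str:
    """Assign a pair to exactly one Clarke zone.

    Parameters
    ----------
    pair
        ``GlucosePair`` or plain ``(reference, estimate)`` tuple in mg/dL.

    Returns
    -------
    str
        One of ``"A".."E"``.
    """
    p = _as_pair(pair)
    r, e = p.reference, p.estimate
    if (e <= 70 and r <= 70) or (0.8 * r <= e <= 1.2 * r):
        return "A"
    if (r >= 180 and e <= 70) or (r <= 70 and e >= 180):
        return "E"
    if (70 <= r <= 290 and e >= r + 110) or (130 <= r <= 180 and e <= 1.4 * r - 182):
        return "C"
    if (r >= 240 and 70 <= e <= 180) or (r <= 70 and 70 <= e <= 180):
        return "D"
    return "B"


def classify_many(
    reference: np.ndarray, estimate: np.ndarray
) -> np.ndarray:
    """Vectorised :func:`classify` over equal-length arrays (mg/dL).

    Returns an array of single-character zone labels.  Inputs are validated
    collectively; the same inequality chain is applied with first-match-wins
    precedence A, E, C, D, else B.
    """
    r = np.asarray(reference, dtype=float)
    e = np.asarray(estimate, dtype=float)
    if r.shape != e.shape:
        raise InvalidInputError("reference and estimate shapes differ")
    bad = ~np.isfinite(r) | ~np.isfinite(e) | (r <= 0) | (e <= 0)
    if bad.any():
        raise InvalidInputError("non-finite or non-positive glucose value")
    if (r > GLUCOSE_SANITY_MAX).any() or (e > GLUCOSE_SANITY_MAX).any():
        raise InvalidInputError("glucose value exceeds the sanity bound")

    a = ((e <= 70) & (r <= 70)) | ((0.8 * r <= e) & (e <= 1.2 * r))
    ez = ((r >= 180) & (e <= 70)) | ((r <= 70) & (e >= 180))
    c = ((70 <= r) & (r <= 290) & (e >= r + 110)) | (
        (130 <= r) & (r <= 180) & (e <= 1.4 * r - 182)
    )
    d = ((r >= 240) & (70 <= e) & (e <= 180)) | ((r <= 70) & (70 <= e) & (e <= 180))

    # np.select honours first-match precedence A, E, C, D, else B
    return np.select([a, ez, c, d], ["A", "E", "C", "D"], default="B").astype("<U1")


def zone_intervals(
    reference: float, axis_max: float = DEFAULT_AXIS_MAX
) -> list[tuple[float, float, str]]:
    """Partition the estimate axis at a fixed reference into labelled intervals.

    Returns a list of ``(lo, hi, zone)`` triples with ``lo`` of the first
    interval equal to 0 and ``hi`` of the last equal to ``axis_max``;
    intervals are contiguous, non-overlapping, and their labels agree with
    :func:`classify` at every interior point.  Labels on the shared endpoint
    of two intervals follow the classifier's first-match tie-break.
    """
    if not (isinstance(reference, (int, float)) and math.isfinite(reference)):
        raise InvalidInputError(f"reference must be finite, got {reference!r}")
    if reference <= 0:
        raise InvalidInputError(f"reference must be > 0 mg/dL, got {reference}")
    r = float(reference)
    cuts = {70.0, 180.0, 0.8 * r, 1.2 * r, r + 110.0, 1.4 * r - 182.0}
    pts = sorted({axis_max} | {c for c in cuts if 0.0 < c < axis_max})
    edges = [0.0] + pts
    intervals: list[tuple[float, float, str]] = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        mid = 0.5 * (lo + hi)
        label = classify(GlucosePair(r, min(mid, GLUCOSE_SANITY_MAX)))
        if intervals and intervals[-1][2] == label:
            intervals[-1] = (intervals[-1][0], hi, label)
        else:
            intervals.append((lo, hi, label))
    return intervals


def severity(
    pair: GlucosePair | tuple[float, float], axis_max: float = DEFAULT_AXIS_MAX
) -> float:
    """Normalised zone position of a pair: 0 on the identity line, → 1 near E.

    The score is ``(z + d) / 5`` where ``z`` is the zone's ordinal index
    (A=0 .. E=4) and ``d ∈ [0, 1)`` the fractional depth of the estimate
    within its zone's interval on the estimate axis, measured away from the
    identity line.  Within zone A the depth is the distance from the
    identity line relative to the A boundary on the estimate's side, so the
    score is 0 exactly on the identity line.  The result is clipped to
    [0, 1].
    """
    p = _as_pair(pair)
    zone = classify(p)
    z = ZONE_INDEX[zone]
    r, e = p.reference, min(p.estimate, axis_max)
    intervals = zone_intervals(r, axis_max=axis_max)

    # locate the interval with the classifier's label whose closure holds e
    chosen = None
    for lo, hi, label in intervals:
        if label == zone and lo <= e <= hi:
            chosen = (lo, hi)
            break
    if chosen is None:  # boundary point labelled by tie-break: nearest match
        chosen = min(
            ((lo, hi) for lo, hi, label in intervals if label == zone),
            key=lambda iv: min(abs(e - iv[0]), abs(e - iv[1])),
        )
    lo, hi = chosen

    if zone == "A" and lo <= r <= hi:
        if e >= r:
            d = (e - r) / (hi - r) if hi > r else 0.0
        else:
            d = (r - e) / (r - lo) if r > lo else 0.0
    else:
        mid = 0.5 * (lo + hi)
        if mid >= r:  # interval above the identity line: depth grows upward
            d = (e - lo) / (hi - lo)
        else:  # below: depth grows downward
            d = (hi - e) / (hi - lo)
    d = min(max(d, 0.0), math.nextafter(1.0, 0.0))
    return min(max((z + d) / 5.0, 0.0), 1.0)


@dataclass(frozen=True)
class ZoneReport:
    """Zone occupancy summary for a set of glucose pairs."""

    n: int
    counts: dict[str, int]
    percents: dict[str, float]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "zone": list(ZONES),
                "count": [self.counts[z] for z in ZONES],
                "percent": [self.percents[z] for z in ZONES],
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def to_json(self) -> str:
        return json.dumps(
            {"n": self.n, "counts": self.counts, "percents": self.percents}
        )


def zone_report(
    pairs: Iterable[GlucosePair | tuple[float, float]] | Sequence
) -> ZoneReport:
    """Count and percentage per Clarke zone over a non-empty pair list."""
    labels = [classify(p) for p in pairs]
    if not labels:
        raise InvalidInputError("zone_report requires at least one pair")
    n = len(labels)
    counts = {z: labels.count(z) for z in ZONES}
    percents = {z: 100.0 * counts[z] / n for z in ZONES}
    return ZoneReport(n=n, counts=counts, percents=percents)
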