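"""Physics-grounded synthetic sensor and cohort generator.

The forward model chains Bouguer–Lambert attenuation through fingertip
tissue, the photodetector's transimpedance responsivity, and the
non-inverting gain stage:

    mu_a   = mu_a0 + k_abs * glucose
    mu_eff = 2 * mu_a * (mu_a + mu_s')          (printed form; a diffusion
                                                 form sqrt(3*mu_a*(mu_a+mu_s'))
                                                 is also available)
    I      = I0 * exp(-mu_eff * L)
    V      = I * responsivity * (1 + R2/R1)

Default optics and circuit constants are anchored so the chain reproduces
the observed endpoints of the study hardware: 103 mg/dL → 1.22 V and
175 mg/dL → 3.5 V on the fingertip channel, with voltage increasing in
glucose (k_abs < 0).  The cohort generator emulates the study protocol:
30 participants (half diabetic), 12 measurements each at 15-minute
intervals spanning a meal, with per-group glucose distributions truncated
to the reference ranges the study observed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import truncnorm

from .calibration import SCHEMA_COLUMNS
from .errors import ConfigurationError, InvalidInputError

FORMULAS = ("printed", "diffusion")

# hardware constants carried as metadata (no time-domain simulation)
TRANSIMPEDANCE_OHMS = 300_000.0
RC_FILTER = {"r_ohms": 330.0, "c_farads": 10e-6}
EMITTER_WAVELENGTHS_NM = (940.0, 980.0)


@dataclass(frozen=True)
class OpticalProperties:
    """Tissue optics: absorption, reduced scattering (mm⁻¹) and path (mm)."""

    mu_a: float
    mu_s_prime: float
    path_length: float

    def __post_init__(self) -> None:
        for name in ("mu_a", "mu_s_prime", "path_length"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v >= 0):
                raise InvalidInputError(f"{name} must be >= 0, got {v}")


@dataclass(frozen=True)
class CircuitParams:
    """Source intensity, detector responsivity and gain-stage resistors."""

    source_intensity: float  # I0, arbitrary optical power units
    responsivity: float  # volts per intensity unit after the 300 kΩ stage
    r1: float  # ohms
    r2: float  # ohms
    pwm_frequency: float = 1000.0  # Hz, metadata
    wavelength_nm: float = 940.0  # metadata

    def __post_init__(self) -> None:
        if not self.source_intensity > 0:
            raise InvalidInputError("source_intensity must be > 0")
        if not self.responsivity > 0:
            raise InvalidInputError("responsivity must be > 0")
        if not self.r1 > 0:
            raise InvalidInputError("r1 must be > 0")
        if self.r2 < 0:
            raise InvalidInputError("r2 must be >= 0")


@dataclass(frozen=True)
class GlucoseOpticsMap:
    """Linear glucose→absorption map: mu_a = mu_a0 + k_abs * glucose."""

    mu_a0: float  # mm⁻¹
    k_abs: float  # mm⁻¹ per (mg/dL)

    def __post_init__(self) -> None:
        if not (math.isfinite(self.mu_a0) and self.mu_a0 >= 0):
            raise InvalidInputError(f"mu_a0 must be >= 0, got {self.mu_a0}")


def mu_eff(props: OpticalProperties, formula: str = "printed") -> float:
    """Effective attenuation coefficient (mm⁻¹).

    ``printed`` mode computes ``2·μa·(μa+μs′)``; ``diffusion`` mode the
    standard diffusion-theory form ``sqrt(3·μa·(μa+μs′))``.
    """
    if formula not in FORMULAS:
        raise InvalidInputError(f"formula must be one of {FORMULAS}")
    prod = props.mu_a * (props.mu_a + props.mu_s_prime)
    if formula == "printed":
        return 2.0 * prod
    return math.sqrt(3.0 * prod)


def transmitted_intensity(
    props: OpticalProperties, I0: float, formula: str = "printed"
) -> float:
    """Bouguer–Lambert transmitted intensity I = I0·exp(−μeff·L)."""
    if not I0 > 0:
        raise InvalidInputError(f"I0 must be > 0, got {I0}")
    return I0 * math.exp(-mu_eff(props, formula) * props.path_length)


def amplifier_gain(r1: float, r2: float) -> float:
    """Non-inverting gain G = 1 + R2/R1."""
    if not r1 > 0:
        raise InvalidInputError(f"r1 must be > 0, got {r1}")
    if r2 < 0:
        raise InvalidInputError(f"r2 must be >= 0, got {r2}")
    return 1.0 + r2 / r1


def glucose_to_voltage(
    glucose: float,
    gmap: GlucoseOpticsMap,
    props_base: OpticalProperties,
    circuit: CircuitParams,
    formula: str = "printed",
) -> float:
    """Deterministic forward chain from glucose (mg/dL) to sensor volts."""
    mu_a = gmap.mu_a0 + gmap.k_abs * glucose
    if mu_a < 0:
        raise InvalidInputError(
            f"glucose {glucose} mg/dL drives mu_a negative under this map"
        )
    props = OpticalProperties(mu_a, props_base.mu_s_prime, props_base.path_length)
    intensity = transmitted_intensity(props, circuit.source_intensity, formula)
    return intensity * circuit.responsivity * amplifier_gain(circuit.r1, circuit.r2)


def voltage_to_glucose(
    voltage: float,
    gmap: GlucoseOpticsMap,
    props_base: OpticalProperties,
    circuit: CircuitParams,
    formula: str = "printed",
    glucose_bounds: tuple[float, float] = (40.0, 400.0),
) -> float:
    """Numeric inverse of the monotone forward chain (clipped to the bounds)."""
    lo, hi = glucose_bounds
    v_lo = glucose_to_voltage(lo, gmap, props_base, circuit, formula)
    v_hi = glucose_to_voltage(hi, gmap, props_base, circuit, formula)
    v_min, v_max = min(v_lo, v_hi), max(v_lo, v_hi)
    v = min(max(voltage, v_min), v_max)
    if v == v_lo:
        return lo
    if v == v_hi:
        return hi
    return brentq(
        lambda g: glucose_to_voltage(g, gmap, props_base, circuit, formula) - v,
        lo,
        hi,
        xtol=1e-9,
    )


# ---------------------------------------------------------------------------
# default sensor: anchored to the observed fingertip endpoints
# ---------------------------------------------------------------------------

#: Table-derived anchor points (glucose mg/dL, fingertip volts).
ANCHOR_LOW = (103.0, 1.22)
ANCHOR_HIGH = (175.0, 3.5)

_DEFAULT_MU_A0 = 0.8  # mm⁻¹
_DEFAULT_MU_S_PRIME = 2.4  # mm⁻¹
_DEFAULT_PATH_MM = 2.0
_DEFAULT_I0 = 30.0  # TP808 rated 30 mW
_DEFAULT_R1 = 10_000.0
_DEFAULT_R2 = 20_000.0


def default_sensor(
    formula: str = "printed",
) -> tuple[GlucoseOpticsMap, OpticalProperties, CircuitParams]:
    """Default optics map, base properties and circuit, solved once so the
    forward chain passes through both anchor points."""
    g1, v1 = ANCHOR_LOW
    g2, v2 = ANCHOR_HIGH
    mu_s, L = _DEFAULT_MU_S_PRIME, _DEFAULT_PATH_MM

    def attenuation_exponent(mu_a: float) -> float:
        p = OpticalProperties(mu_a, mu_s, L)
        return mu_eff(p, formula) * L

    def gap(k: float) -> float:
        # log-ratio of anchor voltages fixed by the attenuation difference
        e1 = attenuation_exponent(_DEFAULT_MU_A0 + k * g1)
        e2 = attenuation_exponent(_DEFAULT_MU_A0 + k * g2)
        return (e1 - e2) - math.log(v2 / v1)

    k_hi = -1e-9
    k_lo = -(_DEFAULT_MU_A0 / g2) * 0.999  # keep mu_a(g2) > 0
    k_abs = brentq(gap, k_lo, k_hi, xtol=1e-15)
    gmap = GlucoseOpticsMap(mu_a0=_DEFAULT_MU_A0, k_abs=k_abs)
    props = OpticalProperties(_DEFAULT_MU_A0, mu_s, L)
    gain = amplifier_gain(_DEFAULT_R1, _DEFAULT_R2)
    scale = v1 / (
        _DEFAULT_I0 * math.exp(-attenuation_exponent(_DEFAULT_MU_A0 + k_abs * g1)) * gain
    )
    circuit = CircuitParams(
        source_intensity=_DEFAULT_I0,
        responsivity=scale,
        r1=_DEFAULT_R1,
        r2=_DEFAULT_R2,
    )
    return gmap, props, circuit


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

#: Post-meal glucose excursion (mg/dL) over the 12-point, 15-minute protocol:
#: four fasting/pre-meal readings, then a hump peaking ~45 min after the meal.
DEFAULT_MEAL_OFFSETS = (0, 0, 0, 0, 5, 10, 10, 8, 6, 4, 2, 1)


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of one synthetic study cohort."""

    n_participants: int = 30
    diabetic_fraction: float = 0.5
    repeats_per_participant: int = 12
    interval_minutes: float = 15.0
    healthy_mean: float = 115.0
    healthy_sd: float = 10.0
    diabetic_mean: float = 165.0
    diabetic_sd: float = 10.0
    # truncation to the reference ranges observed in the study cohort
    healthy_range: tuple[float, float] = (100.0, 130.0)
    diabetic_range: tuple[float, float] = (150.0, 180.0)
    meal_offsets: Optional[Sequence[float]] = None
    glucose_noise_sd: float = 2.0
    voltage_noise_sd: float = 0.03
    tear_slope: float = 1.3
    tear_offset: float = -0.25
    tear_noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 2:
            raise ConfigurationError("n_participants must be >= 2")
        if self.repeats_per_participant < 1:
            raise ConfigurationError("repeats_per_participant must be >= 1")
        if not 0.0 <= self.diabetic_fraction <= 1.0:
            raise ConfigurationError("diabetic_fraction must be in [0, 1]")
        for name in (
            "healthy_sd",
            "diabetic_sd",
            "glucose_noise_sd",
            "voltage_noise_sd",
            "tear_noise_sd",
        ):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float, size: int
) -> np.ndarray:
    if sd == 0:
        return np.full(size, np.clip(mean, lo, hi))
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def generate_cohort(
    spec: CohortSpec,
    gmap: Optional[GlucoseOpticsMap] = None,
    props_base: Optional[OpticalProperties] = None,
    circuit: Optional[CircuitParams] = None,
    formula: str = "printed",
) -> pd.DataFrame:
    """Simulate one cohort and return a measurement table (fixed schema).

    Per participant a baseline glucose is drawn from the group's truncated
    normal; each repeat adds the meal-offset profile plus Gaussian noise,
    clipped back to the group range.  Fingertip voltage comes from the
    forward optical chain plus additive noise; the tear channel is an affine
    function of the fingertip voltage plus noise; the device-displayed
    glucose is the chain's numeric inverse applied to the noisy voltage.
    Fully reproducible from ``spec.seed``.
    """
    if gmap is None or props_base is None or circuit is None:
        d_gmap, d_props, d_circ = default_sensor(formula)
        gmap = gmap or d_gmap
        props_base = props_base or d_props
        circuit = circuit or d_circ

    rng = np.random.default_rng(spec.seed)
    n = spec.n_participants
    n_diab = int(round(spec.diabetic_fraction * n))
    diabetic = np.array([i < n_diab for i in range(n)])
    offsets = np.asarray(
        spec.meal_offsets
        if spec.meal_offsets is not None
        else [
            DEFAULT_MEAL_OFFSETS[i % len(DEFAULT_MEAL_OFFSETS)]
            for i in range(spec.repeats_per_participant)
        ],
        dtype=float,
    )[: spec.repeats_per_participant]

    rows = []
    for pid in range(n):
        if diabetic[pid]:
            mean, sd = spec.diabetic_mean, spec.diabetic_sd
            lo, hi = spec.diabetic_range
            age = int(rng.integers(40, 69))
        else:
            mean, sd = spec.healthy_mean, spec.healthy_sd
            lo, hi = spec.healthy_range
            age = int(rng.integers(18, 36))
        baseline = float(_truncated_normal(rng, mean, sd, lo, hi, 1)[0])
        gender = "M" if rng.random() < 0.5 else "F"
        for rep in range(spec.repeats_per_participant):
            g = baseline + offsets[rep] + rng.normal(0.0, spec.glucose_noise_sd)
            g = float(np.clip(g, lo, hi))
            v_true = glucose_to_voltage(g, gmap, props_base, circuit, formula)
            v_finger = v_true + rng.normal(0.0, spec.voltage_noise_sd)
            v_finger = max(v_finger, 0.0)
            v_tear = (
                spec.tear_slope * v_finger
                + spec.tear_offset
                + rng.normal(0.0, spec.tear_noise_sd)
            )
            v_tear = max(v_tear, 0.0)
            device = voltage_to_glucose(v_finger, gmap, props_base, circuit, formula)
            rows.append(
                {
                    "participant": pid,
                    "repeat": rep,
                    "minutes": rep * spec.interval_minutes,
                    "reference_glucose": round(g),
                    "v_finger": round(v_finger, 6),
                    "v_tear": round(v_tear, 6),
                    "age": age,
                    "device_glucose": round(device),
                    "gender": gender,
                    "diabetic": bool(diabetic[pid]),
                    "fasting": bool(offsets[rep] == 0 and rep < len(offsets) // 2),
                }
            )
    df = pd.DataFrame(rows)
    return df[["participant", "repeat", "minutes"] + SCHEMA_COLUMNS]


def write_cohort(df: pd.DataFrame, path, spec: CohortSpec, formula: str = "printed") -> None:
    """Write a cohort CSV plus a JSON sidecar recording seed and parameters."""
    path = Path(path)
    df.to_csv(path, index=False)
    meta = {
        "spec": asdict(spec),
        "formula": formula,
        "transimpedance_ohms": TRANSIMPEDANCE_OHMS,
        "rc_filter": RC_FILTER,
        "emitter_wavelengths_nm": list(EMITTER_WAVELENGTHS_NM),
    }
    meta["spec"]["meal_offsets"] = (
        list(spec.meal_offsets) if spec.meal_offsets is not None else None
    )
    path.with_suffix(".meta.json").write_text(json.dumps(meta, indent=2))
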