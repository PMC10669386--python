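"""From-scratch Mamdani fuzzy inference for glucose error prediction.

The system maps two crisp inputs — the sensor's analog output voltage and
the normalised Clarke-grid position (severity) of the reading — to a crisp
predicted relative error of the glucose estimate, in percent of the
estimate.  Inference is canonical Mamdani: triangular membership functions,
AND = min, implication = min (clipping), aggregation = pointwise max, and
centroid defuzzification over a sampled output universe.

The default system spans the observed sensor range [1.0, 4.5] V with four
evenly spaced voltage labels (LoGl, MiGl, MoGl, HiGl), five Clarke-zone
labels A–E on [0, 1] for the severity input, five A–E labels on [0, 100] %
for the error output, and a complete 4×5 rule grid whose consequent label
equals the Clarke antecedent label ("If Voltage is LoGl and CEG is A then
Error is A", and so on).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
import yaml

from .errors import ConfigurationError, NoRuleFiredError

logger = logging.getLogger(__name__)

VOLTAGE_LABELS = ("LoGl", "MiGl", "MoGl", "HiGl")
CEG_LABELS = ("A", "B", "C", "D", "E")


@dataclass(frozen=True)
class TriangularMF:
    """Triangular membership function with feet ``a``, ``c`` and peak ``b``.

    Degenerate shoulders (``a == b`` or ``b == c``) evaluate as one-sided
    ramps with membership 1 at ``b``; membership is 0 outside ``[a, c]``.
    """

    a: float
    b: float
    c: float

    def __post_init__(self) -> None:
        if not (self.a <= self.b <= self.c):
            raise ConfigurationError(
                f"triangular MF requires a <= b <= c, got {(self.a, self.b, self.c)}"
            )

    def __call__(self, x) -> np.ndarray | float:
        x = np.asarray(x, dtype=float)
        y = np.zeros_like(x)
        if self.b > self.a:
            m = (x > self.a) & (x < self.b)
            y[m] = (x[m] - self.a) / (self.b - self.a)
        if self.c > self.b:
            m = (x > self.b) & (x < self.c)
            y[m] = (self.c - x[m]) / (self.c - self.b)
        y[x == self.b] = 1.0
        return float(y) if y.ndim == 0 else y


def membership(mf: TriangularMF, x: float) -> float:
    """Degree of membership of ``x`` in ``mf`` (total function on the reals)."""
    return float(mf(x))


@dataclass(frozen=True)
class LinguisticVariable:
    """A named variable with an ordered set of labelled triangular MFs."""

    name: str
    lo: float
    hi: float
    mfs: tuple[tuple[str, TriangularMF], ...]

    def __post_init__(self) -> None:
        if not self.lo < self.hi:
            raise ConfigurationError(f"{self.name}: empty domain [{self.lo}, {self.hi}]")
        labels = [lab for lab, _ in self.mfs]
        if len(set(labels)) != len(labels):
            raise ConfigurationError(f"{self.name}: duplicate MF labels")
        for lab, mf in self.mfs:
            if mf.a < self.lo - 1e-12 or mf.c > self.hi + 1e-12:
                raise ConfigurationError(
                    f"{self.name}/{lab}: support [{mf.a}, {mf.c}] outside domain"
                )
        grid = np.linspace(self.lo, self.hi, 1001)
        cover = np.max([mf(grid) for _, mf in self.mfs], axis=0)
        if not (cover > 0).all():
            raise ConfigurationError(f"{self.name}: MFs do not cover the domain")

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(lab for lab, _ in self.mfs)

    def clamp(self, x: float) -> float:
        if x < self.lo or x > self.hi:
            logger.warning(
                "%s input %.6g outside [%g, %g]; clamped", self.name, x, self.lo, self.hi
            )
            return min(max(x, self.lo), self.hi)
        return x


def fuzzify(var: LinguisticVariable, x: float) -> dict[str, float]:
    """Per-label membership degrees of a crisp input, clamped to the domain."""
    xc = var.clamp(float(x))
    return {lab: float(mf(xc)) for lab, mf in var.mfs}


@dataclass(frozen=True)
class FuzzyRule:
    """One IF-THEN rule: one antecedent label per input, one output label."""

    voltage: str
    ceg: str
    error: str


@dataclass(frozen=True)
class FuzzySystemSpec:
    """Two-input / one-output Mamdani system definition.

    Invariant: the rule base covers every (voltage label, CEG label)
    combination exactly once (checked at construction, not at inference).
    """

    voltage: LinguisticVariable
    ceg: LinguisticVariable
    error: LinguisticVariable
    rules: tuple[FuzzyRule, ...]
    resolution: int = 1001

    def __post_init__(self) -> None:
        if self.resolution < 2:
            raise ConfigurationError("resolution must be at least 2")
        if not self.rules:
            raise ConfigurationError("rule base is empty")
        seen = set()
        for rule in self.rules:
            if rule.voltage not in self.voltage.labels:
                raise ConfigurationError(f"unknown voltage label {rule.voltage!r}")
            if rule.ceg not in self.ceg.labels:
                raise ConfigurationError(f"unknown CEG label {rule.ceg!r}")
            if rule.error not in self.error.labels:
                raise ConfigurationError(f"unknown error label {rule.error!r}")
            key = (rule.voltage, rule.ceg)
            if key in seen:
                raise ConfigurationError(f"duplicate rule for antecedent {key}")
            seen.add(key)
        full = {(v, c) for v in self.voltage.labels for c in self.ceg.labels}
        if seen != full:
            missing = sorted(full - seen)
            raise ConfigurationError(f"incomplete rule grid; missing {missing}")

    # ---- serialisation -------------------------------------------------

    def to_dict(self) -> dict:
        def var(v: LinguisticVariable) -> dict:
            return {
                "name": v.name,
                "domain": [v.lo, v.hi],
                "mfs": [{"label": lab, "abc": [mf.a, mf.b, mf.c]} for lab, mf in v.mfs],
            }

        return {
            "voltage": var(self.voltage),
            "ceg": var(self.ceg),
            "error": var(self.error),
            "rules": [[r.voltage, r.ceg, r.error] for r in self.rules],
            "resolution": self.resolution,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FuzzySystemSpec":
        def var(vd: dict) -> LinguisticVariable:
            return LinguisticVariable(
                name=vd["name"],
                lo=float(vd["domain"][0]),
                hi=float(vd["domain"][1]),
                mfs=tuple(
                    (m["label"], TriangularMF(*map(float, m["abc"])))
                    for m in vd["mfs"]
                ),
            )

        return cls(
            voltage=var(d["voltage"]),
            ceg=var(d["ceg"]),
            error=var(d["error"]),
            rules=tuple(FuzzyRule(*r) for r in d["rules"]),
            resolution=int(d["resolution"]),
        )

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "FuzzySystemSpec":
        return cls.from_dict(yaml.safe_load(text))

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_json(cls, text: str) -> "FuzzySystemSpec":
        return cls.from_dict(json.loads(text))


def _even_partition(
    name: str, lo: float, hi: float, labels: tuple[str, ...]
) -> LinguisticVariable:
    """Evenly spaced triangles with touching feet and shoulders at the ends."""
    peaks = np.linspace(lo, hi, len(labels))
    mfs = []
    for i, lab in enumerate(labels):
        a = peaks[i - 1] if i > 0 else lo
        c = peaks[i + 1] if i < len(labels) - 1 else hi
        mfs.append((lab, TriangularMF(float(a), float(peaks[i]), float(c))))
    return LinguisticVariable(name=name, lo=lo, hi=hi, mfs=tuple(mfs))


def default_system(resolution: int = 1001) -> FuzzySystemSpec:
    """The package's default two-input Mamdani error predictor."""
    voltage = _even_partition("voltage", 1.0, 4.5, VOLTAGE_LABELS)
    ceg = _even_partition("ceg_position", 0.0, 1.0, CEG_LABELS)
    error = _even_partition("error_percent", 0.0, 100.0, CEG_LABELS)
    rules = tuple(
        FuzzyRule(v, c, c) for v in VOLTAGE_LABELS for c in CEG_LABELS
    )
    return FuzzySystemSpec(
        voltage=voltage, ceg=ceg, error=error, rules=rules, resolution=resolution
    )


def infer(
    spec: FuzzySystemSpec, voltage: float, ceg_position: float
) -> tuple[np.ndarray, np.ndarray]:
    """Aggregated output membership curve for one crisp input pair.

    Returns ``(xs, mu)``: the sampled output universe and the pointwise-max
    aggregation of all min-clipped rule consequents.
    """
    deg_v = fuzzify(spec.voltage, voltage)
    deg_c = fuzzify(spec.ceg, ceg_position)
    xs = np.linspace(spec.error.lo, spec.error.hi, spec.resolution)
    out_mf = dict(spec.error.mfs)
    agg = np.zeros_like(xs)
    for rule in spec.rules:
        act = min(deg_v[rule.voltage], deg_c[rule.ceg])
        if act > 0.0:
            np.maximum(agg, np.minimum(act, out_mf[rule.error](xs)), out=agg)
    return xs, agg


def defuzzify_centroid(xs: np.ndarray, mu: np.ndarray) -> float:
    """Centre of gravity of the sampled curve: Σ(xᵢ·μᵢ)/Σ(μᵢ)."""
    mu = np.asarray(mu, dtype=float)
    total = mu.sum()
    if total <= 0.0:
        raise NoRuleFiredError("aggregated output curve is identically zero")
    return float(np.dot(xs, mu) / total)


def predict_error(spec: FuzzySystemSpec, voltage: float, severity: float) -> float:
    """Crisp predicted relative error (%) for one (voltage, severity) input."""
    xs, mu = infer(spec, voltage, severity)
    return defuzzify_centroid(xs, mu)
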