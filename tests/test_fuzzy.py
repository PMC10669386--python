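"""Mamdani engine: membership, fuzzification, inference, defuzzification."""

import random

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from glucofuzz import (
    ConfigurationError,
    FuzzySystemSpec,
    LinguisticVariable,
    NoRuleFiredError,
    TriangularMF,
    default_system,
    defuzzify_centroid,
    fuzzify,
    infer,
    membership,
    predict_error,
)


@pytest.mark.parametrize(
    "mf,x,expected",
    [
        (TriangularMF(0, 50, 100), 50, 1.0),  # peak
        (TriangularMF(0, 50, 100), 125, 0.0),  # outside support
        (TriangularMF(0, 50, 100), -10, 0.0),
        (TriangularMF(0, 50, 100), 25, 0.5),  # ramp midpoint
        (TriangularMF(0, 50, 100), 75, 0.5),
        (TriangularMF(0, 0, 50), 0, 1.0),  # left-shoulder ramp
        (TriangularMF(0, 0, 50), 25, 0.5),
        (TriangularMF(50, 100, 100), 100, 1.0),  # right-shoulder ramp
        (TriangularMF(50, 100, 100), 75, 0.5),
    ],
)
def test_triangular_membership(mf, x, expected):
    assert membership(mf, x) == pytest.approx(expected)


def test_mf_requires_ordered_breakpoints():
    with pytest.raises(ConfigurationError):
        TriangularMF(1.0, 0.5, 2.0)


@settings(max_examples=200, derandomize=True, deadline=None)
@given(st.floats(min_value=-50, max_value=150))
def test_membership_always_in_unit_interval(x):
    mf = TriangularMF(0, 40, 100)
    assert 0.0 <= membership(mf, x) <= 1.0


def test_fuzzify_peak_and_partition_of_unity(fuzzy_system):
    var = fuzzy_system.voltage
    for label, mf in var.mfs:
        assert fuzzify(var, mf.b)[label] == 1.0
    # between adjacent peaks of a touching-feet partition, degrees sum to 1
    rng = np.random.default_rng(4)
    for x in rng.uniform(var.lo, var.hi, 50):
        degrees = fuzzify(var, float(x))
        assert sum(degrees.values()) == pytest.approx(1.0)


def test_fuzzify_clamps_out_of_domain(fuzzy_system):
    var = fuzzy_system.voltage
    assert fuzzify(var, var.lo - 5.0) == fuzzify(var, var.lo)
    assert fuzzify(var, var.hi + 5.0) == fuzzify(var, var.hi)


def test_incomplete_or_duplicate_rule_base_rejected(fuzzy_system):
    rules = list(fuzzy_system.rules)
    with pytest.raises(ConfigurationError, match="missing"):
        FuzzySystemSpec(
            voltage=fuzzy_system.voltage,
            ceg=fuzzy_system.ceg,
            error=fuzzy_system.error,
            rules=tuple(rules[:-1]),
        )
    with pytest.raises(ConfigurationError, match="duplicate"):
        FuzzySystemSpec(
            voltage=fuzzy_system.voltage,
            ceg=fuzzy_system.ceg,
            error=fuzzy_system.error,
            rules=tuple(rules[:-1] + [rules[0]]),
        )


def test_uncovered_domain_rejected():
    with pytest.raises(ConfigurationError, match="cover"):
        LinguisticVariable(
            name="gappy",
            lo=0.0,
            hi=10.0,
            mfs=(("L", TriangularMF(0, 1, 2)), ("H", TriangularMF(8, 9, 10))),
        )


def test_single_rule_fires_fully_at_joint_peaks(fuzzy_system):
    """At (LoGl peak, A peak) the aggregate is the full output-A triangle."""
    xs, agg = infer(fuzzy_system, 1.0, 0.0)
    a_mf = dict(fuzzy_system.error.mfs)["A"]
    assert np.allclose(agg, a_mf(xs))


def test_aggregate_curve_in_unit_interval(fuzzy_system):
    rng = np.random.default_rng(9)
    for _ in range(50):
        _, agg = infer(fuzzy_system, rng.uniform(0, 6), rng.uniform(-0.2, 1.2))
        assert agg.min() >= 0.0 and agg.max() <= 1.0


def test_centroid_symmetric_triangle_is_midpoint():
    xs = np.linspace(0, 100, 1001)
    mu = TriangularMF(25, 50, 75)(xs)
    assert defuzzify_centroid(xs, mu) == pytest.approx(50.0, abs=1e-9)


def test_centroid_right_triangle_analytic():
    """Half-open ramp (0,0,50): analytic centre of gravity is 50/3."""
    xs = np.linspace(0, 100, 1001)
    mu = TriangularMF(0, 0, 50)(xs)
    assert defuzzify_centroid(xs, mu) == pytest.approx(50.0 / 3.0, abs=0.1)


def test_centroid_matches_dense_integration_oracle(fuzzy_system):
    """Sampled centroid vs trapezoidal integration at 100× resolution."""
    dense = default_system(resolution=100_101)
    rng = np.random.default_rng(3)
    for _ in range(20):
        v, s = rng.uniform(1, 4.5), rng.uniform(0, 1)
        sampled = predict_error(fuzzy_system, v, s)
        xs, mu = infer(dense, v, s)
        oracle = float(np.trapezoid(xs * mu, xs) / np.trapezoid(mu, xs))
        assert sampled == pytest.approx(oracle, abs=0.1)


def test_defuzzify_rejects_all_zero_curve():
    xs = np.linspace(0, 100, 101)
    with pytest.raises(NoRuleFiredError):
        defuzzify_centroid(xs, np.zeros_like(xs))


def test_predicted_error_monotone_in_severity(fuzzy_system):
    for v in (1.0, 1.8, 2.6, 3.4, 4.5):
        errs = [
            predict_error(fuzzy_system, v, s) for s in np.arange(0.0, 1.0001, 0.01)
        ]
        assert (np.diff(errs) >= -1e-9).all()


def test_predicted_error_within_output_domain(fuzzy_system):
    rng = np.random.default_rng(21)
    for _ in range(1000):
        e = predict_error(fuzzy_system, rng.uniform(0, 6), rng.uniform(-0.5, 1.5))
        assert 0.0 <= e <= 100.0


def test_inference_invariant_to_rule_order(fuzzy_system):
    shuffled = list(fuzzy_system.rules)
    random.Random(13).shuffle(shuffled)
    other = FuzzySystemSpec(
        voltage=fuzzy_system.voltage,
        ceg=fuzzy_system.ceg,
        error=fuzzy_system.error,
        rules=tuple(shuffled),
    )
    rng = np.random.default_rng(14)
    for _ in range(20):
        v, s = rng.uniform(1, 4.5), rng.uniform(0, 1)
        assert predict_error(fuzzy_system, v, s) == predict_error(other, v, s)


def test_spec_roundtrips_bit_exact(fuzzy_system, tmp_path):
    for text, loader in (
        (fuzzy_system.to_yaml(), FuzzySystemSpec.from_yaml),
        (fuzzy_system.to_json(), FuzzySystemSpec.from_json),
    ):
        reloaded = loader(text)
        assert reloaded == fuzzy_system
        # bit-exact: every MF breakpoint identical, not merely close
        for va, vb in (
            (reloaded.voltage, fuzzy_system.voltage),
            (reloaded.ceg, fuzzy_system.ceg),
            (reloaded.error, fuzzy_system.error),
        ):
            for (la, ma), (lb, mb) in zip(va.mfs, vb.mfs):
                assert la == lb and (ma.a, ma.b, ma.c) == (mb.a, mb.b, mb.c)
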