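"""Clarke Error Grid classification, severity and zone reporting."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from glucofuzz import (
    GlucosePair,
    InvalidInputError,
    classify,
    classify_many,
    severity,
    zone_intervals,
    zone_report,
)
from glucofuzz.ceg import ZONES


@pytest.mark.parametrize(
    "reference,estimate,zone",
    [
        (100, 100, "A"),  # identity line
        (110, 116, "A"),  # within 20% of reference
        (60, 200, "E"),  # hypo reference, hyper estimate
        (60, 65, "A"),  # both in the 70 mg/dL band
        (250, 190, "B"),
        (250, 100, "D"),  # hyper reference read as normal
        (60, 100, "D"),
        (150, 20, "C"),  # overcorrection region below
        (100, 215, "C"),  # estimate >= reference + 110
        (500, 50, "E"),
    ],
)
def test_classify_known_pairs(reference, estimate, zone):
    assert classify(GlucosePair(reference, estimate)) == zone


@pytest.mark.parametrize(
    "reference,estimate",
    [(0, 100), (-5, 100), (100, 0), (float("nan"), 100), (100, float("inf")), (1500, 100)],
)
def test_invalid_pairs_rejected(reference, estimate):
    with pytest.raises(InvalidInputError):
        classify((reference, estimate))


def test_invalid_input_names_offending_field():
    with pytest.raises(InvalidInputError, match="estimate"):
        classify((100, -1))
    with pytest.raises(InvalidInputError, match="reference"):
        classify((-1, 100))


def test_exhaustive_partition_on_integer_grid():
    """Every point of [1,600]² gets exactly one valid zone label."""
    r, e = np.meshgrid(np.arange(1, 601, dtype=float), np.arange(1, 601, dtype=float))
    labels = classify_many(r.ravel(), e.ravel())
    assert labels.shape == (360_000,)
    assert set(np.unique(labels)) <= set(ZONES)


def test_identity_line_is_zone_a():
    g = np.arange(1, 601, dtype=float)
    assert (classify_many(g, g) == "A").all()


def test_vectorised_matches_scalar():
    rng = np.random.default_rng(11)
    r = rng.uniform(1, 600, 2000)
    e = rng.uniform(1, 600, 2000)
    labels = classify_many(r, e)
    for i in range(0, 2000, 37):
        assert labels[i] == classify((r[i], e[i]))


def test_zone_intervals_partition_the_axis():
    for reference in (5, 60, 100, 150, 250, 400, 599):
        ivs = zone_intervals(reference)
        assert ivs[0][0] == 0.0 and ivs[-1][1] == 600.0
        for (lo1, hi1, _), (lo2, hi2, _) in zip(ivs, ivs[1:]):
            assert hi1 == lo2
        assert sum(hi - lo for lo, hi, _ in ivs) == pytest.approx(600.0)


def test_zone_intervals_agree_with_classifier_at_interior_points():
    rng = np.random.default_rng(5)
    for _ in range(10_000):
        reference = rng.uniform(1, 600)
        ivs = zone_intervals(reference)
        lo, hi, label = ivs[rng.integers(len(ivs))]
        e = rng.uniform(lo, hi)
        if lo < e < hi:
            assert classify((reference, e)) == label


def test_zone_intervals_examples():
    ivs100 = zone_intervals(100)
    containing = next(iv for iv in ivs100 if iv[0] <= 100 <= iv[1])
    assert containing[2] == "A"
    labels250 = [label for _, _, label in zone_intervals(250)]
    assert labels250 == ["E", "D", "B", "A", "B", "C"]

    with pytest.raises(InvalidInputError):
        zone_intervals(-1)


def test_severity_identity_and_band():
    assert severity((100, 100)) == 0.0
    s = severity((110, 116))
    assert 0.0 < s < 0.2  # zone A, so (0 + d)/5 < 0.2


@settings(max_examples=200, derandomize=True, deadline=None)
@given(
    st.floats(min_value=1, max_value=600),
    st.floats(min_value=1, max_value=600),
)
def test_severity_bounded(reference, estimate):
    assert 0.0 <= severity((reference, estimate)) <= 1.0


@pytest.mark.parametrize("reference", [60, 100, 150, 250, 400])
def test_severity_monotone_along_vertical_rays(reference):
    up = [severity((reference, float(e))) for e in np.arange(reference, 601.0)]
    assert (np.diff(up) >= -1e-12).all()
    down = [severity((reference, float(e))) for e in np.arange(reference, 0.0, -1.0)]
    assert (np.diff(down) >= -1e-12).all()


def test_zone_report_counts_and_percentages(table2):
    pairs = list(zip(table2.reference_glucose, table2.device_glucose))
    report = zone_report(pairs)
    assert report.n == 15
    assert report.percents["A"] == 100.0
    assert sum(report.counts.values()) == report.n
    assert sum(report.percents.values()) == pytest.approx(100.0, abs=1e-9)


def test_zone_report_single_pair_and_mixed_zones():
    single = zone_report([(100, 100)])
    assert single.percents == {"A": 100.0, "B": 0.0, "C": 0.0, "D": 0.0, "E": 0.0}
    # one pair per zone A, B, D, E at reference 250 (inverting the intervals)
    mixed = zone_report([(250, 250), (250, 190), (250, 100), (250, 50)])
    assert all(mixed.percents[z] == 25.0 for z in ("A", "B", "D", "E"))


def test_zone_report_rejects_empty():
    with pytest.raises(InvalidInputError):
        zone_report([])


def test_zone_report_serialisation(tmp_path):
    report = zone_report([(100, 100), (250, 100)])
    frame = report.to_frame()
    assert list(frame.columns) == ["zone", "count", "percent"]
    report.to_csv(tmp_path / "zones.csv")
    assert (tmp_path / "zones.csv").exists()
    assert '"n": 2' in report.to_json()
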