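"""Threshold point assignment, weighted totals and ranking."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dftbench.scoring import (
    DEFAULT_PROPERTIES,
    JANAK_ENTRIES,
    PERFORMANCE_STAGES,
    ScoringConfig,
    janak_points,
    performance_points,
    property_points,
    rank_combinations,
    total_score,
)


def brute_force_points(xi: float, x_ref: float) -> int:
    """Independent re-statement of the tier rule for oracle comparison."""
    lo, hi = 0.01 * abs(x_ref), 0.05 * abs(x_ref)
    if abs(xi) < lo:
        return 2
    elif lo <= abs(xi) < hi:
        return 1
    else:
        return 0


@pytest.mark.parametrize(
    "xi, ref, expected",
    [
        (0.0, 80.0, 2),
        (2.0, 80.0, 1),
        (10.0, 80.0, 0),
        (-2.0, 80.0, 1),  # sign of the error is irrelevant
        (0.2, 7.16, 1),
        (1.0, 0.67, 0),
        (0.0, 7.16, 2),
    ],
)
def test_point_examples(xi, ref, expected):
    assert property_points(xi, ref) == expected
    assert janak_points(xi, ref) == expected


def test_boundary_values_fall_to_lower_tier():
    assert property_points(0.8, 80.0) == 1  # exactly 1% of reference
    assert property_points(4.0, 80.0) == 0  # exactly 5%
    assert performance_points(1.0, 100.0) == 1
    assert performance_points(5.0, 100.0) == 0


def test_property_points_zero_reference_rejected():
    with pytest.raises(ValueError):
        property_points(0.1, 0.0)


@pytest.mark.parametrize("t, t_max, expected", [(0.0, 100.0, 2), (3.0, 100.0, 1), (100.0, 100.0, 0)])
def test_performance_points_examples(t, t_max, expected):
    assert performance_points(t, t_max) == expected


def test_performance_points_invalid_inputs():
    with pytest.raises(ValueError):
        performance_points(1.0, 0.0)
    with pytest.raises(ValueError):
        performance_points(-1.0, 10.0)


def test_points_agree_with_brute_force_oracle():
    rng = np.random.default_rng(42)
    xis = rng.uniform(-20, 20, 1000)
    refs = rng.uniform(0.5, 400, 1000) * rng.choice([-1, 1], 1000)
    for xi, ref in zip(xis, refs):
        assert property_points(xi, ref) == brute_force_points(xi, ref)


@given(
    xi=st.floats(min_value=0, max_value=50, allow_nan=False),
    shrink=st.floats(min_value=0, max_value=1),
    ref=st.floats(min_value=0.1, max_value=500, allow_nan=False),
)
@settings(derandomize=True, max_examples=100)
def test_monotone_in_error_magnitude(xi, shrink, ref):
    assert property_points(xi * shrink, ref) >= property_points(xi, ref)


def _card(combo, prop=2, perf=2, janak=2):
    return total_score(
        combo,
        {p: prop for p in DEFAULT_PROPERTIES},
        {s: perf for s in PERFORMANCE_STAGES},
        {j: janak for j in JANAK_ENTRIES},
    )


def test_max_raw_default_configuration():
    assert ScoringConfig().max_raw == pytest.approx(12.4)


def test_total_score_extremes_and_worked_example():
    assert _card(("A", "B")).percent == pytest.approx(100.0)
    assert _card(("A", "B"), 0, 0, 0).percent == pytest.approx(0.0)
    mixed = _card(("A", "B"), prop=1, perf=0, janak=2)
    assert mixed.raw_score == pytest.approx(5.8)
    assert mixed.percent == pytest.approx(100 * 5.8 / 12.4)
    assert mixed.display_percent == 47


def test_total_score_missing_entries_listed():
    with pytest.raises(ValueError, match="aip"):
        total_score(("A", "B"), {}, {s: 2 for s in PERFORMANCE_STAGES}, {j: 2 for j in JANAK_ENTRIES})


def test_reduced_property_list_normalizes_to_its_own_maximum():
    cfg = ScoringConfig(properties=("bde_c3", "bde_c4"))
    card = total_score(
        ("A", "B"),
        {"bde_c3": 2, "bde_c4": 2},
        {s: 2 for s in PERFORMANCE_STAGES},
        {j: 2 for j in JANAK_ENTRIES},
        cfg,
    )
    assert card.percent == pytest.approx(100.0)


def test_hundred_percent_only_with_all_twos():
    almost = _card(("A", "B"), prop=2, perf=2, janak=1)
    assert almost.percent < 100.0


def test_ranking_order_ties_and_permutation_invariance():
    cards = [
        _card(("M06-2X", "6-311G(d,p)")),
        _card(("BLYP", "cc-pVDZ"), prop=0, perf=0, janak=0),
        _card(("B3LYP", "cc-pVDZ"), prop=1),
        _card(("CAM-B3LYP", "cc-pVDZ"), prop=1),  # tie with B3LYP
    ]
    matrix, flat = rank_combinations(cards)
    assert flat.iloc[0]["functional"] == "M06-2X" and flat.iloc[0]["rank"] == 1
    tied = flat[flat["rank"] == 2]
    assert list(tied["functional"]) == ["B3LYP", "CAM-B3LYP"]  # alphabetical within tie
    assert flat.iloc[-1]["functional"] == "BLYP"
    _, flat_perm = rank_combinations(list(reversed(cards)))
    assert flat_perm.equals(flat)
    assert matrix.loc["6-311G(d,p)", "M06-2X"] == 100
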