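"""MET model family: resting normalization, continuity, switch points, bank."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from walkmet.models import (
    ALL_PIECEWISE,
    MEN_PIECEWISE,
    MEN_POLYNOMIAL,
    WOMEN_PIECEWISE,
    PiecewiseMetModel,
    PolynomialMetModel,
    derive_intercepts,
    evaluate_linear_baseline,
    evaluate_reference_vo2max,
    model_from_json,
    model_to_json,
    switch_points,
)


@pytest.mark.parametrize(
    "v, expected", [(0.0, 1.0), (1.0, 1.5046), (3.5, (1.766 * 3.5 + 3.5) / 3.5)]
)
def test_linear_baseline(v, expected):
    # the historical (1.766 v + 3.5)/3.5 form and 0.5046 v + 1 agree to 4 d.p.
    assert evaluate_linear_baseline(v) == pytest.approx(expected, abs=5e-4)


def test_linear_baseline_rejects_negative_velocity():
    with pytest.raises(ValueError):
        evaluate_linear_baseline(-0.1)


@pytest.mark.parametrize(
    "v, expected, tol",
    [
        (0.0, 1.0, 1e-15),
        (1.0, 1.515559, 1e-9),  # 1 + sum of the men's coefficients
        (5.0, 6.3131, 5e-5),  # 1 + 2.58505 - 0.72735 + 3.455375
    ],
)
def test_polynomial_evaluation_men(v, expected, tol):
    assert MEN_POLYNOMIAL.predict(v) == pytest.approx(expected, abs=tol)


def test_polynomial_vectorized_and_domain():
    v = np.array([0.0, 1.0, 2.0])
    out = MEN_POLYNOMIAL.predict(v)
    assert out.shape == (3,)
    assert out[0] == 1.0
    with pytest.raises(ValueError):
        MEN_POLYNOMIAL.predict(-1.0)


@pytest.mark.parametrize(
    "slopes, cps, expected",
    [
        ((0.7, 0.7, 0.7), (1.0, 2.0), [1.0, 1.0, 1.0]),  # equal slopes
        ((0.5,), (), [1.0]),  # single segment
        (
            (0.4866, 1.415, 1.99, 4.494),
            (2.68, 3.945, 5.798),
            [1.0, -1.488112, -3.756487, -18.274679],  # recursion by hand
        ),
    ],
)
def test_derive_intercepts(slopes, cps, expected):
    assert derive_intercepts(slopes, cps) == pytest.approx(expected, abs=1e-9)


def test_derive_intercepts_rejects_unsorted_change_points():
    with pytest.raises(ValueError):
        derive_intercepts((1.0, 2.0, 3.0), (2.0, 2.0))
    with pytest.raises(ValueError):
        derive_intercepts((1.0, 2.0), (1.0, 2.0))  # count mismatch


def test_women_switch_points_printed_values():
    """The women's reference model evaluates to 2.304 / 4.094 / 7.782 MET
    at its three change points (3 d.p.)."""
    assert [round(m, 3) for m in switch_points(WOMEN_PIECEWISE)] == [2.304, 4.094, 7.782]


def test_switch_points_increasing_for_positive_slopes():
    for model in (MEN_PIECEWISE, WOMEN_PIECEWISE, ALL_PIECEWISE):
        sp = switch_points(model)
        assert all(b > a for a, b in zip(sp, sp[1:]))
    single = PiecewiseMetModel((0.5,), ())
    assert switch_points(single) == []


def test_piecewise_resting_value_and_domain():
    assert WOMEN_PIECEWISE.predict(0.0) == 1.0
    with pytest.raises(ValueError):
        WOMEN_PIECEWISE.predict(-0.5)


def test_single_segment_matches_linear_baseline():
    model = PiecewiseMetModel((0.5046,), ())
    v = np.linspace(0, 10, 50)
    np.testing.assert_allclose(model.predict(v), evaluate_linear_baseline(v), rtol=1e-15)


@settings(max_examples=60, derandomize=True)
@given(
    slopes=st.lists(
        st.floats(min_value=-3.0, max_value=6.0, allow_nan=False), min_size=2, max_size=6
    ),
    gaps=st.lists(
        st.floats(min_value=0.05, max_value=3.0, allow_nan=False), min_size=1, max_size=5
    ),
)
def test_piecewise_continuity_property(slopes, gaps):
    """Any valid model is continuous at every change point (< 1e-9 MET), and
    re-deriving intercepts reproduces the stored ones."""
    cps = tuple(np.cumsum([0.5] + gaps[: len(slopes) - 1]))[: len(slopes) - 1]
    model = PiecewiseMetModel(tuple(slopes[: len(cps) + 1]), cps)
    for j, v in enumerate(model.change_points):
        left = model.slopes[j] * v + model.intercepts[j]
        right = model.slopes[j + 1] * v + model.intercepts[j + 1]
        assert abs(left - right) < 1e-9
    rederived = derive_intercepts(model.slopes, model.change_points)
    np.testing.assert_allclose(rederived, model.intercepts, rtol=0, atol=1e-12)


@pytest.mark.parametrize(
    "name, walk_time, expected",
    [
        ("bruce-cubic", 0.0, 14.76),  # the resting-offset defect of the cubic
        ("women-a", 0.0, 3.74),
        ("bruce-cubic", 10.0, 34.07),
        ("men", 10.0, 2.94 * 10 + 7.65),
    ],
)
def test_reference_vo2max_bank(name, walk_time, expected):
    assert evaluate_reference_vo2max(name, walk_time) == pytest.approx(expected)


def test_reference_vo2max_unknown_name():
    with pytest.raises(KeyError):
        evaluate_reference_vo2max("nope", 5.0)


@pytest.mark.parametrize("model", [MEN_POLYNOMIAL, WOMEN_PIECEWISE])
def test_json_round_trip_lossless(model):
    clone = model_from_json(model_to_json(model))
    assert clone == model


def test_extrapolation_flag():
    model = PolynomialMetModel((0.5,), training_velocity_max=6.0)
    assert not model.is_extrapolating(5.9)
    assert model.is_extrapolating(6.1)
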