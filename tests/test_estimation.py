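"""Fitting: analytic polynomial LS, hinge LS for slopes, the GA search, RMSE."""

import numpy as np
import pytest

from walkmet import Cohort
from walkmet.estimation import (
    EstimationError,
    GAConfig,
    _sse_for,
    fit_piecewise,
    fit_polynomial,
    rmse,
    slopes_given_change_points,
)
from walkmet.models import WOMEN_PIECEWISE
from walkmet.synthetic import SyntheticConfig, generate

FAST_GA = GAConfig(population_size=30, generations=60, restarts=1, polish_sweeps=3, seed=7)


# --- rmse -------------------------------------------------------------------

def test_rmse_examples():
    assert rmse([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 0.0
    assert rmse([1.0, 2.0], [2.0, 2.0]) == pytest.approx(np.sqrt(0.5))


def test_rmse_domain_errors():
    with pytest.raises(ValueError):
        rmse([1.0], [1.0, 2.0])
    with pytest.raises(ValueError):
        rmse([], [])


# --- polynomial -------------------------------------------------------------

def test_polynomial_exact_interpolation(noiseless_polynomial_cohort):
    """Noiseless data from a cubic unity-intercept curve is recovered exactly."""
    cohort, truth = noiseless_polynomial_cohort
    report = fit_polynomial(cohort, 3)
    np.testing.assert_allclose(report.model.coefficients, truth.coefficients, atol=1e-8)
    assert report.rmse < 1e-10


def test_polynomial_collinear_line(collinear_cohort):
    """Three collinear points through (0, 1): slope 0.5, RMSE 0."""
    report = fit_polynomial(collinear_cohort, 1)
    assert report.model.coefficients[0] == pytest.approx(0.5, abs=1e-12)
    assert report.rmse == pytest.approx(0.0, abs=1e-12)


def test_polynomial_normal_equations_orthogonality():
    cohort = generate(SyntheticConfig(n_men=0, n_women=120, seed=11))
    report = fit_polynomial(cohort, 3)
    basis = np.vander(cohort.velocities, 4, increasing=True)[:, 1:]
    # residuals orthogonal to every basis column (normal equations)
    gram = np.abs(basis.T @ report.residuals)
    scale = np.linalg.norm(basis, axis=0) * np.linalg.norm(report.residuals)
    assert np.all(gram <= 1e-8 * np.maximum(scale, 1.0))


def test_polynomial_needs_enough_distinct_velocities():
    with pytest.raises(EstimationError):
        fit_polynomial(Cohort([1.0, 2.0, 3.0], [1.5, 2.0, 2.5]), 3)
    with pytest.raises(EstimationError):
        fit_polynomial(Cohort([2.0, 2.0, 2.0, 2.0], [1.5, 2.0, 2.5, 2.2]), 2)


# --- inner LS: slopes given change points -----------------------------------

def test_slopes_on_straight_line_any_change_points():
    v = np.linspace(0.5, 6.0, 40)
    cohort = Cohort(v, 1.0 + 0.5 * v)
    slopes, sse = slopes_given_change_points(cohort, [2.0, 4.0])
    np.testing.assert_allclose(slopes, [0.5, 0.5, 0.5], atol=1e-10)
    assert sse == pytest.approx(0.0, abs=1e-18)


def test_slopes_recover_generating_model(noiseless_piecewise_cohort):
    slopes, sse = slopes_given_change_points(
        noiseless_piecewise_cohort, WOMEN_PIECEWISE.change_points
    )
    np.testing.assert_allclose(slopes, WOMEN_PIECEWISE.slopes, atol=1e-6)
    assert sse < 1e-16


def test_slopes_match_bruteforce_normal_equations():
    """Two-segment tent: hinge LS agrees with explicitly assembled normal
    equations for the same parametrization."""
    rng = np.random.default_rng(5)
    v = np.sort(rng.uniform(0.5, 6.0, 24))
    y = np.where(v < 3.0, 0.8 * v, 0.8 * 3.0 + 2.0 * (v - 3.0)) + rng.normal(0, 0.3, 24)
    cohort = Cohort(v, 1.0 + y - min(0.0, (1.0 + y).min() - 0.1))
    cp = 3.0
    design = np.column_stack([v, np.maximum(0.0, v - cp)])
    theta = np.linalg.solve(design.T @ design, design.T @ (cohort.mets - 1.0))
    slopes, _ = slopes_given_change_points(cohort, [cp])
    np.testing.assert_allclose(slopes, np.cumsum(theta), rtol=1e-10)


def test_slopes_rejects_bad_change_points():
    cohort = Cohort([1.0, 2.0, 3.0], [1.5, 2.0, 2.5])
    with pytest.raises(ValueError):
        slopes_given_change_points(cohort, [3.0, 2.0])


def test_empty_segment_warns_or_raises():
    cohort = Cohort([1.0, 1.5, 5.0, 6.0], [1.5, 1.8, 3.5, 4.0])
    with pytest.warns(UserWarning):
        slopes_given_change_points(cohort, [2.5, 3.5])  # (2.5, 3.5) holds no data
    with pytest.raises(EstimationError):
        slopes_given_change_points(cohort, [2.5, 3.5], strict=True)


# --- piecewise GA fit -------------------------------------------------------

def test_piecewise_noiseless_recovery(noiseless_piecewise_cohort):
    cfg = GAConfig(
        population_size=40, generations=80, restarts=1,
        change_point_bounds=(1.0, 7.5), seed=1, polish_sweeps=6,
    )
    report = fit_piecewise(noiseless_piecewise_cohort, 4, cfg)
    np.testing.assert_allclose(
        report.model.change_points, WOMEN_PIECEWISE.change_points, atol=0.05
    )
    np.testing.assert_allclose(report.model.slopes, WOMEN_PIECEWISE.slopes, atol=1e-3)


def test_piecewise_single_segment_reduces_to_line(collinear_cohort):
    report = fit_piecewise(collinear_cohort, 1, FAST_GA)
    assert report.model.n_segments == 1
    assert report.model.slopes[0] == pytest.approx(0.5, abs=1e-12)
    assert report.rmse == pytest.approx(0.0, abs=1e-12)


def test_piecewise_deterministic_given_seed():
    cohort = generate(SyntheticConfig(n_men=0, n_women=60, seed=2))
    r1 = fit_piecewise(cohort, 2, FAST_GA)
    r2 = fit_piecewise(cohort, 2, FAST_GA)
    assert r1.model == r2.model
    assert r1.rmse == r2.rmse


def test_piecewise_nesting_beats_single_segment():
    """The 4-segment optimum is at least as good as the 1-segment fit."""
    cohort = generate(SyntheticConfig(n_men=0, n_women=150, seed=3))
    r1 = fit_piecewise(cohort, 1, FAST_GA)
    r4 = fit_piecewise(cohort, 4, FAST_GA)
    assert r4.rmse <= r1.rmse + 1e-9


def test_ga_best_sse_non_increasing():
    """Elitism: re-running with more generations never worsens the optimum."""
    cohort = generate(SyntheticConfig(n_men=0, n_women=80, seed=4))
    short = fit_piecewise(cohort, 2, GAConfig(
        population_size=20, generations=10, restarts=1, seed=9, polish=False))
    long = fit_piecewise(cohort, 2, GAConfig(
        population_size=20, generations=60, restarts=1, seed=9, polish=False))
    assert long.sse <= short.sse + 1e-12


def test_piecewise_infeasible_bounds():
    cohort = generate(SyntheticConfig(n_men=0, n_women=50, seed=6))
    bad = GAConfig(change_point_bounds=(4.0, 4.4), min_gap=0.3)
    with pytest.raises(EstimationError):
        fit_piecewise(cohort, 4, bad)  # 3 points cannot fit in a 0.4 km/h window


def test_fit_report_serializes():
    cohort = generate(SyntheticConfig(n_men=0, n_women=50, seed=8))
    doc = fit_piecewise(cohort, 2, FAST_GA).to_dict()
    assert doc["model"]["kind"] == "piecewise"
    assert doc["sample_size"] == 50
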