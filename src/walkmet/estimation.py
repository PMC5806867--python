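"""Least-squares and hybrid LS/GA fitting of the MET model family.

The polynomial model is linear in its parameters once the unity intercept is
moved to the response, so it is fitted analytically: ordinary LS of (M - 1)
on the monomial basis [v, v^2, ..., v^K] with no intercept column.

The piecewise-linear model is linear in its slopes but highly non-linear in
its change points, where plain numerical LS tends to stall in local minima.
The fitter therefore decomposes the problem:

* inner problem — with change points V fixed, continuity (b_1 = 1) turns the
  model into the hinge regression

      M(v) = 1 + a_1 v + sum_{j>=2} (a_j - a_{j-1}) max(0, v - V_{j-1}),

  solved analytically by ordinary LS (``slopes_given_change_points``);

* outer problem — a small, seeded genetic algorithm searches change-point
  vectors (sorted, bounded, minimum-gap respecting), scoring each candidate
  by the inner LS solve; elitism makes the best SSE non-increasing across
  generations.  A coordinate-wise bounded scalar polish refines the GA
  optimum.

RMSE is always sqrt(mean squared residual) with 1/N normalization — no
degrees-of-freedom correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.optimize import minimize_scalar

from .cohort import Cohort
from .models import PiecewiseMetModel, PolynomialMetModel

__all__ = [
    "GAConfig",
    "FitReport",
    "EstimationError",
    "rmse",
    "fit_polynomial",
    "slopes_given_change_points",
    "fit_piecewise",
]


class EstimationError(RuntimeError):
    """A model fit could not be carried out on the given data."""


@dataclass(frozen=True)
class GAConfig:
    """Genetic-algorithm settings for the change-point search.

    All settings are optimizer plumbing: they control how hard the search
    works, not what is being estimated.  Defaults are sized for desk-scale
    fits (well under a minute per cohort of a few hundred records).
    ``change_point_bounds=None`` means the [5th, 95th] percentile of the
    observed velocities.
    """

    population_size: int = 60
    generations: int = 300
    tournament_size: int = 3
    crossover_rate: float = 0.7
    mutation_sd: float = 0.2  # km/h
    mutation_prob: float = 0.2  # per gene
    elitism: int = 2
    restarts: int = 3
    min_gap: float = 0.3  # km/h between consecutive change points
    change_point_bounds: tuple[float, float] | None = None
    seed: int = 20180209
    polish: bool = True
    polish_sweeps: int = 2

    def __post_init__(self) -> None:
        for name in ("population_size", "generations", "tournament_size", "restarts"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.elitism < 0 or self.elitism >= self.population_size:
            raise ValueError("elitism must be in [0, population_size)")
        if self.min_gap <= 0:
            raise ValueError("min_gap must be positive")
        if self.change_point_bounds is not None:
            lo, hi = self.change_point_bounds
            if not lo < hi:
                raise ValueError("change_point_bounds must be an increasing interval")


@dataclass
class FitReport:
    """Outcome of one model fit."""

    model: PolynomialMetModel | PiecewiseMetModel
    rmse: float
    sample_size: int
    residuals: np.ndarray
    seed: int | None = None
    generations_run: int = 0
    restarts_run: int = 0
    converged: bool = True
    sse: float = 0.0
    extrapolation_flagged: bool = False
    notes: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        from .models import model_to_dict

        return {
            "model": model_to_dict(self.model),
            "rmse": self.rmse,
            "sse": self.sse,
            "sample_size": self.sample_size,
            "seed": self.seed,
            "generations_run": self.generations_run,
            "restarts_run": self.restarts_run,
            "converged": self.converged,
            "notes": self.notes,
        }


def rmse(observed: Sequence[float], predicted: Sequence[float]) -> float:
    """Root mean square error with 1/N normalization."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or obs.ndim != 1:
        raise ValueError("observed and predicted must be equal-length 1-D sequences")
    if obs.size == 0:
        raise ValueError("cannot compute RMSE of empty sequences")
    return float(np.sqrt(np.mean((obs - pred) ** 2)))


def fit_polynomial(cohort: Cohort, order: int) -> FitReport:
    """Analytic LS fit of the order-K polynomial MET model.

    Solves min_A || (M - 1) - [v, v^2, ..., v^K] A ||^2; the unity resting
    intercept is structural, so no intercept column appears in the basis.
    """
    if order < 1:
        raise ValueError("polynomial order must be >= 1")
    v, m = cohort.velocities, cohort.mets
    n = v.size
    if n <= order:
        raise EstimationError(
            f"need more than {order} records to fit order {order}, got {n}"
        )
    if np.unique(v).size <= order:
        raise EstimationError(
            f"need more than {order} distinct velocities, got {np.unique(v).size}"
        )
    basis = np.vander(v, order + 1, increasing=True)[:, 1:]  # columns v..v^K
    coef, _, rank, _ = np.linalg.lstsq(basis, m - 1.0, rcond=None)
    if rank < order:
        raise EstimationError(
            f"monomial basis is rank-deficient (rank {rank} < {order}); "
            "velocities may be numerically degenerate"
        )
    model = PolynomialMetModel(
        tuple(coef), cohort.label, training_velocity_max=float(v.max())
    )
    resid = m - model.predict(v)
    return FitReport(
        model=model,
        rmse=float(np.sqrt(np.mean(resid**2))),
        sample_size=n,
        residuals=resid,
        sse=float(np.sum(resid**2)),
    )


def _hinge_design(v: np.ndarray, change_points: np.ndarray) -> np.ndarray:
    """Design matrix [v, (v-V_1)_+, ..., (v-V_{n-1})_+]."""
    cols = [v] + [np.maximum(0.0, v - cp) for cp in change_points]
    return np.column_stack(cols)


def _segment_counts(v: np.ndarray, change_points: np.ndarray) -> np.ndarray:
    edges = np.concatenate(([-np.inf], change_points, [np.inf]))
    counts, _ = np.histogram(v, bins=edges)
    return counts


def slopes_given_change_points(
    cohort: Cohort, change_points: Sequence[float], *, strict: bool = False
) -> tuple[np.ndarray, float]:
    """Optimal per-segment slopes for fixed change points, plus the SSE.

    With the change points fixed and b_1 = 1, the continuous model is linear
    in the hinge parameters; this solves that LS problem and converts the
    hinge increments back to per-segment slopes a_j.  A segment containing
    no data leaves its slope unidentified: a warning is issued and the
    minimum-norm LS solution is returned (or EstimationError when
    ``strict``).
    """
    cps = np.asarray(change_points, dtype=float)
    if cps.size and (np.any(np.diff(cps) <= 0) or np.any(cps <= 0)):
        raise ValueError("change points must be positive and strictly increasing")
    v, m = cohort.velocities, cohort.mets
    if cps.size and (cps.min() <= v.min() or cps.max() >= v.max()):
        warnings.warn(
            "change points outside the interior of the data's velocity range",
            stacklevel=2,
        )
    counts = _segment_counts(v, cps)
    if np.any(counts == 0):
        msg = f"segments with no data points (counts {counts.tolist()})"
        if strict:
            raise EstimationError(msg)
        warnings.warn(msg + "; slopes from minimum-norm pseudo-inverse", stacklevel=2)
    design = _hinge_design(v, cps)
    theta, _, _, _ = np.linalg.lstsq(design, m - 1.0, rcond=None)
    slopes = np.cumsum(theta)  # a_j = a_1 + sum of hinge increments
    resid = (m - 1.0) - design @ theta
    return slopes, float(np.sum(resid**2))


def _sse_for(v: np.ndarray, y: np.ndarray, cps: np.ndarray, min_per_segment: int = 1):
    """GA scoring: SSE of the inner LS solve; +inf for degenerate segments."""
    counts = _segment_counts(v, cps)
    if np.any(counts < min_per_segment):
        return np.inf, None
    design = _hinge_design(v, cps)
    theta, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ theta
    return float(np.sum(resid**2)), np.cumsum(theta)


def _repair(cps: np.ndarray, lo: float, hi: float, gap: float) -> np.ndarray:
    """Sort, clip to [lo, hi] and enforce the minimum inter-point gap."""
    cps = np.sort(np.clip(cps, lo, hi))
    for i in range(1, cps.size):  # forward pass pushes points up
        cps[i] = max(cps[i], cps[i - 1] + gap)
    cps = np.minimum(cps, hi)
    for i in range(cps.size - 2, -1, -1):  # backward pass pulls back under hi
        cps[i] = min(cps[i], cps[i + 1] - gap)
    return cps


def _ga_search(
    v: np.ndarray,
    y: np.ndarray,
    n_points: int,
    cfg: GAConfig,
    lo: float,
    hi: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, float]:
    """One GA restart over change-point vectors; returns (best cps, best SSE)."""
    pop = np.sort(rng.uniform(lo, hi, size=(cfg.population_size, n_points)), axis=1)
    pop = np.array([_repair(ind, lo, hi, cfg.min_gap) for ind in pop])
    fitness = np.array([_sse_for(v, y, ind)[0] for ind in pop])
    best_idx = int(np.argmin(fitness))
    best, best_sse = pop[best_idx].copy(), fitness[best_idx]

    for _ in range(cfg.generations):
        order = np.argsort(fitness)
        new_pop = [pop[i].copy() for i in order[: cfg.elitism]]
        while len(new_pop) < cfg.population_size:
            # tournament selection of two parents
            parents = []
            for _k in range(2):
                contenders = rng.integers(0, cfg.population_size, cfg.tournament_size)
                parents.append(pop[contenders[np.argmin(fitness[contenders])]])
            p1, p2 = parents
            if rng.random() < cfg.crossover_rate:
                u = rng.random(n_points)
                child = u * p1 + (1.0 - u) * p2
            else:
                child = p1.copy()
            mutate = rng.random(n_points) < cfg.mutation_prob
            child = child + mutate * rng.normal(0.0, cfg.mutation_sd, n_points)
            new_pop.append(_repair(child, lo, hi, cfg.min_gap))
        pop = np.array(new_pop)
        fitness = np.array([_sse_for(v, y, ind)[0] for ind in pop])
        gen_best = int(np.argmin(fitness))
        if fitness[gen_best] < best_sse:
            best, best_sse = pop[gen_best].copy(), fitness[gen_best]
    return best, best_sse


def _polish(
    v: np.ndarray,
    y: np.ndarray,
    cps: np.ndarray,
    lo: float,
    hi: float,
    gap: float,
    sweeps: int,
) -> tuple[np.ndarray, float]:
    """Coordinate-wise bounded scalar refinement of the change points."""
    cps = cps.copy()
    best_sse = _sse_for(v, y, cps)[0]
    for _ in range(sweeps):
        for i in range(cps.size):
            lower = lo if i == 0 else cps[i - 1] + gap
            upper = hi if i == cps.size - 1 else cps[i + 1] - gap
            if not lower < upper:
                continue

            def objective(x, i=i):
                trial = cps.copy()
                trial[i] = x
                return _sse_for(v, y, trial)[0]

            res = minimize_scalar(
                objective, bounds=(lower, upper), method="bounded",
                options={"xatol": 1e-10, "maxiter": 200},
            )
            if np.isfinite(res.fun) and res.fun < best_sse:
                cps[i] = float(res.x)
                best_sse = float(res.fun)
    return cps, best_sse


def fit_piecewise(
    cohort: Cohort, n_segments: int, config: GAConfig | None = None
) -> FitReport:
    """Hybrid LS/GA fit of the n-segment continuous piecewise-linear model.

    The GA explores change-point vectors; every candidate is scored by the
    analytic inner LS solve for the slopes.  Deterministic given
    ``config.seed``.  ``n_segments=1`` has no change points and reduces to
    the order-1 polynomial fit.
    """
    if n_segments < 1:
        raise ValueError("n_segments must be >= 1")
    cfg = config or GAConfig()
    v, m = cohort.velocities, cohort.mets
    if v.size < 2 * n_segments:
        raise EstimationError(
            f"need at least {2 * n_segments} records for {n_segments} segments, got {v.size}"
        )

    if n_segments == 1:
        poly = fit_polynomial(cohort, 1)
        model = PiecewiseMetModel(
            (poly.model.coefficients[0],),
            (),
            cohort.label,
            training_velocity_max=float(v.max()),
        )
        return replace(
            poly,
            model=model,
            seed=cfg.seed,
            notes={"method": "analytic (single segment)"},
        )

    if cfg.change_point_bounds is not None:
        lo, hi = cfg.change_point_bounds
    else:
        lo, hi = np.percentile(v, [5.0, 95.0])
    n_points = n_segments - 1
    if hi - lo < cfg.min_gap * n_points:
        raise EstimationError(
            f"bounds [{lo:.3g}, {hi:.3g}] cannot hold {n_points} change points "
            f"with gap {cfg.min_gap}"
        )

    y = m - 1.0
    best_cps, best_sse = None, np.inf
    restart_seeds = [cfg.seed + 1000003 * r for r in range(cfg.restarts)]
    for rs in restart_seeds:
        rng = np.random.default_rng(rs)
        cps, sse = _ga_search(v, y, n_points, cfg, lo, hi, rng)
        if sse < best_sse:
            best_cps, best_sse = cps, sse
    if best_cps is None or not np.isfinite(best_sse):
        raise EstimationError(
            "GA found no feasible change-point vector (every candidate left an "
            "empty segment); widen the bounds or reduce n_segments"
        )
    if cfg.polish:
        best_cps, best_sse = _polish(v, y, best_cps, lo, hi, cfg.min_gap, cfg.polish_sweeps)

    slopes = _sse_for(v, y, best_cps)[1]
    model = PiecewiseMetModel(
        tuple(slopes),
        tuple(best_cps),
        cohort.label,
        training_velocity_max=float(v.max()),
    )
    resid = m - model.predict(v)
    return FitReport(
        model=model,
        rmse=float(np.sqrt(np.mean(resid**2))),
        sample_size=v.size,
        residuals=resid,
        seed=cfg.seed,
        generations_run=cfg.generations * cfg.restarts,
        restarts_run=cfg.restarts,
        sse=float(np.sum(resid**2)),
        notes={"bounds": [float(lo), float(hi)], "polished": cfg.polish},
    )
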