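"""Leave-one-out cross-validation for MET model selection.

LOO CV refits the model N times, each time holding out a single record and
predicting it; RMSE_cv over the N held-out predictions measures
out-of-sample accuracy, and the Pearson correlation between reference and
predicted METs summarizes agreement.  For the piecewise model each fold
re-runs the full LS/GA search with a fold-derived deterministic seed
(reusing the full-data change points is available as a fast option, but it
biases RMSE_cv downward and is off by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Union

import numpy as np
from scipy import stats
from sklearn.model_selection import LeaveOneOut

from .cohort import Cohort
from .estimation import (
    EstimationError,
    FitReport,
    GAConfig,
    fit_piecewise,
    fit_polynomial,
    slopes_given_change_points,
)
from .models import PiecewiseMetModel, model_to_dict

__all__ = [
    "PolynomialSpec",
    "PiecewiseSpec",
    "CrossValReport",
    "loo_cv",
    "pearson_r",
]


@dataclass(frozen=True)
class PolynomialSpec:
    """Model specification: order-K polynomial."""

    order: int = 3

    def fit(self, cohort: Cohort, seed: int | None = None) -> FitReport:
        return fit_polynomial(cohort, self.order)

    def describe(self) -> dict:
        return {"kind": "polynomial", "order": self.order}


@dataclass(frozen=True)
class PiecewiseSpec:
    """Model specification: n-segment piecewise-linear with GA settings.

    ``refit_change_points`` controls the LOO mode: True re-runs the full
    LS/GA search every fold; False freezes the full-data change points and
    refits only the slopes per fold.
    """

    n_segments: int = 4
    config: GAConfig = field(default_factory=GAConfig)
    refit_change_points: bool = True

    def fit(self, cohort: Cohort, seed: int | None = None) -> FitReport:
        cfg = self.config if seed is None else GAConfig(
            **{**self.config.__dict__, "seed": seed}
        )
        return fit_piecewise(cohort, self.n_segments, cfg)

    def describe(self) -> dict:
        return {
            "kind": "piecewise",
            "n_segments": self.n_segments,
            "refit_change_points": self.refit_change_points,
        }


ModelSpec = Union[PolynomialSpec, PiecewiseSpec]


@dataclass
class CrossValReport:
    """LOO cross-validation outcome."""

    spec: dict
    predictions: np.ndarray
    observed: np.ndarray
    rmse_cv: float
    pearson_r: float
    n_folds: int
    seed: int | None = None
    mode: str = "refit"

    def to_dict(self) -> dict:
        return {
            "spec": self.spec,
            "rmse_cv": self.rmse_cv,
            "pearson_r": self.pearson_r,
            "n_folds": self.n_folds,
            "seed": self.seed,
            "mode": self.mode,
            "reference_vs_predicted": [
                [float(o), float(p)] for o, p in zip(self.observed, self.predictions)
            ],
        }


def pearson_r(observed, predicted) -> float:
    """Product-moment correlation between observed and predicted METs."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or obs.ndim != 1 or obs.size < 2:
        raise ValueError("need two equal-length 1-D sequences of length >= 2")
    if np.ptp(obs) == 0 or np.ptp(pred) == 0:
        raise ValueError("correlation undefined: one of the sequences has zero variance")
    return float(stats.pearsonr(obs, pred).statistic)


def loo_cv(cohort: Cohort, spec: ModelSpec, seed: int | None = None) -> CrossValReport:
    """Leave-one-out cross-validation of a model specification.

    Each fold l trains on the other N-1 records and predicts record l.  A
    failing fold aborts with its index — folds are never silently skipped.
    Piecewise folds that refit change points use seed = base_seed + fold
    index so the whole run is reproducible from one number.
    """
    n = len(cohort)
    if n < 3:
        raise ValueError(f"LOO CV needs at least 3 records, got {n}")
    base_seed = seed if seed is not None else (
        spec.config.seed if isinstance(spec, PiecewiseSpec) else 0
    )

    frozen_cps = None
    mode = "refit"
    if isinstance(spec, PiecewiseSpec) and not spec.refit_change_points:
        full_fit = spec.fit(cohort, seed=base_seed)
        frozen_cps = full_fit.model.change_points
        mode = "fixed_change_points"

    preds = np.empty(n)
    for fold, (train_idx, test_idx) in enumerate(LeaveOneOut().split(cohort.velocities)):
        train = cohort.subset(train_idx)
        v_test = cohort.velocities[test_idx]
        try:
            if frozen_cps is not None:
                slopes, _ = slopes_given_change_points(train, frozen_cps)
                model = PiecewiseMetModel(tuple(slopes), tuple(frozen_cps), cohort.label)
            else:
                model = spec.fit(train, seed=base_seed + fold).model
        except (EstimationError, ValueError) as exc:
            raise EstimationError(f"LOO fold {fold} failed: {exc}") from exc
        preds[test_idx] = model.predict(v_test)

    rmse_cv = float(np.sqrt(np.mean((cohort.mets - preds) ** 2)))
    return CrossValReport(
        spec=spec.describe(),
        predictions=preds,
        observed=cohort.mets.copy(),
        rmse_cv=rmse_cv,
        pearson_r=pearson_r(cohort.mets, preds),
        n_folds=n,
        seed=base_seed,
        mode=mode,
    )
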