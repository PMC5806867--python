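"""MET-vs-velocity model family for 6MWT effort-tolerance estimation.

All models share the generalized-MET normalization: the resting value at
v = 0 is exactly 1 MET regardless of the individual's resting oxygen uptake,
so the intercept is structural, never estimated.

Three model classes:

* the classical linear baseline  M1(v) = 0.5046 v + 1  (Connors-Hilling),
* a polynomial expansion         M_pe(v) = 1 + a1 v + ... + aK v^K,
* a continuous n-segment piecewise-linear curve M_pl(v) with change points
  V_1 < ... < V_{n-1}, where continuity fixes the segment intercepts
  recursively: b_1 = 1 and b_j = (a_{j-1} - a_j) V_{j-1} + b_{j-1}.

The piecewise model's MET values at its change points ("switch points"
M^(i) = M_pl(V_i)) double as data-driven rehabilitation-class boundaries.

A small bank of published VO2max-vs-treadmill-time reference formulas is
included for comparison against the MET models.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "PolynomialMetModel",
    "PiecewiseMetModel",
    "ReferenceVo2maxModel",
    "REFERENCE_VO2MAX_BANK",
    "evaluate_linear_baseline",
    "derive_intercepts",
    "switch_points",
    "evaluate_reference_vo2max",
    "model_to_dict",
    "model_from_dict",
    "model_to_json",
    "model_from_json",
    "MEN_POLYNOMIAL",
    "WOMEN_POLYNOMIAL",
    "ALL_POLYNOMIAL",
    "MEN_PIECEWISE",
    "WOMEN_PIECEWISE",
    "ALL_PIECEWISE",
]

#: Slope of the classical linear 6MWT model M1 = 0.5046 v + 1 (the
#: (1.766 v + 3.5)/3.5 form divided through by the 3.5 ml/kg/min resting
#: uptake; both printed forms agree to 4 decimals).
LINEAR_BASELINE_SLOPE = 0.5046


def _check_velocity(velocity) -> np.ndarray:
    v = np.asarray(velocity, dtype=float)
    if np.any(v < 0):
        raise ValueError("velocity must be non-negative")
    return v


def evaluate_linear_baseline(velocity):
    """Classical linear baseline M1(v) = 0.5046 v + 1 [MET]."""
    v = _check_velocity(velocity)
    out = LINEAR_BASELINE_SLOPE * v + 1.0
    return float(out) if np.isscalar(velocity) else out


@dataclass(frozen=True)
class PolynomialMetModel:
    """Order-K polynomial MET model with the intercept fixed at 1.

    ``coefficients`` are (a_1, ..., a_K); the resting unity term is implied.
    """

    coefficients: tuple[float, ...]
    population_label: str = ""
    training_velocity_max: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "coefficients", tuple(float(c) for c in self.coefficients))
        if len(self.coefficients) < 1:
            raise ValueError("polynomial model needs at least one coefficient")

    @property
    def order(self) -> int:
        return len(self.coefficients)

    def predict(self, velocity):
        """Evaluate 1 + sum_k a_k v^k (numerically stable Horner scheme)."""
        v = _check_velocity(velocity)
        out = np.polynomial.polynomial.polyval(v, np.concatenate(([1.0], self.coefficients)))
        return float(out) if np.isscalar(velocity) else out

    __call__ = predict

    def is_extrapolating(self, velocity) -> bool:
        """True if any queried velocity exceeds the largest training velocity."""
        if self.training_velocity_max is None:
            return False
        return bool(np.any(np.asarray(velocity, dtype=float) > self.training_velocity_max))


def derive_intercepts(slopes: Sequence[float], change_points: Sequence[float]) -> list[float]:
    """Intercepts of a continuous piecewise-linear MET curve.

    Continuity at each change point, together with the resting anchor
    b_1 = 1, determines every intercept:

        b_j = (a_{j-1} - a_j) * V_{j-1} + b_{j-1},   j = 2..n.
    """
    slopes = [float(a) for a in slopes]
    change_points = [float(v) for v in change_points]
    if len(slopes) != len(change_points) + 1:
        raise ValueError(
            f"{len(slopes)} slopes require {len(slopes) - 1} change points, "
            f"got {len(change_points)}"
        )
    if any(v <= 0 for v in change_points):
        raise ValueError("change points must be positive")
    if any(b <= a for a, b in zip(change_points, change_points[1:])):
        raise ValueError("change points must be strictly increasing")
    intercepts = [1.0]
    for j in range(1, len(slopes)):
        intercepts.append((slopes[j - 1] - slopes[j]) * change_points[j - 1] + intercepts[j - 1])
    return intercepts


@dataclass(frozen=True)
class PiecewiseMetModel:
    """Continuous n-segment piecewise-linear MET model.

    Segment j applies on [V_{j-1}, V_j) with V_0 = 0 and V_n = +inf; its
    intercept is derived from continuity (``derive_intercepts``), never
    stored independently, so the curve is continuous by construction and
    equals 1 MET at rest.
    """

    slopes: tuple[float, ...]
    change_points: tuple[float, ...]
    population_label: str = ""
    training_velocity_max: float | None = None
    intercepts: tuple[float, ...] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "slopes", tuple(float(a) for a in self.slopes))
        object.__setattr__(self, "change_points", tuple(float(v) for v in self.change_points))
        object.__setattr__(
            self, "intercepts", tuple(derive_intercepts(self.slopes, self.change_points))
        )

    @property
    def n_segments(self) -> int:
        return len(self.slopes)

    def predict(self, velocity):
        v = _check_velocity(velocity)
        seg = np.searchsorted(np.asarray(self.change_points), v, side="right")
        out = np.asarray(self.slopes)[seg] * v + np.asarray(self.intercepts)[seg]
        return float(out) if np.isscalar(velocity) else out

    __call__ = predict

    def is_extrapolating(self, velocity) -> bool:
        if self.training_velocity_max is None:
            return False
        return bool(np.any(np.asarray(velocity, dtype=float) > self.training_velocity_max))

    @classmethod
    def from_parameter_vector(
        cls, params: Sequence[float], n_segments: int, population_label: str = ""
    ) -> "PiecewiseMetModel":
        """Build from the stacked estimate vector C = [a_1..a_n, V_1..V_{n-1}]."""
        params = [float(p) for p in params]
        if len(params) != 2 * n_segments - 1:
            raise ValueError(
                f"{n_segments}-segment model needs {2 * n_segments - 1} parameters, "
                f"got {len(params)}"
            )
        return cls(
            slopes=tuple(params[:n_segments]),
            change_points=tuple(params[n_segments:]),
            population_label=population_label,
        )

    @property
    def parameter_vector(self) -> np.ndarray:
        return np.concatenate([self.slopes, self.change_points])


def switch_points(model: PiecewiseMetModel) -> list[float]:
    """MET values M^(i) = M_pl(V_i) at each change point.

    Strictly increasing whenever all slopes are positive; used as
    model-derived rehabilitation-class boundaries.
    """
    return [float(model.predict(v)) for v in model.change_points]


@dataclass(frozen=True)
class ReferenceVo2maxModel:
    """A published VO2max(T) formula for staged treadmill tests.

    ``coefficients`` are polynomial coefficients in walk time T [min],
    lowest order first; evaluation returns ml/kg/min.
    """

    name: str
    coefficients: tuple[float, ...]
    population_note: str = ""

    @property
    def kind(self) -> str:
        return "cubic-in-T" if len(self.coefficients) == 4 else "linear-in-T"

    def predict(self, walk_time: float) -> float:
        if walk_time < 0:
            raise ValueError("walk time must be non-negative")
        return float(np.polynomial.polynomial.polyval(walk_time, np.asarray(self.coefficients)))

    __call__ = predict


#: Published VO2max-vs-treadmill-time formulas (Bruce-protocol literature).
#: The cubic's offset 14.76 ml/kg/min is far from the ~3.5 resting uptake,
#: which is exactly the kind of resting-anchor defect the generalized MET
#: models avoid.
REFERENCE_VO2MAX_BANK: dict[str, ReferenceVo2maxModel] = {
    m.name: m
    for m in (
        ReferenceVo2maxModel(
            "bruce-cubic", (14.76, -1.379, 0.451, -0.012), "general; nonlinear in T"
        ),
        ReferenceVo2maxModel("women-a", (3.74, 2.94), "women"),
        ReferenceVo2maxModel("women-b", (-3.9, 4.38), "women"),
        ReferenceVo2maxModel("men", (7.65, 2.94), "men"),
        ReferenceVo2maxModel("young-men", (3.91, 3.62), "young men"),
    )
}


def evaluate_reference_vo2max(name: str, walk_time: float) -> float:
    """Evaluate a named bank formula at walk time T [min] -> ml/kg/min."""
    try:
        model = REFERENCE_VO2MAX_BANK[name]
    except KeyError:
        raise KeyError(
            f"unknown reference VO2max model {name!r}; "
            f"known: {sorted(REFERENCE_VO2MAX_BANK)}"
        ) from None
    return model.predict(walk_time)


# --- reference fitted models for the COPD study populations ----------------
# Parameter estimates obtained on the study cohort of 299 COPD patients
# (159 men, 140 women); polynomial order K = 3, piecewise n = 4 segments.

MEN_POLYNOMIAL = PolynomialMetModel((0.51701, -0.029094, 0.027643), "men")
WOMEN_POLYNOMIAL = PolynomialMetModel((0.1822, 0.092524, 0.015432), "women")
ALL_POLYNOMIAL = PolynomialMetModel((0.44886, -0.014615, 0.026691), "all")

MEN_PIECEWISE = PiecewiseMetModel(
    (0.4877, 1.544, 2.106, 4.194), (2.50, 4.429, 5.879), "men"
)
WOMEN_PIECEWISE = PiecewiseMetModel(
    (0.4866, 1.415, 1.99, 4.494), (2.68, 3.945, 5.798), "women"
)
ALL_PIECEWISE = PiecewiseMetModel(
    (0.494, 1.486, 2.081, 4.099), (2.602, 4.255, 5.814), "all"
)


# --- JSON (de)serialization -------------------------------------------------

def model_to_dict(model) -> dict:
    """Lossless dict form of any MET model, keyed by ``kind``."""
    if isinstance(model, PolynomialMetModel):
        return {
            "kind": "polynomial",
            "coefficients": list(model.coefficients),
            "population_label": model.population_label,
            "training_velocity_max": model.training_velocity_max,
        }
    if isinstance(model, PiecewiseMetModel):
        return {
            "kind": "piecewise",
            "slopes": list(model.slopes),
            "change_points": list(model.change_points),
            "population_label": model.population_label,
            "training_velocity_max": model.training_velocity_max,
        }
    raise TypeError(f"cannot serialize model of type {type(model).__name__}")


def model_from_dict(doc: dict):
    kind = doc.get("kind")
    if kind == "polynomial":
        return PolynomialMetModel(
            tuple(doc["coefficients"]),
            doc.get("population_label", ""),
            doc.get("training_velocity_max"),
        )
    if kind == "piecewise":
        return PiecewiseMetModel(
            tuple(doc["slopes"]),
            tuple(doc["change_points"]),
            doc.get("population_label", ""),
            doc.get("training_velocity_max"),
        )
    raise ValueError(f"unknown model kind {kind!r}")


def model_to_json(model) -> str:
    return json.dumps(model_to_dict(model), indent=2, sort_keys=True)


def model_from_json(text: str):
    return model_from_dict(json.loads(text))
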