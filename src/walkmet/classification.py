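"""Rehabilitation-class assignment from MET capacity.

Cardiopulmonary rehabilitation practice divides patients into four groups
by MET capacity.  The conventional division is

    A (less sick)   : M >= 7.0
    B (less medium) : 5.0 <= M < 7.0
    C (more medium) : 3.0 <= M < 5.0
    D (severe sick) : 1.0 <  M < 3.0

A fitted 4-segment piecewise MET model yields an alternative, data-driven
scheme: its three switch points M^(i) = M_pl(V_i) replace the conventional
boundaries 3/5/7.  Measured METs at or below the resting value 1.0 are
assigned to the most severe group with an explicit below-resting flag
rather than rejected — near-rest scores do occur in severe patients.
"""

from __future__ import annotations

from bisect import bisect_right
from collections import Counter
from dataclasses import dataclass

import numpy as np

from .cohort import Cohort
from .models import PiecewiseMetModel, switch_points

__all__ = [
    "RehabGroupScheme",
    "GroupAssignment",
    "CONVENTIONAL_SCHEME",
    "classify",
    "scheme_from_model",
    "assign_cohort",
    "scheme_disagreement",
]

DEFAULT_LABELS = ("D", "C", "B", "A")  # most severe -> least severe


@dataclass(frozen=True)
class RehabGroupScheme:
    """Ordered MET thresholds and the group labels they separate.

    ``labels`` run from most severe to least severe; label i applies on
    [boundaries[i-1], boundaries[i]) with the lower bound closed, so a MET
    exactly at a boundary belongs to the less-severe side (e.g. M = 7.0 is
    group A conventionally).
    """

    boundaries: tuple[float, ...]
    labels: tuple[str, ...] = DEFAULT_LABELS
    provenance: str = "conventional"

    def __post_init__(self) -> None:
        object.__setattr__(self, "boundaries", tuple(float(b) for b in self.boundaries))
        object.__setattr__(self, "labels", tuple(self.labels))
        if any(b2 <= b1 for b1, b2 in zip(self.boundaries, self.boundaries[1:])):
            raise ValueError("boundaries must be strictly increasing")
        if len(self.labels) != len(self.boundaries) + 1:
            raise ValueError(
                f"{len(self.boundaries)} boundaries require "
                f"{len(self.boundaries) + 1} labels, got {len(self.labels)}"
            )

    def rank(self, label: str) -> int:
        """Severity rank: 0 = most severe."""
        return self.labels.index(label)


CONVENTIONAL_SCHEME = RehabGroupScheme((3.0, 5.0, 7.0))


@dataclass(frozen=True)
class GroupAssignment:
    label: str
    below_resting: bool = False


def classify(met: float, scheme: RehabGroupScheme = CONVENTIONAL_SCHEME) -> GroupAssignment:
    """Assign one MET value to a rehabilitation group.

    Monotone in MET with respect to the severity ordering; M <= 1.0 maps to
    the most severe group with ``below_resting`` set.
    """
    if met <= 0:
        raise ValueError(f"MET must be positive, got {met}")
    if met <= 1.0:
        return GroupAssignment(scheme.labels[0], below_resting=True)
    return GroupAssignment(scheme.labels[bisect_right(scheme.boundaries, met)])


def scheme_from_model(model: PiecewiseMetModel) -> RehabGroupScheme:
    """Build a four-class scheme from a 4-segment model's switch points."""
    if model.n_segments != 4:
        raise ValueError(
            "model-derived schemes need a 4-segment model (3 switch points "
            f"-> 4 classes); got {model.n_segments} segments"
        )
    return RehabGroupScheme(
        tuple(switch_points(model)),
        provenance=f"model-derived:{model.population_label or 'unlabeled'}",
    )


def assign_cohort(
    cohort: Cohort, scheme: RehabGroupScheme = CONVENTIONAL_SCHEME
) -> tuple[list[GroupAssignment], dict[str, int]]:
    """Label every record; returns (assignments, per-group counts).

    Counts include every group label (zero when empty) and always sum to N.
    """
    assignments = [classify(m, scheme) for m in cohort.mets]
    counts = Counter(a.label for a in assignments)
    return assignments, {label: counts.get(label, 0) for label in scheme.labels}


def scheme_disagreement(
    cohort: Cohort, scheme_a: RehabGroupScheme, scheme_b: RehabGroupScheme
) -> np.ndarray:
    """Indices of records the two schemes place in different groups.

    Group identity is compared by severity rank so schemes with different
    label sets remain comparable.
    """
    ranks_a = [scheme_a.rank(classify(m, scheme_a).label) for m in cohort.mets]
    ranks_b = [scheme_b.rank(classify(m, scheme_b).label) for m in cohort.mets]
    return np.flatnonzero(np.asarray(ranks_a) != np.asarray(ranks_b))
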