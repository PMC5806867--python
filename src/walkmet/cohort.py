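"""Cohort container for paired 6MWT / treadmill-test measurements.

A :class:`WalkRecord` pairs one patient's six-minute-walk result (distance in
meters, or equivalently the average velocity ``v_6M = D/100`` in km/h) with
the MET score of their submaximal treadmill exercise test.  A
:class:`Cohort` is a labeled collection of such records backed by numpy
arrays, which is what the fitting and validation routines consume.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

__all__ = ["WalkRecord", "Cohort"]


@dataclass(frozen=True)
class WalkRecord:
    """One patient's 6MWT measurement paired with a treadmill MET score.

    ``distance_m`` and ``velocity_kmh`` are locked together by the 6MWT
    identity v_6M = D/100; construct from either via the class methods.
    """

    distance_m: float
    met: float
    sex: str | None = None
    age: float | None = None

    def __post_init__(self) -> None:
        if self.distance_m < 0:
            raise ValueError(f"negative walk distance: {self.distance_m}")
        if self.met <= 0:
            raise ValueError(f"non-positive MET score: {self.met}")
        if self.sex is not None and self.sex not in ("male", "female"):
            raise ValueError(f"sex must be 'male' or 'female', got {self.sex!r}")
        if self.age is not None and self.age <= 0:
            raise ValueError(f"non-positive age: {self.age}")

    @property
    def velocity_kmh(self) -> float:
        """Six-minute equivalent velocity v_6M = D/100 [km/h]."""
        return self.distance_m / 100.0

    @classmethod
    def from_velocity(
        cls,
        velocity_kmh: float,
        met: float,
        sex: str | None = None,
        age: float | None = None,
    ) -> "WalkRecord":
        return cls(distance_m=100.0 * velocity_kmh, met=met, sex=sex, age=age)


@dataclass
class Cohort:
    """A labeled collection of walk records.

    Velocities are the canonical abscissa (km/h); distances are recovered as
    ``100 * velocity``.
    """

    velocities: np.ndarray
    mets: np.ndarray
    label: str = ""
    sexes: np.ndarray | None = None
    ages: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.velocities = np.asarray(self.velocities, dtype=float)
        self.mets = np.asarray(self.mets, dtype=float)
        if self.velocities.shape != self.mets.shape or self.velocities.ndim != 1:
            raise ValueError("velocities and mets must be equal-length 1-D arrays")
        if np.any(self.velocities < 0):
            raise ValueError("negative velocity in cohort")
        if np.any(self.mets <= 0):
            raise ValueError("non-positive MET in cohort")
        for name in ("sexes", "ages"):
            arr = getattr(self, name)
            if arr is not None:
                arr = np.asarray(arr)
                if arr.shape != self.velocities.shape:
                    raise ValueError(f"{name} length does not match cohort size")
                setattr(self, name, arr)

    def __len__(self) -> int:
        return self.velocities.size

    @property
    def size(self) -> int:
        return len(self)

    @property
    def distances(self) -> np.ndarray:
        return 100.0 * self.velocities

    def __iter__(self) -> Iterator[WalkRecord]:
        for i in range(len(self)):
            yield WalkRecord(
                distance_m=100.0 * self.velocities[i],
                met=self.mets[i],
                sex=None if self.sexes is None else str(self.sexes[i]),
                age=None if self.ages is None else float(self.ages[i]),
            )

    @classmethod
    def from_records(cls, records: Iterable[WalkRecord], label: str = "") -> "Cohort":
        recs = list(records)
        sexes = [r.sex for r in recs]
        ages = [r.age for r in recs]
        return cls(
            velocities=np.array([r.velocity_kmh for r in recs], dtype=float),
            mets=np.array([r.met for r in recs], dtype=float),
            label=label,
            sexes=np.array(sexes, dtype=object) if any(s is not None for s in sexes) else None,
            ages=np.array(ages, dtype=float) if all(a is not None for a in ages) and recs else None,
        )

    @classmethod
    def concat(cls, cohorts: Sequence["Cohort"], label: str = "all") -> "Cohort":
        """Concatenate cohorts; the 'all patients' population is always built
        this way (N_p = N_m + N_w), never re-read from a third source."""
        if not cohorts:
            raise ValueError("cannot concatenate zero cohorts")
        sexes = None
        if all(c.sexes is not None for c in cohorts):
            sexes = np.concatenate([c.sexes for c in cohorts])
        ages = None
        if all(c.ages is not None for c in cohorts):
            ages = np.concatenate([c.ages for c in cohorts])
        return cls(
            velocities=np.concatenate([c.velocities for c in cohorts]),
            mets=np.concatenate([c.mets for c in cohorts]),
            label=label,
            sexes=sexes,
            ages=ages,
        )

    def subset(self, index: np.ndarray, label: str | None = None) -> "Cohort":
        return Cohort(
            velocities=self.velocities[index],
            mets=self.mets[index],
            label=self.label if label is None else label,
            sexes=None if self.sexes is None else self.sexes[index],
            ages=None if self.ages is None else self.ages[index],
        )

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "distance_m": self.distances,
                "velocity_kmh": self.velocities,
                "met": self.mets,
            }
        )
        if self.sexes is not None:
            df["sex"] = self.sexes
        if self.ages is not None:
            df["age"] = self.ages
        return df
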