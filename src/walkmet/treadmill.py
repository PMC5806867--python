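"""Fixed-paced treadmill test conversions.

A fixed-paced (staged) treadmill protocol prescribes a belt velocity v_i
[km/h] for each stage i of duration T_{s,i} [min].  A patient's raw result
is the walk time T; the framework converts it into the walked distance

    D = (50/3) * sum_{i<=S} T_{s,i} * v_i  +  (50/3) * dT * v_{S+1}   [m]

where S is the number of *completed* stages and dT the time spent in the
uncompleted stage.  From D come the average velocity v = (3/50) D/T [km/h]
and the six-minute-walk equivalent velocity v_6M = D/100 [km/h], which put
treadmill scores and 6MWT scores on a common abscissa.  The rational factor
50/3 (= 1000/60 m/min per km/h) is used exactly; nothing is rounded until
display.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

__all__ = [
    "TreadmillProtocol",
    "TreadmillOutcome",
    "PatientProfile",
    "MBRUCE",
    "split_walk_time",
    "walked_distance",
    "average_velocity",
    "six_minute_velocity",
    "predicted_hr_limit",
    "convert",
]

#: meters per minute in one km/h; exact rational used throughout
_KMH_TO_M_PER_MIN = 50.0 / 3.0


@dataclass(frozen=True)
class TreadmillProtocol:
    """A staged, fixed-paced treadmill protocol.

    Parameters
    ----------
    name
        Text label, e.g. ``"mbruce"``.
    stage_durations
        Per-stage durations T_{s,i} [min]; all positive.
    stage_velocities
        Per-stage belt velocities v_i [km/h]; all non-negative.
    met_table
        Optional tabulated walk-time -> MET scores as reported by the test
        device.  The mapping is tabulated input, not a formula: devices such
        as the Cardioperfect report METs against protocol time directly.
    """

    name: str
    stage_durations: tuple[float, ...]
    stage_velocities: tuple[float, ...]
    met_table: Mapping[float, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "stage_durations", tuple(float(d) for d in self.stage_durations))
        object.__setattr__(self, "stage_velocities", tuple(float(v) for v in self.stage_velocities))
        if len(self.stage_durations) != len(self.stage_velocities):
            raise ValueError("stage_durations and stage_velocities must have equal length")
        if len(self.stage_durations) < 1:
            raise ValueError("protocol needs at least one stage")
        if any(d <= 0 for d in self.stage_durations):
            raise ValueError("all stage durations must be positive")
        if any(v < 0 for v in self.stage_velocities):
            raise ValueError("stage velocities must be non-negative")

    @property
    def n_stages(self) -> int:
        return len(self.stage_durations)

    @property
    def total_duration(self) -> float:
        return sum(self.stage_durations)

    def met_for_time(self, walk_time: float) -> float:
        """Tabulated MET score for a walk time; KeyError if not tabulated."""
        try:
            return self.met_table[walk_time]
        except KeyError:
            raise KeyError(
                f"no tabulated MET score for walk time {walk_time} min "
                f"in protocol {self.name!r}"
            ) from None

    @classmethod
    def from_dict(cls, spec: Mapping) -> "TreadmillProtocol":
        """Build from a config mapping (keys: name, stage_durations,
        stage_velocities, optional met_table)."""
        met_table = {float(k): float(v) for k, v in dict(spec.get("met_table", {})).items()}
        return cls(
            name=str(spec["name"]),
            stage_durations=tuple(spec["stage_durations"]),
            stage_velocities=tuple(spec["stage_velocities"]),
            met_table=met_table,
        )


#: Modified Bruce preset: 3-minute stages, stages 1-3 at 2.7 km/h, stage 4 at
#: 4.0 km/h.  Later stages of the published protocol can be appended via a
#: custom TreadmillProtocol; the one tabulated (time, MET) score shipped is
#: the device-reported 5.95 MET at T = 10.5 min.
MBRUCE = TreadmillProtocol(
    name="mbruce",
    stage_durations=(3.0, 3.0, 3.0, 3.0),
    stage_velocities=(2.7, 2.7, 2.7, 4.0),
    met_table={10.5: 5.95},
)


@dataclass(frozen=True)
class TreadmillOutcome:
    """Derived quantities for one treadmill walk time under a protocol."""

    walk_time: float
    completed_stages: int
    partial_stage_time: float
    distance: float
    average_velocity: float
    six_minute_equivalent_velocity: float


@dataclass(frozen=True)
class PatientProfile:
    """Minimal patient descriptor; age drives the HRmax formula."""

    age: float
    sex: str | None = None
    body_mass: float | None = None
    height: float | None = None

    def __post_init__(self) -> None:
        if self.age <= 0:
            raise ValueError("age must be positive")
        if self.body_mass is not None and self.body_mass <= 0:
            raise ValueError("body mass must be positive when given")
        if self.height is not None and self.height <= 0:
            raise ValueError("height must be positive when given")


def split_walk_time(protocol: TreadmillProtocol, walk_time: float) -> tuple[int, float]:
    """Split a walk time into (completed stages S, partial stage time dT).

    S is the largest stage count whose cumulative duration does not exceed
    ``walk_time``; a walk time landing exactly on a stage boundary is
    attributed to the completed stage (dT = 0), so dT is always strictly less
    than the next stage's duration unless the protocol is exhausted.
    """
    if walk_time < 0:
        raise ValueError(f"walk time must be non-negative, got {walk_time}")
    total = protocol.total_duration
    if walk_time > total + 1e-12:
        raise ValueError(
            f"walk time {walk_time} min exceeds protocol duration {total} min"
        )
    elapsed = 0.0
    for s, dur in enumerate(protocol.stage_durations):
        if walk_time <= elapsed + dur or s == protocol.n_stages - 1:
            d_t = walk_time - elapsed
            if abs(d_t - dur) < 1e-12:  # boundary -> stage counted as completed
                return s + 1, 0.0
            return s, d_t
        elapsed += dur
    raise AssertionError("unreachable")


def walked_distance(protocol: TreadmillProtocol, walk_time: float) -> float:
    """Distance D [m] walked in ``walk_time`` minutes under the protocol."""
    s, d_t = split_walk_time(protocol, walk_time)
    completed = sum(
        protocol.stage_durations[i] * protocol.stage_velocities[i] for i in range(s)
    )
    partial = d_t * protocol.stage_velocities[s] if d_t > 0 else 0.0
    return _KMH_TO_M_PER_MIN * (completed + partial)


def average_velocity(distance: float, walk_time: float) -> float:
    """Average velocity v = (3/50) * D / T [km/h]."""
    if walk_time <= 0:
        raise ValueError("walk time must be positive to compute a velocity")
    if distance < 0:
        raise ValueError("distance must be non-negative")
    return (3.0 / 50.0) * distance / walk_time


def six_minute_velocity(distance: float) -> float:
    """Six-minute-walk equivalent velocity v_6M = D/100 [km/h]."""
    if distance < 0:
        raise ValueError("distance must be non-negative")
    return distance / 100.0


def predicted_hr_limit(profile: PatientProfile, fraction: float = 1.0) -> float:
    """Target heart rate: fraction of HRmax = 208 - 0.7 * age [beats/min].

    Submaximal testing conventionally terminates at 70-80% of predicted
    HRmax, i.e. ``fraction`` in [0.70, 0.80].
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    return fraction * (208.0 - 0.7 * profile.age)


def convert(protocol: TreadmillProtocol, walk_time: float) -> TreadmillOutcome:
    """Full conversion of a walk time into the outcome bundle."""
    s, d_t = split_walk_time(protocol, walk_time)
    dist = walked_distance(protocol, walk_time)
    v = average_velocity(dist, walk_time) if walk_time > 0 else 0.0
    return TreadmillOutcome(
        walk_time=walk_time,
        completed_stages=s,
        partial_stage_time=d_t,
        distance=dist,
        average_velocity=v,
        six_minute_equivalent_velocity=six_minute_velocity(dist),
    )
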