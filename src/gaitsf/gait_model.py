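"""Domain types, unit/side conventions and the Perry gait-phase taxonomy.

All angles are in degrees, all times within a cycle in percent of cycle
time (%CT, equivalently %GC), running 0..100 from one initial contact of a
foot to the next initial contact of the same foot. The canonical sampling
grid has 101 points at 1%CT spacing.

Perry's eight phases are used to localise events within the cycle:
loading response (LR), midstance (MSt), terminal stance (TSt), terminal
double stance (TDSt), initial swing (ISw), midswing (MSw) and terminal
swing (TSw) tile [0, 100]; initial contact (IC, 0-2%CT) overlaps LR and is
reported as a flag rather than a ninth disjoint phase.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InputError, InsufficientDataError

__all__ = [
    "Group",
    "Side",
    "Joint",
    "GaitPhase",
    "PhaseHit",
    "PHASES",
    "IC",
    "GRID",
    "AngleCycle",
    "NormalizedCurve",
    "SFCurve",
    "CurveParams",
    "SubjectSet",
    "locate_phase",
    "canonical_sign_labels",
    "opposite_side",
]

#: Canonical percent-cycle grid: 0, 1, ..., 100 %CT.
GRID: np.ndarray = np.arange(101.0)
GRID.setflags(write=False)


class Group(str, Enum):
    UTHR = "uTHR"
    NORMAL = "normal"


class Side(str, Enum):
    RIGHT = "right"
    LEFT = "left"
    INVOLVED = "involved"
    UNINVOLVED = "uninvolved"


class Joint(str, Enum):
    PELVIS = "pelvis_tilt"
    HIP = "hip_flexext"
    KNEE = "knee_flexext"
    ANKLE = "ankle_dorsiplantar"


_SIDE_OPPOSITE = {
    Side.RIGHT: Side.LEFT,
    Side.LEFT: Side.RIGHT,
    Side.INVOLVED: Side.UNINVOLVED,
    Side.UNINVOLVED: Side.INVOLVED,
}


def opposite_side(side: Side | str) -> Side:
    """Contralateral side: right<->left, involved<->uninvolved."""
    return _SIDE_OPPOSITE[Side(side)]


@dataclass(frozen=True)
class GaitPhase:
    """One Perry phase as a %CT interval."""

    name: str
    start_pct: float
    end_pct: float

    def __contains__(self, t: float) -> bool:
        return self.start_pct <= t < self.end_pct


#: The seven disjoint phases tiling [0, 100]; IC overlaps LR and is kept
#: separate (see :data:`IC`).
PHASES: tuple[GaitPhase, ...] = (
    GaitPhase("LR", 0.0, 10.0),
    GaitPhase("MSt", 10.0, 30.0),
    GaitPhase("TSt", 30.0, 50.0),
    GaitPhase("TDSt", 50.0, 60.0),
    GaitPhase("ISw", 60.0, 73.0),
    GaitPhase("MSw", 73.0, 87.0),
    GaitPhase("TSw", 87.0, 100.0),
)

#: Initial contact, overlapping the first 2%CT of LR.
IC = GaitPhase("IC", 0.0, 2.0)


@dataclass(frozen=True)
class PhaseHit:
    """Result of phase lookup: the primary phase plus the IC-overlap flag."""

    phase: GaitPhase
    ic: bool

    @property
    def name(self) -> str:
        return self.phase.name


def locate_phase(t: float) -> PhaseHit:
    """Map a cycle time ``t`` (%CT) to its Perry phase.

    Intervals are half-open ``[start, end)``; ``t = 100`` belongs to TSw.
    ``ic`` is True for ``t <= 2`` where initial contact overlaps loading
    response.

    Raises
    ------
    InputError
        If ``t`` lies outside [0, 100].
    """
    if not np.isfinite(t) or t < 0.0 or t > 100.0:
        raise InputError(f"cycle time {t!r} outside [0, 100] %CT")
    ic = t <= IC.end_pct
    if t == 100.0:
        return PhaseHit(PHASES[-1], ic)
    for phase in PHASES:
        if t in phase:
            return PhaseHit(phase, ic)
    raise AssertionError("phases do not tile [0, 100]")  # pragma: no cover


def canonical_sign_labels(comparison_mode: str) -> tuple[Side, Side]:
    """Side/curve labels for a comparison mode; sign of SF = first - second.

    ``normal_LR``       -> (right, left):        positive SF = right dominance.
    ``uTHR_sides``      -> (uninvolved, involved): positive = uninvolved
                           (unoperated) side dominance.
    ``uTHR_vs_normal``  -> (normal reference, involved): positive = normal
                           curve dominance.
    """
    modes = {
        "normal_LR": (Side.RIGHT, Side.LEFT),
        "uTHR_sides": (Side.UNINVOLVED, Side.INVOLVED),
        "uTHR_vs_normal": (Side.RIGHT, Side.INVOLVED),
    }
    try:
        return modes[comparison_mode]
    except KeyError:
        raise ConfigurationError(
            f"unknown comparison mode {comparison_mode!r}; "
            f"expected one of {sorted(modes)}"
        ) from None


# ---------------------------------------------------------------------------
# Data containers
# ---------------------------------------------------------------------------


def _as_float_array(values: Sequence[float] | np.ndarray, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise InputError(f"{name} must be one-dimensional")
    return arr


@dataclass(frozen=True)
class AngleCycle:
    """One side's joint-angle trace over a single gait cycle.

    ``times`` are in seconds (strictly increasing, >= 4 samples), ``angles``
    in degrees. The first and last sample define 0 and 100%CT; cycle
    segmentation is the caller's responsibility.
    """

    subject_id: str
    group: Group
    side: Side
    joint: Joint
    times: np.ndarray
    angles: np.ndarray
    cycle_index: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "group", Group(self.group))
        object.__setattr__(self, "side", Side(self.side))
        object.__setattr__(self, "joint", Joint(self.joint))
        times = _as_float_array(self.times, "times")
        angles = _as_float_array(self.angles, "angles")
        if times.size != angles.size:
            raise InputError(
                f"times ({times.size}) and angles ({angles.size}) differ in length"
            )
        if times.size < 4:
            raise InsufficientDataError(
                f"cycle needs >= 4 samples, got {times.size}"
            )
        if not np.all(np.diff(times) > 0):
            raise InputError("cycle times must be strictly increasing")
        if not np.all(np.isfinite(angles)):
            raise InputError("cycle angles must be finite")
        times.setflags(write=False)
        angles.setflags(write=False)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "angles", angles)

    @property
    def n_samples(self) -> int:
        return int(self.times.size)

    @property
    def duration(self) -> float:
        """Cycle duration in seconds."""
        return float(self.times[-1] - self.times[0])


@dataclass(frozen=True)
class NormalizedCurve:
    """An angle curve resampled to the canonical 0-100%CT grid.

    ``values`` holds the angle in degrees at 0, 1, ..., 100 %CT (101 points
    by default; other lengths are permitted for testing the resampler but
    are rejected by :func:`gaitsf.normalization.validate_pair`).
    """

    values: np.ndarray
    joint: Joint | None = None
    side: Side | None = None
    subject_id: str | None = None
    group: Group | None = None
    cycle_index: int | None = None

    def __post_init__(self) -> None:
        values = _as_float_array(self.values, "values")
        if values.size < 2:
            raise InputError("a normalized curve needs at least 2 values")
        if not np.all(np.isfinite(values)):
            raise InputError("normalized curve values must be finite")
        values.setflags(write=False)
        object.__setattr__(self, "values", values)
        if self.joint is not None:
            object.__setattr__(self, "joint", Joint(self.joint))
        if self.side is not None:
            object.__setattr__(self, "side", Side(self.side))
        if self.group is not None:
            object.__setattr__(self, "group", Group(self.group))

    @property
    def grid(self) -> np.ndarray:
        """%CT positions of the values (0..100, evenly spaced)."""
        if self.values.size == GRID.size:
            return GRID
        return np.linspace(0.0, 100.0, self.values.size)

    def with_values(self, values: np.ndarray) -> "NormalizedCurve":
        return replace(self, values=values)


@dataclass(frozen=True)
class SFCurve:
    """A symmetry-function trace (percent) on the %CT grid.

    Sign convention: ``values > 0`` where the ``first_label`` curve exceeds
    the ``second_label`` curve.
    """

    values: np.ndarray
    first_label: str
    second_label: str
    joint: Joint | None = None

    def __post_init__(self) -> None:
        values = _as_float_array(self.values, "values")
        if not np.all(np.isfinite(values)):
            raise InputError("SF values must be finite")
        values.setflags(write=False)
        object.__setattr__(self, "values", values)
        if self.joint is not None:
            object.__setattr__(self, "joint", Joint(self.joint))

    @property
    def grid(self) -> np.ndarray:
        if self.values.size == GRID.size:
            return GRID
        return np.linspace(0.0, 100.0, self.values.size)


@dataclass(frozen=True)
class CurveParams:
    """Extremes of a curve: Peak^min/Peak^max, their %CT, and the range.

    Units follow the source curve: degrees for angle curves, percent for SF
    curves. ``rom = peak_max - peak_min`` by construction.
    """

    peak_min: float
    t_min: float
    peak_max: float
    t_max: float
    rom: float

    def __post_init__(self) -> None:
        if self.rom < -1e-12:
            raise InputError("rom must be non-negative")
        for t in (self.t_min, self.t_max):
            if not 0.0 <= t <= 100.0:
                raise InputError(f"peak time {t} outside [0, 100] %CT")

    FIELDS = ("peak_min", "t_min", "peak_max", "t_max", "rom")

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in self.FIELDS}


@dataclass
class SubjectSet:
    """A collection of AngleCycles grouped by subject/side/joint."""

    cycles: list[AngleCycle] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.cycles)

    def __iter__(self) -> Iterator[AngleCycle]:
        return iter(self.cycles)

    def add(self, cycle: AngleCycle) -> None:
        self.cycles.append(cycle)

    def extend(self, cycles: Iterable[AngleCycle]) -> None:
        self.cycles.extend(cycles)

    def subjects(self, group: Group | str | None = None) -> list[str]:
        if group is not None:
            group = Group(group)
        seen: dict[str, None] = {}
        for c in self.cycles:
            if group is None or c.group == group:
                seen.setdefault(c.subject_id, None)
        return list(seen)

    def joints(self) -> list[Joint]:
        seen: dict[Joint, None] = {}
        for c in self.cycles:
            seen.setdefault(c.joint, None)
        return list(seen)

    def select(
        self,
        *,
        subject_id: str | None = None,
        group: Group | str | None = None,
        side: Side | str | None = None,
        joint: Joint | str | None = None,
    ) -> "SubjectSet":
        """Filter cycles on any combination of keys."""
        group = Group(group) if group is not None else None
        side = Side(side) if side is not None else None
        joint = Joint(joint) if joint is not None else None
        out = [
            c
            for c in self.cycles
            if (subject_id is None or c.subject_id == subject_id)
            and (group is None or c.group == group)
            and (side is None or c.side == side)
            and (joint is None or c.joint == joint)
        ]
        return SubjectSet(out)

    def to_frame(self) -> pd.DataFrame:
        """Long-format dataframe: one row per sample."""
        parts = []
        for c in self.cycles:
            parts.append(
                pd.DataFrame(
                    {
                        "subject_id": c.subject_id,
                        "group": c.group.value,
                        "side": c.side.value,
                        "joint": c.joint.value,
                        "cycle_index": c.cycle_index,
                        "time_s": c.times,
                        "angle_deg": c.angles,
                    }
                )
            )
        if not parts:
            return pd.DataFrame(
                columns=[
                    "subject_id",
                    "group",
                    "side",
                    "joint",
                    "cycle_index",
                    "time_s",
                    "angle_deg",
                ]
            )
        return pd.concat(parts, ignore_index=True)
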