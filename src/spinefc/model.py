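"""Core data model: units, spike trains and trials.

Spike times are stored in milliseconds from trial start as float64; trial
durations in seconds. A :class:`Trial` bundles the spike trains of one
recording epoch with the array geometry under which its units were localized
and is the unit of FDR control downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from .errors import TrialValidationError
from .geometry import ArrayGeometry, assign_region


@dataclass(frozen=True)
class UnitMeta:
    """Identity and anatomical provenance of one sorted unit."""

    unit_id: str
    electrode_id: int
    depth_um: float
    region: str
    admissible: bool = True

    def with_admissible(self, flag: bool) -> "UnitMeta":
        return replace(self, admissible=flag)


class SpikeTrain:
    """Ordered spike times (ms) of one unit within one trial."""

    __slots__ = ("unit", "times")

    def __init__(self, unit: UnitMeta, times: Iterable[float], *, copy: bool = True):
        arr = np.asarray(times, dtype=np.float64)
        if copy:
            arr = arr.copy()
        if arr.ndim != 1:
            raise TrialValidationError(f"unit {unit.unit_id}: times must be 1-D")
        if arr.size and np.any(np.diff(arr) < 0):
            arr = np.sort(arr)
        self.unit = unit
        self.times = arr

    @property
    def n_spikes(self) -> int:
        return int(self.times.size)

    def isi(self) -> np.ndarray:
        """Inter-spike intervals in ms (empty for <2 spikes)."""
        return np.diff(self.times)

    def validate(self, duration_ms: float, *, reject_duplicates: bool = True) -> None:
        t = self.times
        if t.size == 0:
            return
        if t[0] < 0 or t[-1] > duration_ms:
            raise TrialValidationError(
                f"unit {self.unit.unit_id}: spike times outside [0, {duration_ms}] ms "
                f"(range {t[0]}..{t[-1]})")
        if reject_duplicates and np.any(np.diff(t) == 0):
            raise TrialValidationError(
                f"unit {self.unit.unit_id}: exact duplicate spike times")

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, SpikeTrain)
            and self.unit == other.unit
            and np.array_equal(self.times, other.times)
        )

    def __repr__(self) -> str:
        return f"SpikeTrain(unit={self.unit.unit_id!r}, n_spikes={self.n_spikes})"


@dataclass
class Trial:
    """A population of spike trains plus geometry and duration."""

    trial_id: str
    duration_s: float
    geometry: ArrayGeometry
    trains: list[SpikeTrain] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise TrialValidationError("duration_s must be positive")
        # deterministic order everywhere downstream
        self.trains = sorted(self.trains, key=lambda tr: tr.unit.unit_id)

    @property
    def duration_ms(self) -> float:
        return self.duration_s * 1000.0

    @property
    def n_units(self) -> int:
        return len(self.trains)

    def unit_ids(self) -> list[str]:
        return [tr.unit.unit_id for tr in self.trains]

    def train_of(self, unit_id: str) -> SpikeTrain:
        for tr in self.trains:
            if tr.unit.unit_id == unit_id:
                return tr
        raise KeyError(unit_id)

    def validate(self, *, reject_duplicates: bool = True) -> None:
        seen: set[str] = set()
        for tr in self.trains:
            u = tr.unit
            if u.unit_id in seen:
                raise TrialValidationError(f"duplicate unit_id {u.unit_id!r}")
            seen.add(u.unit_id)
            if not self.geometry.has_electrode(u.electrode_id):
                raise TrialValidationError(
                    f"unit {u.unit_id}: unknown electrode_id {u.electrode_id}")
            expected = assign_region(u.depth_um, self.geometry)
            if u.region != expected:
                raise TrialValidationError(
                    f"unit {u.unit_id}: region {u.region} inconsistent with depth "
                    f"{u.depth_um} um (expected {expected})")
            tr.validate(self.duration_ms, reject_duplicates=reject_duplicates)

    def with_trains(self, trains: Sequence[SpikeTrain]) -> "Trial":
        return Trial(self.trial_id, self.duration_s, self.geometry, list(trains))

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, Trial)
            and self.trial_id == other.trial_id
            and self.duration_s == other.duration_s
            and self.geometry == other.geometry
            and self.trains == other.trains
        )


def make_unit(unit_id: str, electrode_id: int, geometry: ArrayGeometry,
              *, admissible: bool = True) -> UnitMeta:
    """UnitMeta with depth and region filled in from the electrode position."""
    depth = geometry.depth_of(int(electrode_id))
    return UnitMeta(
        unit_id=str(unit_id),
        electrode_id=int(electrode_id),
        depth_um=depth,
        region=assign_region(depth, geometry),
        admissible=admissible,
    )
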