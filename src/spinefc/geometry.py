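"""Electrode-array geometry and depth-defined anatomical regions.

The recordings this package models come from dual-shank linear silicon probes
implanted through the dorsoventral extent of the lumbar spinal gray matter.
Each contact sits at a known depth below the dorsal surface, and contacts are
partitioned into four depth-defined regions:

* ``sDH`` — superficial dorsal horn (surface to ~400 um, laminae I-III)
* ``dDH`` — deep dorsal horn (~500-1000 um, laminae III/IV-VI)
* ``IG``  — intermediate gray (~1100-1300 um, laminae VII-VIII)
* ``VH``  — ventral horn (~1400-1600+ um, laminae VIII-IX)

The published depth ranges leave gaps (e.g. ~400 vs ~500 um); cut-points are
therefore placed at the midpoints 450/1050/1350 um, which reproduces the
8/12/6/6 electrodes-per-region split of the default 2x16, 100-um-pitch array.
Boundaries are configurable per trial through the metadata sidecar.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property
from typing import Mapping, Sequence

import pandas as pd

from .errors import ConfigurationError

#: Canonical region order, dorsal to ventral.
REGIONS: tuple[str, ...] = ("sDH", "dDH", "IG", "VH")

_REGION_INDEX: Mapping[str, int] = {r: i for i, r in enumerate(REGIONS)}

#: The ten unordered region-pair categories, in canonical (figure) order.
REGION_PAIR_CATEGORIES: tuple[str, ...] = (
    "sDH-sDH", "sDH-dDH", "sDH-IG", "sDH-VH",
    "dDH-dDH", "dDH-IG", "dDH-VH",
    "IG-IG", "IG-VH",
    "VH-VH",
)

#: Same-region ("within") categories.
WITHIN_CATEGORIES: tuple[str, ...] = ("sDH-sDH", "dDH-dDH", "IG-IG", "VH-VH")


def pair_category_label(region_a: str, region_b: str) -> str:
    """Unordered category label for a pair of regions.

    ``pair_category_label("dDH", "sDH") == "sDH-dDH"``: categories are
    combinations, not permutations, ordered dorsal-first.
    """
    for r in (region_a, region_b):
        if r not in _REGION_INDEX:
            raise ValueError(f"unknown region {r!r}; expected one of {REGIONS}")
    a, b = sorted((region_a, region_b), key=_REGION_INDEX.__getitem__)
    return f"{a}-{b}"


@dataclass(frozen=True)
class ArrayGeometry:
    """Layout of a multi-shank linear electrode array in depth coordinates.

    Electrode ids are integers ``1..n_shanks*contacts_per_shank``, assigned
    shank-major, dorsal to ventral: row 0 is the most superficial contact and
    depth increases by exactly ``pitch_um`` per row.
    """

    n_shanks: int = 2
    contacts_per_shank: int = 16
    pitch_um: float = 100.0
    top_row_depth_um: float = 100.0
    region_boundaries_um: tuple[float, float, float] = (450.0, 1050.0, 1350.0)

    def __post_init__(self) -> None:
        if self.n_shanks < 1 or self.contacts_per_shank < 1:
            raise ConfigurationError("geometry needs at least one shank and contact")
        if self.pitch_um <= 0:
            raise ConfigurationError("pitch_um must be positive")
        if self.top_row_depth_um < 0:
            raise ConfigurationError("top_row_depth_um must be non-negative")
        b = tuple(float(x) for x in self.region_boundaries_um)
        if len(b) != len(REGIONS) - 1 or any(b[i] >= b[i + 1] for i in range(len(b) - 1)):
            raise ConfigurationError(
                "region_boundaries_um must be 3 strictly increasing depths")
        object.__setattr__(self, "region_boundaries_um", b)

    # -- derived layout -------------------------------------------------

    @property
    def n_electrodes(self) -> int:
        return self.n_shanks * self.contacts_per_shank

    @property
    def tip_depth_um(self) -> float:
        """Depth of the deepest contact row."""
        return self.top_row_depth_um + (self.contacts_per_shank - 1) * self.pitch_um

    def depth_of_row(self, row: int) -> float:
        return self.top_row_depth_um + row * self.pitch_um

    @cached_property
    def _contact_index(self) -> dict[int, tuple[int, int, float, str]]:
        table: dict[int, tuple[int, int, float, str]] = {}
        for shank in range(self.n_shanks):
            for row in range(self.contacts_per_shank):
                eid = shank * self.contacts_per_shank + row + 1
                depth = self.depth_of_row(row)
                table[eid] = (shank, row, depth, assign_region(depth, self))
        return table

    def contacts(self) -> pd.DataFrame:
        """Contact table: electrode_id, shank, row, depth_um, region."""
        rows = [
            {"electrode_id": eid, "shank": s, "row": r, "depth_um": d, "region": reg}
            for eid, (s, r, d, reg) in sorted(self._contact_index.items())
        ]
        return pd.DataFrame(rows)

    @property
    def electrode_ids(self) -> tuple[int, ...]:
        return tuple(sorted(self._contact_index))

    def has_electrode(self, electrode_id: int) -> bool:
        return int(electrode_id) in self._contact_index

    def depth_of(self, electrode_id: int) -> float:
        return self._contact_index[int(electrode_id)][2]

    def region_of(self, electrode_id: int) -> str:
        return self._contact_index[int(electrode_id)][3]

    def shank_of(self, electrode_id: int) -> int:
        return self._contact_index[int(electrode_id)][0]

    def row_of(self, electrode_id: int) -> int:
        return self._contact_index[int(electrode_id)][1]

    def region_electrode_counts(self) -> dict[str, int]:
        """Number of contacts per region (default geometry: 8/12/6/6)."""
        counts = {r: 0 for r in REGIONS}
        for _, (_, _, _, reg) in self._contact_index.items():
            counts[reg] += 1
        return counts

    def electrodes_in_region(self, region: str) -> tuple[int, ...]:
        return tuple(
            eid for eid, (_, _, _, reg) in sorted(self._contact_index.items())
            if reg == region
        )

    def to_dict(self) -> dict:
        return {
            "n_shanks": self.n_shanks,
            "contacts_per_shank": self.contacts_per_shank,
            "pitch_um": self.pitch_um,
            "top_row_depth_um": self.top_row_depth_um,
            "region_boundaries_um": list(self.region_boundaries_um),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ArrayGeometry":
        return cls(
            n_shanks=int(d["n_shanks"]),
            contacts_per_shank=int(d["contacts_per_shank"]),
            pitch_um=float(d["pitch_um"]),
            top_row_depth_um=float(d["top_row_depth_um"]),
            region_boundaries_um=tuple(float(x) for x in d["region_boundaries_um"]),
        )


def assign_region(depth_um: float, geometry: ArrayGeometry) -> str:
    """Region of a recording site at ``depth_um`` below the dorsal surface.

    Piecewise-constant and total: depths <= b1 map to sDH, (b1, b2] to dDH,
    (b2, b3] to IG and > b3 to VH, with (b1, b2, b3) the geometry's
    boundaries (default 450/1050/1350 um).
    """
    depth = float(depth_um)
    if depth < 0:
        raise TrialDepthError(f"depth must be non-negative, got {depth}")
    b1, b2, b3 = geometry.region_boundaries_um
    if depth <= b1:
        return "sDH"
    if depth <= b2:
        return "dDH"
    if depth <= b3:
        return "IG"
    return "VH"


class TrialDepthError(ValueError):
    """Raised for physically impossible (negative) depths."""


def default_geometry() -> ArrayGeometry:
    """The 2-shank, 16-contact, 100-um-pitch array used throughout."""
    return ArrayGeometry()
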