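"""Build the 16-entry plan library: bladder variants, adapted CTVs, PTVs, doses.

A library of bladder contours is generated from the full simulation bladder
by moving its posterior wall (anterior–posterior axis) and superior wall
(superior–inferior axis) in 1 cm steps, from 1 cm expansion to 2 cm
contraction on each axis — 4 × 4 = 16 variants including the original.

The wall operators are directional Booleans: contraction of a wall by
``d`` is the intersection of the mask with its own copy translated ``d``
toward that wall's interior; expansion is the union with a copy translated
``d`` outward. On a convex mask only the named wall moves — the opposite
wall is untouched, which a generic morphological erosion would not give.

Each variant yields a bladder-adapted CTV (envelope minus bladder variant),
a PTV (isotropic margin via Euclidean distance transform), and a reference
dose from the surrogate conformal engine.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING

import numpy as np
from scipy import ndimage

from .grid import Structure, StructureSet, VoxelGrid, translate_mask

if TYPE_CHECKING:  # pragma: no cover
    from .dose_engine import DoseGrid, DoseModelParams, Prescription

__all__ = [
    "ShiftSpec",
    "ShiftGrid",
    "MarginSpec",
    "LibraryEntry",
    "PlanLibrary",
    "shift_bladder_wall",
    "build_bladder_library",
    "derive_ctv",
    "expand_margin",
    "build_plan_library",
]


@dataclass(frozen=True, order=True)
class ShiftSpec:
    """Directional wall shift in cm.

    ``ap_cm`` moves the posterior wall: positive = anteriorly (contraction),
    negative = posteriorly (expansion). ``si_cm`` moves the superior wall:
    positive = inferiorly (contraction), negative = superiorly (expansion).
    ``(0, 0)`` is the unmodified original.
    """

    ap_cm: float = 0.0
    si_cm: float = 0.0

    @property
    def is_identity(self) -> bool:
        return self.ap_cm == 0.0 and self.si_cm == 0.0

    def key(self) -> str:
        def fmt(v: float) -> str:
            return f"{v:+g}" if v else "0"

        return f"ap{fmt(self.ap_cm)}_si{fmt(self.si_cm)}"


@dataclass(frozen=True)
class ShiftGrid:
    """Cartesian grid of wall shifts; default 4 × 4 = 16 including (0, 0)."""

    ap_values_cm: tuple[float, ...] = (-1.0, 0.0, 1.0, 2.0)
    si_values_cm: tuple[float, ...] = (-1.0, 0.0, 1.0, 2.0)
    step_cm: float = 1.0

    def __post_init__(self) -> None:
        if 0.0 not in self.ap_values_cm or 0.0 not in self.si_values_cm:
            raise ValueError("shift grid must include the (0, 0) original")

    def __len__(self) -> int:
        return len(self.ap_values_cm) * len(self.si_values_cm)

    def specs(self) -> list[ShiftSpec]:
        return [
            ShiftSpec(ap, si)
            for ap in self.ap_values_cm
            for si in self.si_values_cm
        ]


@dataclass(frozen=True)
class MarginSpec:
    """Isotropic CTV→PTV margin in mm (default 6)."""

    margin_mm: float = 6.0

    def __post_init__(self) -> None:
        if self.margin_mm < 0:
            raise ValueError("margin must be nonnegative")


@dataclass
class LibraryEntry:
    shift: ShiftSpec
    bladder: Structure
    ctv: Structure
    ptv: Structure
    dose: "DoseGrid | None" = None


@dataclass
class PlanLibrary:
    """Map from wall shift to pre-built reference plan."""

    entries: dict[ShiftSpec, LibraryEntry]
    prescription: "Prescription"
    margin: MarginSpec
    grid: VoxelGrid

    def __post_init__(self) -> None:
        if ShiftSpec(0.0, 0.0) not in self.entries:
            raise ValueError("plan library must contain the (0, 0) original entry")

    def __len__(self) -> int:
        return len(self.entries)

    def __getitem__(self, shift: ShiftSpec) -> LibraryEntry:
        return self.entries[shift]

    @property
    def original(self) -> LibraryEntry:
        return self.entries[ShiftSpec(0.0, 0.0)]

    def most_contracted(self) -> LibraryEntry:
        shift = max(self.entries, key=lambda s: (s.ap_cm, s.si_cm))
        return self.entries[shift]


def _round_voxels(distance_cm: float, spacing_mm: float) -> int:
    return int(round(distance_cm * 10.0 / spacing_mm))


def shift_bladder_wall(
    bladder_mask: np.ndarray, shift: ShiftSpec, grid: VoxelGrid
) -> np.ndarray:
    """Move the posterior and/or superior wall of a mask by directional Booleans.

    AP operator first, then SI. Shift distances are rounded to the nearest
    integer voxel count (exact for the default 1 cm steps on 2 mm spacing).
    A shift consuming the whole mask extent yields an empty mask.
    """
    out = bladder_mask
    d_ap = _round_voxels(shift.ap_cm, grid.spacing_mm[1])
    if d_ap > 0:  # posterior wall anteriorly: intersect with anterior copy
        out = out & translate_mask(out, (0, -d_ap, 0))
    elif d_ap < 0:  # posterior wall posteriorly: union with posterior copy
        out = out | translate_mask(out, (0, -d_ap, 0))
    d_si = _round_voxels(shift.si_cm, grid.spacing_mm[2])
    if d_si > 0:  # superior wall inferiorly: intersect with inferior copy
        out = out & translate_mask(out, (0, 0, -d_si))
    elif d_si < 0:  # superior wall superiorly: union with superior copy
        out = out | translate_mask(out, (0, 0, -d_si))
    return out


def build_bladder_library(
    bladder: Structure, shift_grid: ShiftGrid | None = None
) -> list[tuple[ShiftSpec, np.ndarray]]:
    """One bladder variant per shift-grid element; (0, 0) equals the input."""
    if bladder.is_empty:
        raise ValueError("cannot build a bladder library from an empty bladder")
    shift_grid = shift_grid or ShiftGrid()
    return [
        (spec, shift_bladder_wall(bladder.mask, spec, bladder.grid))
        for spec in shift_grid.specs()
    ]


def derive_ctv(ctv_envelope: Structure, bladder_variant: np.ndarray) -> Structure:
    """Bladder-adapted CTV: envelope minus the bladder variant."""
    if bladder_variant.shape != ctv_envelope.grid.shape:
        raise ValueError("bladder variant is not on the envelope's grid")
    return Structure("ctv", ctv_envelope.mask & ~bladder_variant, ctv_envelope.grid)


def expand_margin(ctv: Structure, margin: MarginSpec | None = None) -> Structure:
    """Isotropic geometric margin via Euclidean distance transform.

    A voxel belongs to the PTV iff its center lies within ``margin_mm`` of
    some CTV voxel center (boundary inclusive), so PTV ⊇ CTV always and an
    empty CTV gives an empty PTV.
    """
    margin = margin or MarginSpec()
    if ctv.is_empty or margin.margin_mm == 0.0:
        return Structure("ptv", ctv.mask.copy(), ctv.grid)
    dist = ndimage.distance_transform_edt(~ctv.mask, sampling=ctv.grid.spacing_mm)
    return Structure("ptv", dist <= margin.margin_mm, ctv.grid)


def build_plan_library(
    sim: StructureSet,
    shift_grid: ShiftGrid | None = None,
    margin: MarginSpec | None = None,
    prescription: "Prescription | None" = None,
    dose_params: "DoseModelParams | None" = None,
) -> PlanLibrary:
    """Full library build: bladder variant → CTV → PTV → reference dose."""
    from .dose_engine import DoseModelParams, Prescription, conformal_dose

    shift_grid = shift_grid or ShiftGrid()
    margin = margin or MarginSpec()
    prescription = prescription or Prescription()
    dose_params = dose_params or DoseModelParams()

    envelope = sim["ctv_envelope"]
    entries: dict[ShiftSpec, LibraryEntry] = {}
    for spec, variant in build_bladder_library(sim["bladder"], shift_grid):
        ctv = derive_ctv(envelope, variant)
        ptv = expand_margin(ctv, margin)
        dose = conformal_dose(ptv, prescription, dose_params)
        entries[spec] = LibraryEntry(
            shift=spec,
            bladder=Structure(f"bladder_{spec.key()}", variant, sim.grid),
            ctv=ctv,
            ptv=ptv,
            dose=dose,
        )
    return PlanLibrary(entries, prescription, margin, sim.grid)
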