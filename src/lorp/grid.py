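"""Voxel-grid data model shared by every stage of the pipeline.

Axis convention (fixed throughout the package):

* ``x`` — patient right → left
* ``y`` — anterior → posterior (larger ``y`` is more posterior)
* ``z`` — inferior → superior (larger ``z`` is more superior)

Masks are boolean arrays indexed ``[ix, iy, iz]``; the world coordinate of
voxel ``(i, j, k)`` is ``origin_mm + (i, j, k) * spacing_mm`` (voxel centers).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping

import numpy as np

__all__ = [
    "VoxelGrid",
    "Structure",
    "StructureSet",
    "REQUIRED_STRUCTURES",
    "make_grid",
    "translate_mask",
    "volume_cm3",
]

#: Structures every synthetic pelvic anatomy must provide.
REQUIRED_STRUCTURES = (
    "bladder",
    "ctv_envelope",
    "intestine",
    "colon",
    "femur_l",
    "femur_r",
    "perineum",
)


@dataclass(frozen=True)
class VoxelGrid:
    """Regular 3D lattice: shape, spacing and origin in mm.

    Two grids are *compatible* iff shape, spacing and origin are all equal;
    every mask/dose operation in the package requires compatible grids.
    """

    shape: tuple[int, int, int]
    spacing_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        shape = tuple(int(n) for n in self.shape)
        spacing = tuple(float(s) for s in self.spacing_mm)
        origin = tuple(float(o) for o in self.origin_mm)
        if len(shape) != 3 or len(spacing) != 3 or len(origin) != 3:
            raise ValueError("grid shape, spacing and origin must be length-3")
        if any(n <= 0 for n in shape):
            raise ValueError(f"grid shape must be positive, got {shape}")
        if any(s <= 0 for s in spacing):
            raise ValueError(f"grid spacing must be strictly positive, got {spacing}")
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "spacing_mm", spacing)
        object.__setattr__(self, "origin_mm", origin)

    @property
    def voxel_volume_cm3(self) -> float:
        sx, sy, sz = self.spacing_mm
        return sx * sy * sz / 1000.0

    def axis_coords_mm(self, axis: int) -> np.ndarray:
        """World coordinates of voxel centers along one axis."""
        return self.origin_mm[axis] + np.arange(self.shape[axis]) * self.spacing_mm[axis]

    def world_coordinate(self, index: tuple[int, int, int]) -> tuple[float, float, float]:
        return tuple(
            self.origin_mm[a] + index[a] * self.spacing_mm[a] for a in range(3)
        )

    def compatible(self, other: "VoxelGrid") -> bool:
        return (
            self.shape == other.shape
            and self.spacing_mm == other.spacing_mm
            and self.origin_mm == other.origin_mm
        )


def make_grid(
    shape: tuple[int, int, int],
    spacing_mm: tuple[float, float, float],
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0),
) -> VoxelGrid:
    """Construct a :class:`VoxelGrid`, validating shape and spacing."""
    return VoxelGrid(tuple(shape), tuple(spacing_mm), tuple(origin_mm))


@dataclass
class Structure:
    """A named binary mask living on a :class:`VoxelGrid`."""

    name: str
    mask: np.ndarray
    grid: VoxelGrid

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.grid.shape:
            raise ValueError(
                f"structure '{self.name}': mask shape {self.mask.shape} "
                f"!= grid shape {self.grid.shape}"
            )

    @property
    def volume_cm3(self) -> float:
        return volume_cm3(self)

    @property
    def is_empty(self) -> bool:
        return not self.mask.any()

    def translated(self, shift_vox: tuple[int, int, int]) -> "Structure":
        return Structure(self.name, translate_mask(self.mask, shift_vox), self.grid)


def volume_cm3(structure: Structure) -> float:
    """Volume of a structure: set-voxel count times voxel volume, in cm³."""
    return int(structure.mask.sum()) * structure.grid.voxel_volume_cm3


def translate_mask(mask: np.ndarray, shift_vox: tuple[int, int, int]) -> np.ndarray:
    """Integer-voxel translation of a binary mask with zero fill.

    ``out[i] = mask[i - shift]`` — a positive shift moves content toward
    larger indices (e.g. ``(0, +d, 0)`` moves a mask posteriorly by ``d``
    voxels under the package axis convention).
    """
    out = np.zeros_like(mask)
    src: list[slice] = []
    dst: list[slice] = []
    for axis, d in enumerate(shift_vox):
        n = mask.shape[axis]
        d = int(d)
        if abs(d) >= n:
            return out
        if d >= 0:
            src.append(slice(0, n - d))
            dst.append(slice(d, n))
        else:
            src.append(slice(-d, n))
            dst.append(slice(0, n + d))
    out[tuple(dst)] = mask[tuple(src)]
    return out


@dataclass
class StructureSet:
    """Named binary masks sharing one grid.

    The seven :data:`REQUIRED_STRUCTURES` must be present; additional
    structures (e.g. a derived ``ctv``/``ptv``) are allowed.
    """

    grid: VoxelGrid
    structures: dict[str, Structure] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in REQUIRED_STRUCTURES:
            if name not in self.structures:
                raise ValueError(f"structure set is missing required '{name}'")
        for name, s in self.structures.items():
            if not s.grid.compatible(self.grid):
                raise ValueError(f"structure '{name}' is on an incompatible grid")
        bladder = self.structures["bladder"].mask
        for femur in ("femur_l", "femur_r"):
            if (bladder & self.structures[femur].mask).any():
                raise ValueError(f"bladder overlaps {femur}")
        if self.structures["ctv_envelope"].is_empty:
            raise ValueError("ctv_envelope is empty")

    def __getitem__(self, name: str) -> Structure:
        return self.structures[name]

    def __contains__(self, name: str) -> bool:
        return name in self.structures

    def __iter__(self) -> Iterator[str]:
        return iter(self.structures)

    def names(self) -> list[str]:
        return list(self.structures)

    def translated(self, shift_vox: tuple[int, int, int]) -> "StructureSet":
        return StructureSet(
            self.grid,
            {n: s.translated(shift_vox) for n, s in self.structures.items()},
        )

    @classmethod
    def from_masks(cls, grid: VoxelGrid, masks: Mapping[str, np.ndarray]) -> "StructureSet":
        return cls(grid, {n: Structure(n, m, grid) for n, m in masks.items()})
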