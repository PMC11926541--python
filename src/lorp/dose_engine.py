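"""Surrogate conformal dose engine, virtual couch shift, and strategy analogs.

The engine is an explicit stand-in for a treatment planning system: the
prescription dose is delivered uniformly over the PTV plus a small plateau
extension, then falls off linearly over a penumbra of fixed width. With
``s(x)`` the signed Euclidean distance to the PTV surface (negative
inside), plateau extension ``p`` and penumbra width ``w``::

    D(x) = Rx                         for s(x) <= p
    D(x) = Rx * (1 - (s(x) - p) / w)  for p < s(x) <= p + w
    D(x) = 0                          otherwise

No beam geometry is modeled; the plan-library logic under study is
dose-model-agnostic and every property claimed here is stated for this
surrogate. Dose never exceeds the prescription anywhere.

Three adaptation strategies are provided:

* ``lorp_atp`` — register, select a plan from the library, virtual couch
  shift of the selected reference dose;
* ``catp`` — virtual couch shift of the original (0, 0) reference dose,
  no reselection (conventional adapt-to-position);
* ``ats`` — re-plan from scratch on the daily anatomy (adapt-to-shape):
  conformal dose on the daily true PTV.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional

import numpy as np
from scipy import ndimage

from .anatomy import FractionScenario
from .grid import Structure, StructureSet, VoxelGrid
from .library_builder import MarginSpec, PlanLibrary, derive_ctv, expand_margin

__all__ = [
    "Prescription",
    "DoseModelParams",
    "DoseGrid",
    "conformal_dose",
    "apply_couch_shift",
    "daily_target",
    "deliver_strategy",
    "STRATEGIES",
]

STRATEGIES = ("lorp_atp", "catp", "ats")


@dataclass(frozen=True)
class Prescription:
    """Prescribed dose: 25 Gy in 5 fractions by default."""

    total_dose_gy: float = 25.0
    n_fractions: int = 5

    def __post_init__(self) -> None:
        if self.total_dose_gy <= 0 or self.n_fractions <= 0:
            raise ValueError("prescription must be positive")

    @property
    def dose_per_fraction_gy(self) -> float:
        return self.total_dose_gy / self.n_fractions


@dataclass(frozen=True)
class DoseModelParams:
    """Surrogate engine parameters: plateau extension and penumbra width, mm."""

    plateau_extension_mm: float = 1.0
    penumbra_width_mm: float = 8.0

    def __post_init__(self) -> None:
        if self.plateau_extension_mm < 0:
            raise ValueError("plateau extension must be nonnegative")
        if self.penumbra_width_mm <= 0:
            raise ValueError("penumbra width must be positive")


@dataclass
class DoseGrid:
    """Scalar dose in Gy on a voxel grid."""

    values: np.ndarray
    grid: VoxelGrid

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValueError("dose array shape does not match grid")
        if not np.isfinite(self.values).all() or (self.values < 0).any():
            raise ValueError("dose must be finite and nonnegative")


def _signed_distance_mm(mask: np.ndarray, grid: VoxelGrid) -> np.ndarray:
    """Signed Euclidean distance to the mask surface; negative inside."""
    spacing = grid.spacing_mm
    outside = ndimage.distance_transform_edt(~mask, sampling=spacing)
    inside = ndimage.distance_transform_edt(mask, sampling=spacing)
    return outside - inside


def conformal_dose(
    ptv: Structure,
    prescription: Prescription | None = None,
    params: DoseModelParams | None = None,
) -> DoseGrid:
    """Plateau-plus-linear-penumbra dose conformal to the PTV."""
    prescription = prescription or Prescription()
    params = params or DoseModelParams()
    if ptv.is_empty:
        raise ValueError("cannot plan on an empty PTV")
    rx = prescription.total_dose_gy
    p, w = params.plateau_extension_mm, params.penumbra_width_mm
    s = _signed_distance_mm(ptv.mask, ptv.grid)
    dose = np.where(
        s <= p, rx, np.where(s <= p + w, rx * (1.0 - (s - p) / w), 0.0)
    )
    return DoseGrid(np.clip(dose, 0.0, rx), ptv.grid)


def apply_couch_shift(
    dose: DoseGrid, translation_mm: tuple[float, float, float]
) -> DoseGrid:
    """Virtual couch shift: resample the dose at ``x − translation``.

    Trilinear interpolation with zero fill outside the field; integer-voxel
    translations reduce to exact array shifts.
    """
    shift_vox = [translation_mm[a] / dose.grid.spacing_mm[a] for a in range(3)]
    if all(float(s).is_integer() for s in shift_vox):
        out = np.zeros_like(dose.values)
        src, dst = [], []
        for axis, s in enumerate(shift_vox):
            n = dose.values.shape[axis]
            d = int(s)
            if abs(d) >= n:
                return DoseGrid(out, dose.grid)
            if d >= 0:
                src.append(slice(0, n - d))
                dst.append(slice(d, n))
            else:
                src.append(slice(-d, n))
                dst.append(slice(0, n + d))
        out[tuple(dst)] = dose.values[tuple(src)]
        return DoseGrid(out, dose.grid)
    shifted = ndimage.shift(
        dose.values, shift_vox, order=1, mode="constant", cval=0.0, prefilter=False
    )
    return DoseGrid(np.clip(shifted, 0.0, None), dose.grid)


def daily_target(daily: StructureSet, margin: MarginSpec) -> tuple[Structure, Structure]:
    """Ground-truth daily CTV and PTV: envelope minus daily bladder, margined."""
    ctv = derive_ctv(daily["ctv_envelope"], daily["bladder"].mask)
    ptv = expand_margin(ctv, margin)
    return ctv, ptv


def deliver_strategy(
    strategy: Literal["lorp_atp", "catp", "ats"],
    library: PlanLibrary,
    scenario: FractionScenario,
    sim: StructureSet,
    params: DoseModelParams | None = None,
) -> tuple[DoseGrid, Optional["SelectionResult"]]:
    """Deliver one fraction under an adaptation strategy.

    Returns the delivered dose on the daily frame and, for ``lorp_atp``,
    the plan-selection result.
    """
    from .plan_selection import SelectionResult, register_translation, select_plan

    params = params or DoseModelParams()
    daily = scenario.daily

    if strategy == "ats":
        _, ptv = daily_target(daily, library.margin)
        return conformal_dose(ptv, library.prescription, params), None

    translation = register_translation(sim, daily)
    if strategy == "catp":
        dose = apply_couch_shift(library.original.dose, translation)
        return dose, None
    if strategy == "lorp_atp":
        result = select_plan(library, daily["bladder"], translation)
        dose = apply_couch_shift(library[result.shift].dose, translation)
        return dose, result
    raise ValueError(f"unknown strategy {strategy!r}")
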