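"""Translation-only registration and the daily plan-of-the-day selection rule.

Registration uses the femoral heads as a bony surrogate: the centroid of
the femur union is aligned from simulation to daily, then refined by a
local integer-voxel search maximizing femur-mask overlap.

Selection follows the library rule: map each library bladder into the
daily frame and pick the *largest* one whose posterior and superior walls
do not exceed the actual daily bladder's walls — the least-contracted
admissible entry, so the CTV is as small as OAR sparing allows while still
covering the target. If no entry is admissible the most-contracted entry
is returned as a fallback and the fraction is flagged out-of-library
(such fractions may fail the dose criteria; the flag preserves that
observable). Anterior and inferior walls are not constrained.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Literal

import numpy as np

from .grid import Structure, StructureSet
from .library_builder import PlanLibrary, ShiftSpec

__all__ = ["SelectionResult", "wall_extent", "register_translation", "select_plan"]

_WALL_AXIS = {"posterior": 1, "superior": 2}
_EPS_MM = 1e-6


@dataclass(frozen=True)
class SelectionResult:
    """Outcome of the daily selection: chosen shift, admissibility, wall gaps.

    ``wall_gaps_mm`` is (daily wall − selected library wall) per constrained
    wall, in the daily frame; both are ≥ 0 for an admissible selection.
    """

    shift: ShiftSpec
    admissible: bool
    out_of_library: bool
    wall_gaps_mm: tuple[float, float]


def wall_extent(
    mask: np.ndarray, grid, wall: Literal["posterior", "superior"]
) -> float:
    """World coordinate (mm) of a mask's posterior (max-y) or superior (max-z) wall."""
    if wall not in _WALL_AXIS:
        raise ValueError(f"unknown wall {wall!r}")
    axis = _WALL_AXIS[wall]
    other = tuple(a for a in range(3) if a != axis)
    profile = mask.any(axis=other)
    idx = np.nonzero(profile)[0]
    if idx.size == 0:
        raise ValueError("wall extent of an empty mask is undefined")
    return grid.origin_mm[axis] + idx.max() * grid.spacing_mm[axis]


def register_translation(
    sim: StructureSet, daily: StructureSet, search_vox: int = 2
) -> tuple[float, float, float]:
    """Recover the simulation→daily translation from the femoral heads.

    Centroid alignment of the femur union, rounded to voxels, refined over
    a ±``search_vox`` integer-voxel neighborhood by maximizing overlap with
    the daily femur masks. Exact for integer-voxel ground-truth offsets.
    """
    for ss, label in ((sim, "simulation"), (daily, "daily")):
        for name in ("femur_l", "femur_r"):
            if name not in ss or ss[name].is_empty:
                raise ValueError(f"{label} anatomy lacks a nonempty {name}")

    grid = sim.grid
    if not grid.compatible(daily.grid):
        raise ValueError("simulation and daily grids are incompatible")

    sim_femurs = sim["femur_l"].mask | sim["femur_r"].mask
    daily_femurs = daily["femur_l"].mask | daily["femur_r"].mask

    def centroid(mask: np.ndarray) -> np.ndarray:
        return np.array(np.nonzero(mask), dtype=float).mean(axis=1)

    base = np.round(centroid(daily_femurs) - centroid(sim_femurs)).astype(int)

    from .grid import translate_mask

    best, best_overlap = base, -1
    for offset in itertools.product(range(-search_vox, search_vox + 1), repeat=3):
        cand = base + np.array(offset)
        overlap = int((translate_mask(sim_femurs, tuple(cand)) & daily_femurs).sum())
        if overlap > best_overlap:
            best, best_overlap = cand, overlap
    return tuple(best[a] * grid.spacing_mm[a] for a in range(3))


def select_plan(
    library: PlanLibrary,
    daily_bladder: Structure,
    translation_mm: tuple[float, float, float] = (0.0, 0.0, 0.0),
) -> SelectionResult:
    """Pick the largest library bladder that stays within the daily walls.

    An entry is admissible iff, after mapping into the daily frame by
    ``translation_mm``, its posterior extent ≤ the daily bladder's posterior
    extent and its superior extent ≤ the daily superior extent. Among
    admissible entries the largest bladder volume wins; ties break toward
    the smaller total shift magnitude, then the smaller AP shift. With no
    admissible entry the most-contracted entry is returned, flagged
    out-of-library.
    """
    if len(library) == 0:
        raise ValueError("empty plan library")
    if daily_bladder.is_empty:
        raise ValueError("daily bladder is empty")
    grid = daily_bladder.grid

    daily_post = wall_extent(daily_bladder.mask, grid, "posterior")
    daily_sup = wall_extent(daily_bladder.mask, grid, "superior")

    def gaps(entry) -> tuple[float, float]:
        # library walls mapped into the daily frame by the registration offset
        post = wall_extent(entry.bladder.mask, grid, "posterior") + translation_mm[1]
        sup = wall_extent(entry.bladder.mask, grid, "superior") + translation_mm[2]
        return (daily_post - post, daily_sup - sup)

    candidates = []
    for spec, entry in library.entries.items():
        if entry.bladder.is_empty:
            # a fully consumed variant never exceeds any wall; volume 0
            candidates.append((spec, entry, (np.inf, np.inf), 0.0))
            continue
        g = gaps(entry)
        candidates.append((spec, entry, g, entry.bladder.volume_cm3))

    admissible = [
        c for c in candidates if c[2][0] >= -_EPS_MM and c[2][1] >= -_EPS_MM
    ]
    if admissible:
        spec, entry, g, _ = min(
            admissible,
            key=lambda c: (-c[3], abs(c[0].ap_cm) + abs(c[0].si_cm), c[0].ap_cm),
        )
        finite = tuple(x if np.isfinite(x) else 0.0 for x in g)
        return SelectionResult(spec, True, False, finite)

    fallback = library.most_contracted()
    g = gaps(fallback) if not fallback.bladder.is_empty else (0.0, 0.0)
    return SelectionResult(fallback.shift, False, True, tuple(g))
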