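"""Synthetic pelvic anatomy and inter-fraction bladder-filling variation.

The generator rasterizes analytic solids on a voxel grid to stand in for a
delineated simulation scan of a rectal-cancer patient:

* an ellipsoidal full **bladder** anterior to the target region;
* a **ctv_envelope** — the clinical target volume *before* bladder
  accommodation: an elliptical cylinder hugging the bladder's posterior
  wall, whose anterior boundary reaches ~1.8 cm into the full bladder
  (the anterior margin that absorbs bladder-filling variation);
* tubular **intestine** and **colon** superior-anterior to the target;
* paired **femoral heads** lateral; a **perineum** slab inferior.

Daily (per-fraction) anatomy is derived from the simulation anatomy by
retracting the bladder's posterior and superior walls (the dominant
inter-fraction change: patients rarely reproduce the full simulation
bladder), translating the whole anatomy by a couch setup offset, and —
rarely — a "gas event" that pushes the anterior part of the target
envelope further anteriorly, the mechanism that can carry a fraction
beyond the reach of any plan library.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .grid import Structure, StructureSet, VoxelGrid, make_grid, translate_mask

__all__ = [
    "AnatomyParams",
    "DistSpec",
    "VariationModel",
    "FractionScenario",
    "generate_simulation_anatomy",
    "sample_fraction_scenario",
]


@dataclass(frozen=True)
class AnatomyParams:
    """Geometry of the synthetic simulation anatomy (all lengths in mm).

    Defaults give a pelvic field of view of 192 mm per axis at 2 mm
    isotropic spacing. Organ centers are jittered per patient by
    ``center_jitter_mm`` (normal sd, applied with the generation seed) so a
    cohort is not ten copies of one phantom.
    """

    grid_shape: tuple[int, int, int] = (96, 96, 96)
    spacing_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)
    origin_mm: tuple[float, float, float] = (-96.0, -96.0, -96.0)

    bladder_center: tuple[float, float, float] = (0.0, -20.0, 10.0)
    bladder_semiaxes: tuple[float, float, float] = (30.0, 32.0, 30.0)

    # Elliptical cylinder along z; anterior bound = envelope_center_y - envelope_semiaxes[1]
    envelope_center_y: float = 28.0
    envelope_semiaxes: tuple[float, float] = (42.0, 34.0)
    envelope_z_range: tuple[float, float] = (-40.0, 40.0)

    intestine_center: tuple[float, float, float] = (0.0, -45.0, 55.0)
    intestine_radius: float = 11.0
    intestine_half_length: float = 40.0

    colon_center: tuple[float, float, float] = (0.0, -5.0, 62.0)
    colon_radius: float = 10.0
    colon_half_length: float = 45.0

    femur_center: tuple[float, float, float] = (62.0, 0.0, -5.0)  # |x| used for both sides
    femur_radius: float = 20.0

    perineum_center: tuple[float, float, float] = (0.0, 15.0, -70.0)
    perineum_semiaxes: tuple[float, float, float] = (35.0, 30.0, 16.0)

    center_jitter_mm: float = 2.0

    def grid(self) -> VoxelGrid:
        return make_grid(self.grid_shape, self.spacing_mm, self.origin_mm)


@dataclass(frozen=True)
class DistSpec:
    """Truncated-normal specification: ``clip(N(mean, sd), lower, upper)``."""

    mean: float
    sd: float
    lower: float
    upper: float

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be nonnegative")
        if self.lower > self.upper:
            raise ValueError("lower bound exceeds upper bound")

    def sample(self, rng: np.random.Generator) -> float:
        return float(np.clip(rng.normal(self.mean, self.sd), self.lower, self.upper))


def _point_mass(v: float) -> DistSpec:
    return DistSpec(v, 0.0, v, v)


@dataclass(frozen=True)
class VariationModel:
    """Inter-fraction variation of the daily anatomy.

    Wall retractions are in cm, positive = wall pulled inward (posterior
    wall anteriorly / superior wall inferiorly); bounds keep them within
    [−1, 3] cm. The default retraction distributions are calibrated so the
    daily/simulation bladder volume ratio has median near 0.5 — two
    sequential ≈12 mm chord cuts of the default ellipsoidal bladder each
    retain ≈72 % of the volume, 0.72² ≈ 0.52.
    """

    posterior_wall_retraction_cm: DistSpec = DistSpec(1.2, 0.6, -1.0, 3.0)
    superior_wall_retraction_cm: DistSpec = DistSpec(1.2, 0.6, -1.0, 3.0)
    couch_translation_mm: tuple[DistSpec, DistSpec, DistSpec] = (
        DistSpec(0.0, 3.0, -10.0, 10.0),
        DistSpec(0.0, 3.0, -10.0, 10.0),
        DistSpec(0.0, 3.0, -10.0, 10.0),
    )
    gas_event_prob: float = 0.08
    gas_displacement_mm: float = 10.0

    def __post_init__(self) -> None:
        for spec in (self.posterior_wall_retraction_cm, self.superior_wall_retraction_cm):
            if spec.lower < -1.0 or spec.upper > 3.0:
                raise ValueError("wall retraction bounds must stay within [-1, 3] cm")
        if not 0.0 <= self.gas_event_prob <= 1.0:
            raise ValueError("gas_event_prob must be a probability")

    @classmethod
    def degenerate(cls) -> "VariationModel":
        """Point-mass-at-zero model: the daily anatomy equals the simulation."""
        zero = _point_mass(0.0)
        return cls(
            posterior_wall_retraction_cm=zero,
            superior_wall_retraction_cm=zero,
            couch_translation_mm=(zero, zero, zero),
            gas_event_prob=0.0,
        )


@dataclass
class FractionScenario:
    """One fraction's ground truth: daily anatomy plus how it was produced."""

    daily: StructureSet
    true_translation_mm: tuple[float, float, float]
    applied_retractions_cm: tuple[float, float]
    gas_event: bool
    retraction_clamped: bool = False


# ---------------------------------------------------------------------------
# rasterization helpers


def _ellipsoid(grid: VoxelGrid, center, semiaxes) -> np.ndarray:
    x = grid.axis_coords_mm(0)[:, None, None]
    y = grid.axis_coords_mm(1)[None, :, None]
    z = grid.axis_coords_mm(2)[None, None, :]
    return (
        ((x - center[0]) / semiaxes[0]) ** 2
        + ((y - center[1]) / semiaxes[1]) ** 2
        + ((z - center[2]) / semiaxes[2]) ** 2
    ) <= 1.0


def _tube_x(grid: VoxelGrid, center, radius: float, half_length: float) -> np.ndarray:
    """Cylinder with axis along x (left-right), capped at ±half_length."""
    x = grid.axis_coords_mm(0)[:, None, None]
    y = grid.axis_coords_mm(1)[None, :, None]
    z = grid.axis_coords_mm(2)[None, None, :]
    radial = (y - center[1]) ** 2 + (z - center[2]) ** 2 <= radius**2
    return radial & (np.abs(x - center[0]) <= half_length)


def _elliptic_cylinder_z(
    grid: VoxelGrid, center_y: float, semiaxes_xy, z_range
) -> np.ndarray:
    x = grid.axis_coords_mm(0)[:, None, None]
    y = grid.axis_coords_mm(1)[None, :, None]
    z = grid.axis_coords_mm(2)[None, None, :]
    inside = ((x / semiaxes_xy[0]) ** 2 + ((y - center_y) / semiaxes_xy[1]) ** 2) <= 1.0
    return inside & (z >= z_range[0]) & (z <= z_range[1])


def _jitter(center, rng: np.random.Generator, sd: float):
    return tuple(c + rng.normal(0.0, sd) for c in center)


def generate_simulation_anatomy(
    params: AnatomyParams | None = None, seed: int = 0
) -> StructureSet:
    """Rasterize a synthetic simulation anatomy; deterministic in (params, seed)."""
    params = params or AnatomyParams()
    grid = params.grid()
    rng = np.random.default_rng(seed)
    sd = params.center_jitter_mm

    bladder_center = _jitter(params.bladder_center, rng, sd)
    envelope_cy = params.envelope_center_y + rng.normal(0.0, sd)
    intestine_center = _jitter(params.intestine_center, rng, sd)
    colon_center = _jitter(params.colon_center, rng, sd)
    femur_dz = rng.normal(0.0, sd)
    perineum_center = _jitter(params.perineum_center, rng, sd)

    bladder = _ellipsoid(grid, bladder_center, params.bladder_semiaxes)
    envelope = _elliptic_cylinder_z(
        grid, envelope_cy, params.envelope_semiaxes, params.envelope_z_range
    )
    intestine = _tube_x(
        grid, intestine_center, params.intestine_radius, params.intestine_half_length
    )
    colon = _tube_x(grid, colon_center, params.colon_radius, params.colon_half_length)
    fx, fy, fz = params.femur_center
    femur_l = _ellipsoid(grid, (abs(fx), fy, fz + femur_dz), (params.femur_radius,) * 3)
    femur_r = _ellipsoid(grid, (-abs(fx), fy, fz + femur_dz), (params.femur_radius,) * 3)
    perineum = _ellipsoid(grid, perineum_center, params.perineum_semiaxes)

    if not bladder.any():
        raise ValueError("anatomy parameters produced an empty bladder")
    if not envelope.any():
        raise ValueError("anatomy parameters produced an empty ctv_envelope")
    if not (bladder & envelope).any():
        raise ValueError(
            "bladder and ctv_envelope do not overlap; bladder subtraction "
            "would be trivial — adjust envelope_center_y/semiaxes"
        )

    masks = {
        "bladder": bladder & ~(femur_l | femur_r),
        "ctv_envelope": envelope,
        "intestine": intestine,
        "colon": colon,
        "femur_l": femur_l,
        "femur_r": femur_r,
        "perineum": perineum,
    }
    return StructureSet.from_masks(grid, masks)


def _gas_displaced_envelope(
    envelope: np.ndarray, grid: VoxelGrid, displacement_mm: float
) -> np.ndarray:
    """Push the envelope's anterior third anteriorly by ``displacement_mm``.

    Models gas in the colon/rectum displacing the anterior target boundary;
    the envelope grows (union), its posterior part is unchanged.
    """
    ys = np.nonzero(envelope.any(axis=(0, 2)))[0]
    if ys.size == 0:
        return envelope
    y0, y1 = ys.min(), ys.max()
    cut = y0 + (y1 - y0 + 1) // 3
    anterior = np.zeros_like(envelope)
    anterior[:, y0 : cut + 1, :] = envelope[:, y0 : cut + 1, :]
    d_vox = int(round(displacement_mm / grid.spacing_mm[1]))
    return envelope | translate_mask(anterior, (0, -d_vox, 0))


def sample_fraction_scenario(
    sim: StructureSet,
    model: VariationModel | None = None,
    seed: int = 0,
) -> FractionScenario:
    """Sample one daily anatomy from the simulation anatomy.

    The daily bladder is the simulation bladder with its posterior and
    superior walls retracted (the same wall operators the library builder
    uses), the whole anatomy is then translated by an integer-voxel couch
    offset, and the target envelope optionally receives a gas-event
    anterior displacement. Retractions exceeding the bladder extent are
    clamped and flagged.
    """
    # local import: library_builder depends on grid only, no cycle at runtime
    from .library_builder import ShiftSpec, shift_bladder_wall

    model = model or VariationModel()
    rng = np.random.default_rng(seed)
    grid = sim.grid

    post_cm = model.posterior_wall_retraction_cm.sample(rng)
    sup_cm = model.superior_wall_retraction_cm.sample(rng)
    trans_mm = [spec.sample(rng) for spec in model.couch_translation_mm]
    gas = bool(rng.random() < model.gas_event_prob)

    # clamp retractions to the bladder extent along each axis
    bladder = sim["bladder"].mask
    clamped = False
    ys = np.nonzero(bladder.any(axis=(0, 2)))[0]
    zs = np.nonzero(bladder.any(axis=(0, 1)))[0]
    max_post_cm = (ys.max() - ys.min()) * grid.spacing_mm[1] / 10.0
    max_sup_cm = (zs.max() - zs.min()) * grid.spacing_mm[2] / 10.0
    if post_cm > max_post_cm:
        post_cm, clamped = max_post_cm, True
    if sup_cm > max_sup_cm:
        sup_cm, clamped = max_sup_cm, True

    daily_bladder = shift_bladder_wall(bladder, ShiftSpec(post_cm, sup_cm), grid)

    envelope = sim["ctv_envelope"].mask
    if gas:
        envelope = _gas_displaced_envelope(envelope, grid, model.gas_displacement_mm)

    # couch offset: stored on the simulation grid, integer voxels (no resampling)
    shift_vox = tuple(
        int(round(trans_mm[a] / grid.spacing_mm[a])) for a in range(3)
    )
    true_translation = tuple(shift_vox[a] * grid.spacing_mm[a] for a in range(3))

    masks = {name: sim[name].mask for name in sim.names()}
    masks["bladder"] = daily_bladder
    masks["ctv_envelope"] = envelope
    daily_masks = {
        name: translate_mask(mask, shift_vox) for name, mask in masks.items()
    }
    daily = StructureSet.from_masks(grid, daily_masks)

    return FractionScenario(
        daily=daily,
        true_translation_mm=true_translation,
        applied_retractions_cm=(post_cm, sup_cm),
        gas_event=gas,
        retraction_clamped=clamped,
    )
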