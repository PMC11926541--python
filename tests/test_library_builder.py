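import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial import cKDTree

import lorp
from lorp.library_builder import ShiftSpec, shift_bladder_wall

from conftest import box_mask, sphere_mask


@pytest.fixture(scope="module")
def box_on_grid(small_grid):
    # 40 x 40 x 40 mm box: 20 voxels per axis at 2 mm
    return box_mask(small_grid, (-20, -20, -20), (18, 18, 18))


def _extent_mm(mask, grid, axis, end="max"):
    idx = np.nonzero(mask.any(axis=tuple(a for a in range(3) if a != axis)))[0]
    i = idx.max() if end == "max" else idx.min()
    return grid.origin_mm[axis] + i * grid.spacing_mm[axis]


class TestShiftBladderWall:
    def test_identity_shift(self, small_grid, box_on_grid):
        out = shift_bladder_wall(box_on_grid, ShiftSpec(0, 0), small_grid)
        assert np.array_equal(out, box_on_grid)

    def test_posterior_contraction_on_box(self, small_grid, box_on_grid):
        """1 cm AP contraction removes exactly a 40x10x40 mm posterior slab."""
        out = shift_bladder_wall(box_on_grid, ShiftSpec(1, 0), small_grid)
        assert _extent_mm(out, small_grid, 1) == _extent_mm(box_on_grid, small_grid, 1) - 10
        assert _extent_mm(out, small_grid, 1, "min") == _extent_mm(
            box_on_grid, small_grid, 1, "min"
        )
        removed_vox = box_on_grid.sum() - out.sum()
        assert removed_vox * 8 == 40 * 10 * 40  # mm^3

    def test_posterior_expansion_on_box(self, small_grid):
        box = box_mask(small_grid, (-20, -20, -20), (18, 8, 18))
        out = shift_bladder_wall(box, ShiftSpec(-1, 0), small_grid)
        assert _extent_mm(out, small_grid, 1) == _extent_mm(box, small_grid, 1) + 10
        assert _extent_mm(out, small_grid, 1, "min") == _extent_mm(
            box, small_grid, 1, "min"
        )

    def test_superior_wall_moves_inferior_fixed(self, small_grid, box_on_grid):
        out = shift_bladder_wall(box_on_grid, ShiftSpec(0, 1), small_grid)
        assert _extent_mm(out, small_grid, 2) == _extent_mm(box_on_grid, small_grid, 2) - 10
        assert _extent_mm(out, small_grid, 2, "min") == _extent_mm(
            box_on_grid, small_grid, 2, "min"
        )

    def test_opposite_walls_unchanged_on_ellipsoid(self, sim_anatomy):
        """Each directional operator moves only its named wall along its axis."""
        bladder = sim_anatomy["bladder"].mask
        grid = sim_anatomy.grid
        ap_only = shift_bladder_wall(bladder, ShiftSpec(2, 0), grid)
        assert _extent_mm(ap_only, grid, 1, "min") == _extent_mm(bladder, grid, 1, "min")
        si_only = shift_bladder_wall(bladder, ShiftSpec(0, 2), grid)
        assert _extent_mm(si_only, grid, 2, "min") == _extent_mm(bladder, grid, 2, "min")

    def test_overlarge_shift_empties_mask(self, small_grid, box_on_grid):
        out = shift_bladder_wall(box_on_grid, ShiftSpec(5, 0), small_grid)
        assert not out.any()

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        lo=st.integers(2, 8),
        size=st.integers(3, 12),
        d_vox=st.integers(1, 6),
    )
    def test_contraction_on_random_boxes(self, lo, size, d_vox):
        """AP contraction by d voxels removes exactly a d-voxel posterior slab."""
        grid = lorp.make_grid((24,) * 3, (2.0,) * 3)
        mask = np.zeros(grid.shape, bool)
        mask[4:12, lo : lo + size, 6:14] = True
        out = shift_bladder_wall(mask, ShiftSpec(d_vox * 0.2, 0), grid)  # 2 mm voxels
        expected = np.zeros_like(mask)
        if size > d_vox:
            expected[4:12, lo : lo + size - d_vox, 6:14] = True
        assert np.array_equal(out, expected)


class TestBladderLibrary:
    def test_sixteen_entries_with_original(self, sim_anatomy):
        lib = lorp.build_bladder_library(sim_anatomy["bladder"])
        assert len(lib) == 16
        originals = [m for spec, m in lib if spec.is_identity]
        assert len(originals) == 1
        assert np.array_equal(originals[0], sim_anatomy["bladder"].mask)

    def test_nesting_partial_order(self, sim_anatomy):
        """Componentwise-larger contraction gives a subset bladder."""
        lib = dict(lorp.build_bladder_library(sim_anatomy["bladder"]))
        specs = list(lib)
        for a in specs:
            for b in specs:
                if a.ap_cm >= b.ap_cm and a.si_cm >= b.si_cm:
                    assert not (lib[a] & ~lib[b]).any(), (a, b)

    def test_empty_bladder_rejected(self, small_grid):
        empty = lorp.Structure("bladder", np.zeros(small_grid.shape, bool), small_grid)
        with pytest.raises(ValueError):
            lorp.build_bladder_library(empty)


class TestDeriveCtv:
    def test_disjoint_bladder_leaves_envelope(self, small_grid):
        env = lorp.Structure("env", box_mask(small_grid, (-20, 0, -20), (18, 18, 18)), small_grid)
        bladder = box_mask(small_grid, (-20, -20, -20), (18, -4, 18))
        ctv = lorp.derive_ctv(env, bladder)
        assert np.array_equal(ctv.mask, env.mask)

    def test_enclosing_bladder_empties_ctv(self, small_grid):
        env = lorp.Structure("env", box_mask(small_grid, (-10, -10, -10), (8, 8, 8)), small_grid)
        bladder = box_mask(small_grid, (-20, -20, -20), (18, 18, 18))
        assert lorp.derive_ctv(env, bladder).is_empty

    def test_volume_arithmetic(self, sim_anatomy):
        env = sim_anatomy["ctv_envelope"]
        bladder = sim_anatomy["bladder"].mask
        ctv = lorp.derive_ctv(env, bladder)
        overlap = (env.mask & bladder).sum() * env.grid.voxel_volume_cm3
        assert ctv.volume_cm3 == pytest.approx(env.volume_cm3 - overlap)


class TestExpandMargin:
    def test_zero_margin_is_identity(self, small_grid):
        ctv = lorp.Structure("ctv", sphere_mask(small_grid, (0, 0, 0), 10), small_grid)
        ptv = lorp.expand_margin(ctv, lorp.MarginSpec(0.0))
        assert np.array_equal(ptv.mask, ctv.mask)

    def test_empty_ctv_gives_empty_ptv(self, small_grid):
        ctv = lorp.Structure("ctv", np.zeros(small_grid.shape, bool), small_grid)
        assert lorp.expand_margin(ctv).is_empty

    def test_sphere_margin_matches_enlarged_sphere(self):
        """6 mm margin on a 20 mm sphere is a 26 mm sphere within one voxel."""
        grid = lorp.make_grid((40,) * 3, (2.0,) * 3, (-40.0,) * 3)
        ctv = lorp.Structure("ctv", sphere_mask(grid, (0, 0, 0), 20.0), grid)
        ptv = lorp.expand_margin(ctv, lorp.MarginSpec(6.0))
        inner = sphere_mask(grid, (0, 0, 0), 26.0 - 2.0 * np.sqrt(3))
        outer = sphere_mask(grid, (0, 0, 0), 26.0 + 2.0 * np.sqrt(3))
        assert (inner & ~ptv.mask).sum() == 0
        assert (ptv.mask & ~outer).sum() == 0

    def test_exhaustive_distance_oracle(self, small_grid):
        """PTV == set of voxel centers within 6 mm of a CTV center (KD-tree oracle)."""
        rng = np.random.default_rng(5)
        mask = np.zeros(small_grid.shape, bool)
        pts = rng.integers(6, 18, size=(30, 3))
        mask[pts[:, 0], pts[:, 1], pts[:, 2]] = True
        ctv = lorp.Structure("ctv", mask, small_grid)
        ptv = lorp.expand_margin(ctv, lorp.MarginSpec(6.0))

        coords = np.stack(
            np.meshgrid(*[small_grid.axis_coords_mm(a) for a in range(3)], indexing="ij"),
            axis=-1,
        ).reshape(-1, 3)
        tree = cKDTree(coords[mask.ravel()])
        dist, _ = tree.query(coords)
        oracle = (dist <= 6.0 + 1e-9).reshape(small_grid.shape)
        assert np.array_equal(ptv.mask, oracle)


class TestBuildPlanLibrary:
    def test_sixteen_nonempty_ptvs(self, plan_library):
        assert len(plan_library) == 16
        for entry in plan_library.entries.values():
            assert not entry.ptv.is_empty
            assert entry.dose is not None

    def test_ctv_disjoint_from_its_bladder(self, plan_library):
        for entry in plan_library.entries.values():
            assert not (entry.ctv.mask & entry.bladder.mask).any()

    def test_ctv_monotone_in_contraction(self, plan_library):
        """A more-contracted bladder frees more envelope: CTVs are nested."""
        e = plan_library.entries
        for a in e:
            for b in e:
                if a.ap_cm >= b.ap_cm and a.si_cm >= b.si_cm:
                    assert not (e[b].ctv.mask & ~e[a].ctv.mask).any()

    def test_ptv_contains_ctv(self, plan_library):
        for entry in plan_library.entries.values():
            assert not (entry.ctv.mask & ~entry.ptv.mask).any()
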