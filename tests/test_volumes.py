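import numpy as np
import pytest

from dvhpredict import (
    ContourSet,
    DoseGrid,
    VolumeGrid,
    rasterize_contours,
    resample_dose,
    subtract_masks,
)
from dvhpredict.errors import GeometryError, InvalidContourError

from conftest import make_dose, make_mask


# ---------------------------------------------------------------------------
# independent even-odd crossing-count oracle
# ---------------------------------------------------------------------------


def point_in_polygon_oracle(px, py, verts):
    """Classic ray-crossing parity test (ray toward +x)."""
    inside = False
    n = len(verts)
    for i in range(n):
        x1, y1 = verts[i]
        x2, y2 = verts[(i + 1) % n]
        if (y1 > py) != (y2 > py):
            x_cross = x1 + (py - y1) * (x2 - x1) / (y2 - y1)
            if px < x_cross:
                inside = not inside
    return inside


def rasterize_oracle(contours, grid):
    occ = np.zeros(grid.shape, dtype=bool)
    xs, ys, zs = (grid.axis_coords(k) for k in range(3))
    for z, verts in contours.polygons:
        iz = int(round((z - grid.origin[2]) / grid.spacing[2]))
        if iz < 0 or iz >= grid.shape[2] or abs(z - zs[iz]) > grid.spacing[2] / 2:
            continue
        for i, x in enumerate(xs):
            for j, y in enumerate(ys):
                if point_in_polygon_oracle(x, y, verts):
                    occ[i, j, iz] = not occ[i, j, iz]
    return occ


class TestVolumeGrid:
    def test_invariants(self):
        g = VolumeGrid(shape=(2, 3, 4), spacing=(1.0, 2.0, 0.5))
        assert g.voxel_volume == pytest.approx(1.0)
        assert g.n_voxels == 24

    @pytest.mark.parametrize("bad", [(0, 1, 1), (-1, 2, 2)])
    def test_bad_shape(self, bad):
        with pytest.raises(GeometryError):
            VolumeGrid(shape=bad, spacing=(1, 1, 1))

    def test_bad_spacing(self):
        with pytest.raises(GeometryError):
            VolumeGrid(shape=(2, 2, 2), spacing=(1.0, 0.0, 1.0))

    def test_axis_coords(self):
        g = VolumeGrid(shape=(3, 3, 3), spacing=(2.0, 2.0, 2.0), origin=(1.0, 0.0, 0.0))
        assert np.allclose(g.axis_coords(0), [1.0, 3.0, 5.0])


class TestRasterize:
    def test_square_four_voxels(self, unit_grid5):
        # corners (0.5,0.5)-(2.5,2.5): exactly centers (1,1),(1,2),(2,1),(2,2)
        verts = np.array([[0.5, 0.5], [2.5, 0.5], [2.5, 2.5], [0.5, 2.5]])
        mask = rasterize_contours(ContourSet("sq", [(2.0, verts)]), unit_grid5)
        occ = mask.occupancy
        assert occ.sum() == 4
        assert all(occ[i, j, 2] for i in (1, 2) for j in (1, 2))

    def test_polygon_between_centers_empty(self, unit_grid5):
        verts = np.array([[0.1, 0.1], [0.4, 0.1], [0.4, 0.4], [0.1, 0.4]])
        with pytest.warns(UserWarning, match="zero occupied"):
            mask = rasterize_contours(ContourSet("tiny", [(0.0, verts)]), unit_grid5)
        assert mask.voxel_count == 0

    def test_ring_hole(self):
        grid = VolumeGrid(shape=(9, 9, 1), spacing=(1.0, 1.0, 1.0))
        outer = np.array([[0.5, 0.5], [7.5, 0.5], [7.5, 7.5], [0.5, 7.5]])
        inner = np.array([[2.5, 2.5], [5.5, 2.5], [5.5, 5.5], [2.5, 5.5]])
        cs = ContourSet("ring", [(0.0, outer), (0.0, inner)])
        mask = rasterize_contours(cs, grid)
        assert mask.occupancy.all() == False  # noqa: E712 - hole exists
        expected = rasterize_oracle(cs, grid)
        np.testing.assert_array_equal(mask.occupancy, expected)
        # occupancy = outer region minus inner region
        assert mask.occupancy[1, 1, 0] and not mask.occupancy[4, 4, 0]

    def test_too_few_vertices(self):
        with pytest.raises(InvalidContourError):
            ContourSet("bad", [(0.0, np.array([[0, 0], [1, 1]]))])

    def test_off_slice_contour_warns(self, unit_grid5):
        verts = np.array([[0.5, 0.5], [2.5, 0.5], [2.5, 2.5], [0.5, 2.5]])
        with pytest.warns(UserWarning) as record:
            mask = rasterize_contours(ContourSet("off", [(17.0, verts)]), unit_grid5)
        assert any("no grid slice" in str(w.message) for w in record)
        assert mask.voxel_count == 0

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_oracle_random_polygons(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(8, 33))
        grid = VolumeGrid(shape=(n, n, 3), spacing=(1.0, 1.0, 2.0), origin=(-1.0, 0.5, 0.0))
        polygons = []
        for iz in range(3):
            z = grid.axis_coords(2)[iz]
            for _ in range(int(rng.integers(1, 4))):
                # star-shaped random polygon (simple by construction)
                k = int(rng.integers(3, 9))
                angles = np.sort(rng.uniform(0, 2 * np.pi, k))
                radii = rng.uniform(0.13 * n, 0.45 * n, k)
                cx, cy = rng.uniform(0, n, 2)
                verts = np.column_stack(
                    [cx + radii * np.cos(angles), cy + radii * np.sin(angles)]
                )
                polygons.append((z, verts))
        cs = ContourSet("rand", polygons)
        mask = rasterize_contours(cs, grid)
        np.testing.assert_array_equal(mask.occupancy, rasterize_oracle(cs, grid))


class TestSubtract:
    def test_disjoint(self, unit_grid5):
        a = np.zeros((5, 5, 5), bool); a[0] = True
        b = np.zeros((5, 5, 5), bool); b[4] = True
        res = subtract_masks(make_mask(unit_grid5, a, "A"), make_mask(unit_grid5, b, "B"))
        np.testing.assert_array_equal(res.occupancy, a)
        assert res.name == "A-B"

    def test_subset_empty(self, unit_grid5):
        a = np.zeros((5, 5, 5), bool); a[2, 2, 2] = True
        b = np.ones((5, 5, 5), bool)
        with pytest.warns(UserWarning, match="zero occupied"):
            res = subtract_masks(make_mask(unit_grid5, a), make_mask(unit_grid5, b))
        assert res.is_empty

    def test_block_minus_center(self, unit_grid5):
        a = np.zeros((5, 5, 5), bool); a[1:4, 1:4, 1:4] = True
        b = np.zeros((5, 5, 5), bool); b[2, 2, 2] = True
        res = subtract_masks(make_mask(unit_grid5, a), make_mask(unit_grid5, b))
        assert res.voxel_count == 26

    def test_grid_mismatch(self, unit_grid5):
        other = VolumeGrid(shape=(5, 5, 5), spacing=(2.0, 1.0, 1.0))
        a = make_mask(unit_grid5, np.ones((5, 5, 5), bool))
        b = make_mask(other, np.ones((5, 5, 5), bool))
        with pytest.raises(GeometryError):
            subtract_masks(a, b)

    @pytest.mark.parametrize("seed", range(6))
    def test_partition_property(self, unit_grid5, seed):
        # |a - b| + |a AND b| == |a| and (a - b) AND b == empty
        rng = np.random.default_rng(seed)
        a = rng.random((5, 5, 5)) < 0.5
        b = rng.random((5, 5, 5)) < 0.5
        a[0, 0, 0] = b[1, 1, 1] = True  # avoid empty-mask warnings
        ma, mb = make_mask(unit_grid5, a, "A"), make_mask(unit_grid5, b, "B")
        res = subtract_masks(ma, mb)
        assert res.voxel_count + int((a & b).sum()) == ma.voxel_count
        assert not (res.occupancy & b).any()


class TestResample:
    def test_identity(self, unit_grid5):
        rng = np.random.default_rng(0)
        dose = DoseGrid(grid=unit_grid5, dose=rng.random((5, 5, 5)))
        out = resample_dose(dose, unit_grid5)
        np.testing.assert_array_equal(out.dose, dose.dose)

    def test_constant_preserved(self, unit_grid5):
        dose = make_dose(unit_grid5, 10.0)
        target = VolumeGrid(shape=(9, 9, 9), spacing=(0.5, 0.5, 0.5), origin=(0.0, 0.0, 0.0))
        out = resample_dose(dose, target)
        np.testing.assert_allclose(out.dose, 10.0)

    def test_midpoint_trilinear(self):
        src = VolumeGrid(shape=(2, 1, 1), spacing=(1.0, 1.0, 1.0))
        dose = DoseGrid(grid=src, dose=np.array([0.0, 20.0]).reshape(2, 1, 1))
        target = VolumeGrid(shape=(1, 1, 1), spacing=(1.0, 1.0, 1.0), origin=(0.5, 0.0, 0.0))
        out = resample_dose(dose, target)
        assert out.dose[0, 0, 0] == pytest.approx(10.0)

    def test_out_of_extent_zero(self, unit_grid5):
        dose = make_dose(unit_grid5, 5.0)
        target = VolumeGrid(shape=(3, 3, 3), spacing=(1.0, 1.0, 1.0), origin=(3.0, 3.0, 3.0))
        out = resample_dose(dose, target)
        assert out.dose[0, 0, 0] == pytest.approx(5.0)  # (3,3,3) still in extent
        assert out.dose[2, 2, 2] == 0.0  # (5,5,5) outside

    def test_zero_overlap_raises(self, unit_grid5):
        dose = make_dose(unit_grid5, 5.0)
        target = VolumeGrid(shape=(2, 2, 2), spacing=(1.0, 1.0, 1.0), origin=(100.0, 0.0, 0.0))
        with pytest.raises(GeometryError):
            resample_dose(dose, target)
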