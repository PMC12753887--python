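import numpy as np
import pytest

from cordsim import (
    AtrophySpec,
    CordMask,
    SimulationRecipe,
    StructuringElement,
    Volume3D,
    composite,
    compute_csa,
    dilate_mask,
    fill_canal,
    scale_cord,
    simulate_atrophy,
    strip_cord,
)
from cordsim.atrophy import slice_centroids

ATROPHY_GRID = (0.5, 1.0, 1.5, 2.0, 3.0, 4.0, 5.0, 6.0, 10.0)


class TestAtrophySpec:
    @pytest.mark.parametrize("a", [0.0, 0.5, 10.0, 99.9])
    def test_area_consistency(self, a):
        s = AtrophySpec(a).linear_scale
        assert 0 < s <= 1
        assert (1 - s**2) * 100 == pytest.approx(a, abs=1e-9)

    def test_zero_atrophy_is_identity_scale(self):
        assert AtrophySpec(0.0).linear_scale == 1.0

    @pytest.mark.parametrize("a", [-1.0, 100.0, 150.0])
    def test_invalid_percent(self, a):
        with pytest.raises(ValueError):
            AtrophySpec(a)


class TestStripCord:
    def test_partition_of_volume(self, phantom):
        vol, mask, _ = phantom
        cord_only, dilated = strip_cord(vol, mask, StructuringElement(3))
        inside = dilated.data > 0
        np.testing.assert_array_equal(cord_only.data[inside], vol.data[inside])
        assert (cord_only.data[~inside] == 0).all()

    def test_dilation_monotonicity(self, phantom):
        vol, mask, _ = phantom
        _, dilated = strip_cord(vol, mask, StructuringElement(3))
        assert dilated.data.sum() > mask.data.sum()

    def test_empty_mask_rejected(self):
        vol = Volume3D(np.zeros((4, 4, 2)), (1, 1, 1))
        empty = CordMask(np.zeros((4, 4, 2)), (1, 1, 1))
        with pytest.raises(ValueError, match="empty"):
            strip_cord(vol, empty, StructuringElement(1))


def region_mask(shape, coords):
    m = np.zeros(shape)
    for c in coords:
        m[c] = 1.0
    return CordMask(m, (1, 1, 1))


class TestFillCanal:
    def test_constant_boundary_fills_constant(self):
        vol = Volume3D(np.full((8, 8, 1), 5.0), (1, 1, 1))
        region = region_mask((8, 8, 1), [(3, 3, 0), (3, 4, 0), (4, 3, 0), (4, 4, 0)])
        out = fill_canal(vol, region)
        np.testing.assert_allclose(out.data, 5.0, atol=1e-12)

    def test_linear_run_interpolates(self):
        """A 1x3 unknown run between Dirichlet values 0 and 4 fills 1, 2, 3.

        The 5-point stencil reduces to the 1-D tridiagonal Laplace system
        here because the lateral neighbours mirror the same linear ramp.
        """
        data = np.zeros((3, 5, 1))
        data[:, :, 0] = np.tile([0.0, 1.0, 2.0, 3.0, 4.0], (3, 1))
        vol = Volume3D(data, (1, 1, 1))
        region = region_mask((3, 5, 1), [(1, 1, 0), (1, 2, 0), (1, 3, 0)])
        scr = vol.data.copy()
        scr[1, 1:4, 0] = 99.0  # make sure the solver really overwrites
        out = fill_canal(Volume3D(scr, (1, 1, 1)), region)
        np.testing.assert_allclose(out.data[1, 1:4, 0], [1.0, 2.0, 3.0], atol=1e-10)

    def test_matches_dense_direct_solve(self, rng):
        """Sparse per-slice solve equals an independent dense Dirichlet solve."""
        from scipy import ndimage

        for _ in range(5):
            sl = rng.random((24, 24))
            seed_blob = np.zeros((24, 24), bool)
            seed_blob[10:14, 9:15] = True
            blob = ndimage.binary_dilation(seed_blob, iterations=rng.integers(1, 4))
            blob[0, :] = blob[-1, :] = blob[:, 0] = blob[:, -1] = False
            vol = Volume3D(sl[:, :, None], (1, 1, 1))
            region = CordMask(blob[:, :, None].astype(float), (1, 1, 1))
            out = fill_canal(vol, region)

            # dense oracle: assemble the full Laplace system with numpy only
            idx = {tuple(p): i for i, p in enumerate(np.argwhere(blob))}
            n = len(idx)
            A = np.zeros((n, n))
            b = np.zeros(n)
            for (x, y), i in idx.items():
                A[i, i] = 4.0
                for q in ((x + 1, y), (x - 1, y), (x, y + 1), (x, y - 1)):
                    if q in idx:
                        A[i, idx[q]] = -1.0
                    else:
                        b[i] += sl[q]
            dense = np.linalg.solve(A, b)
            got = np.array([out.data[x, y, 0] for (x, y) in idx])
            np.testing.assert_allclose(got, dense, rtol=1e-8)

    def test_interior_is_discrete_harmonic(self, phantom):
        vol, mask, _ = phantom
        _, dilated = strip_cord(vol, mask, StructuringElement(3))
        out = fill_canal(vol, dilated)
        reg = dilated.data > 0
        lap = (
            4 * out.data
            - np.roll(out.data, 1, 0)
            - np.roll(out.data, -1, 0)
            - np.roll(out.data, 1, 1)
            - np.roll(out.data, -1, 1)
        )
        from scipy import ndimage

        interior = ndimage.binary_erosion(
            reg, structure=np.array([[[0], [1], [0]], [[1], [1], [1]], [[0], [1], [0]]])
        )
        rng_int = out.data.max() - out.data.min()
        assert np.abs(lap[interior]).max() <= 1e-6 * rng_int

    def test_outside_region_bit_exact(self, phantom):
        vol, mask, _ = phantom
        _, dilated = strip_cord(vol, mask, StructuringElement(3))
        out = fill_canal(vol, dilated)
        outside = dilated.data == 0
        np.testing.assert_array_equal(out.data[outside], vol.data[outside])

    def test_maximum_principle(self, rng):
        sl = rng.random((16, 16))
        blob = np.zeros((16, 16), bool)
        blob[5:11, 6:12] = True
        vol = Volume3D(sl[:, :, None], (1, 1, 1))
        out = fill_canal(vol, CordMask(blob[:, :, None].astype(float), (1, 1, 1)))
        from scipy import ndimage

        rim = ndimage.binary_dilation(blob) & ~blob
        assert out.data[:, :, 0][blob].min() >= sl[rim].min() - 1e-12
        assert out.data[:, :, 0][blob].max() <= sl[rim].max() + 1e-12

    def test_region_touching_edge_rejected(self):
        vol = Volume3D(np.zeros((6, 6, 1)), (1, 1, 1))
        region = region_mask((6, 6, 1), [(0, 3, 0)])
        with pytest.raises(ValueError, match="edge"):
            fill_canal(vol, region)

    def test_empty_region_is_noop(self, rng):
        vol = Volume3D(rng.random((6, 6, 2)), (1, 1, 1))
        out = fill_canal(vol, CordMask(np.zeros((6, 6, 2)), (1, 1, 1)))
        np.testing.assert_array_equal(out.data, vol.data)


class TestScaleCord:
    def test_zero_atrophy_identity(self, phantom):
        vol, mask, _ = phantom
        out_v, out_m = scale_cord(vol, mask, AtrophySpec(0.0))
        np.testing.assert_allclose(out_v.data, vol.data, atol=1e-9)
        np.testing.assert_allclose(out_m.data, mask.data, atol=1e-9)

    def test_disc_area_law_at_ten_percent(self):
        """The soft mask's area (its sum) tracks s^2 exactly; a 0.5
        threshold tracks it only to lattice-quantization accuracy."""
        xx, yy = np.mgrid[-15:16, -15:16]
        disc = (xx**2 + yy**2 <= 100).astype(float)[:, :, None]
        mask = CordMask(disc, (1, 1, 1))
        vol = Volume3D(disc * 80.0, (1, 1, 1))
        _, soft = scale_cord(vol, mask, AtrophySpec(10.0))
        assert soft.data.sum() / disc.sum() == pytest.approx(0.9, abs=0.005)
        thresh = (soft.data > 0.5).sum() / disc.sum()
        assert thresh == pytest.approx(0.9, abs=0.06)

    def test_centroid_is_fixed_point(self, phantom):
        vol, mask, _ = phantom
        _, soft = scale_cord(vol, mask, AtrophySpec(10.0))
        before = slice_centroids(mask)
        after = slice_centroids(soft)
        assert np.nanmax(np.abs(before - after)) < 0.1

    def test_empty_slice_passes_through(self):
        m = np.zeros((12, 12, 2))
        m[4:8, 4:8, 0] = 1  # slice 1 has no cord
        vol = Volume3D(np.ones((12, 12, 2)), (1, 1, 1))
        out_v, _ = scale_cord(vol, CordMask(m, (1, 1, 1)), AtrophySpec(10.0))
        np.testing.assert_array_equal(out_v.data[:, :, 1], vol.data[:, :, 1])


class TestComposite:
    def test_alpha_extremes(self, rng):
        filled = Volume3D(rng.random((8, 8, 2)), (1, 1, 1))
        cord = Volume3D(rng.random((8, 8, 2)), (1, 1, 1))
        zeros = CordMask(np.zeros((8, 8, 2)), (1, 1, 1))
        ones = CordMask(np.ones((8, 8, 2)), (1, 1, 1))
        np.testing.assert_array_equal(
            composite(filled, cord, zeros).data, filled.data
        )
        np.testing.assert_array_equal(composite(filled, cord, ones).data, cord.data)

    def test_convexity(self, rng):
        filled = Volume3D(rng.random((8, 8, 2)), (1, 1, 1))
        cord = Volume3D(rng.random((8, 8, 2)), (1, 1, 1))
        alpha = CordMask(rng.random((8, 8, 2)), (1, 1, 1))
        out = composite(filled, cord, alpha)
        lo = np.minimum(filled.data, cord.data)
        hi = np.maximum(filled.data, cord.data)
        assert (out.data >= lo - 1e-12).all() and (out.data <= hi + 1e-12).all()

    def test_hard_mode_replaces_above_threshold(self, rng):
        filled = Volume3D(np.zeros((4, 4, 1)), (1, 1, 1))
        cord = Volume3D(np.ones((4, 4, 1)), (1, 1, 1))
        alpha = CordMask(np.full((4, 4, 1), 0.6), (1, 1, 1))
        out = composite(filled, cord, alpha, mode="hard", threshold=0.5)
        np.testing.assert_array_equal(out.data, 1.0)

    def test_geometry_mismatch_rejected(self):
        a = Volume3D(np.zeros((4, 4, 1)), (1, 1, 1))
        b = Volume3D(np.zeros((5, 5, 1)), (1, 1, 1))
        m = CordMask(np.zeros((4, 4, 1)), (1, 1, 1))
        with pytest.raises(ValueError):
            composite(a, b, m)


class TestSimulateAtrophy:
    def test_zero_atrophy_round_trip(self, phantom, baseline):
        vol, mask, _ = phantom
        out, _ = baseline
        dilated = dilate_mask(mask, StructuringElement(3))
        outside = dilated.data == 0
        np.testing.assert_array_equal(out.data[outside], vol.data[outside])
        inside = dilated.data > 0
        rng_int = vol.data.max() - vol.data.min()
        assert np.abs(out.data - vol.data)[inside].max() <= 0.01 * rng_int

    @pytest.mark.parametrize("a", [0.5, 4.0, 10.0])
    def test_locality(self, phantom, a):
        """Atrophy only ever edits voxels inside the dilated cord mask."""
        vol, mask, _ = phantom
        out, _, _ = simulate_atrophy(SimulationRecipe(vol, mask, AtrophySpec(a)))
        outside = dilate_mask(mask, StructuringElement(3)).data == 0
        np.testing.assert_array_equal(out.data[outside], vol.data[outside])

    def test_csa_strictly_decreases_over_grid(self, phantom):
        vol, mask, _ = phantom
        csas = []
        for a in ATROPHY_GRID:
            _, soft, _ = simulate_atrophy(SimulationRecipe(vol, mask, AtrophySpec(a)))
            csas.append(compute_csa(soft).mean_mm2)
        assert all(np.diff(csas) < 0)

    def test_deterministic(self, phantom):
        vol, mask, _ = phantom
        r = SimulationRecipe(vol, mask, AtrophySpec(3.0))
        a1, m1, _ = simulate_atrophy(r)
        a2, m2, _ = simulate_atrophy(r)
        np.testing.assert_array_equal(a1.data, a2.data)
        np.testing.assert_array_equal(m1.data, m2.data)

    def test_provenance_records_parameters(self, phantom):
        vol, mask, _ = phantom
        _, _, prov = simulate_atrophy(SimulationRecipe(vol, mask, AtrophySpec(2.0)))
        assert prov["atrophy_percent"] == 2.0
        assert prov["linear_scale"] == pytest.approx(np.sqrt(0.98))
        assert prov["se_radius_px"] == 3
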