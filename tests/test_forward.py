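import numpy as np
import pytest

import mwstroke as mw

from mwstroke.forward import channel_pairs, pack_channels, unpack_channels

from conftest import forward_for


class TestWavenumber:
    def test_vacuum(self):
        k = mw.background_wavenumber(mw.Medium(1.0, 0.0), 1e9)
        assert k.real == pytest.approx(20.958, abs=0.01)
        assert k.imag == pytest.approx(0.0, abs=1e-9)

    def test_head_medium_closed_form(self):
        # frozen from (2 pi f / c) * sqrt(41.40 - 18.694j), principal branch
        k = mw.background_wavenumber(mw.HEAD, 1e9)
        assert k == pytest.approx(138.091 - 29.732j, abs=0.01)

    @pytest.mark.parametrize("sigma", [0.0, 0.1, 1.04, 5.0])
    def test_branch_decaying(self, sigma):
        k = mw.background_wavenumber(mw.Medium(41.4, sigma), 1e9)
        assert k.real > 0
        assert k.imag <= 0


class TestGreensFunction:
    def test_inverse_distance_amplitude(self):
        k = 20.958  # real: no attenuation, pure 1/R
        g1 = mw.greens_function([0, 0, 0], [50, 0, 0], k)
        g2 = mw.greens_function([0, 0, 0], [100, 0, 0], k)
        assert abs(g1) / abs(g2) == pytest.approx(2.0, rel=1e-12)

    def test_lossy_monotone_decay(self):
        k = mw.background_wavenumber(mw.HEAD, 1e9)
        mags = [
            abs(mw.greens_function([0, 0, 0], [r, 0, 0], k)) for r in (20, 40, 60, 80)
        ]
        assert np.all(np.diff(mags) < 0)

    def test_hand_value_head_medium(self):
        # exp(-j k 0.05)/(4 pi 0.05) for k = 138.091 - 29.732j
        g = mw.greens_function([0, 0, 0], [50, 0, 0], 138.091 - 29.732j)
        assert g == pytest.approx(0.29263 - 0.20953j, abs=2e-4)

    def test_coincident_points_raise(self):
        with pytest.raises(ValueError, match="coincide"):
            mw.greens_function([1, 2, 3], [1, 2, 3], 20.0 - 1.0j)


class TestOperatorAssembly:
    def test_shape_55_channels(self, slice_operator, slice_grid):
        assert slice_operator.matrix.shape == (55, slice_grid.n_voxels)
        assert slice_operator.n_channels == 55
        assert len(channel_pairs()) == 55

    def test_calibration_constant_linearity(self, array, slice_grid):
        op1 = mw.assemble_operator(array, slice_grid, mw.HEAD, c0=1.0)
        op2 = mw.assemble_operator(array, slice_grid, mw.HEAD, c0=2.0)
        assert np.allclose(op2.matrix, 2.0 * op1.matrix)

    def test_voxel_volume_linearity(self, array, slice_grid):
        """Entries are proportional to the voxel volume dV."""
        E = np.ones((10, slice_grid.n_voxels), complex)
        coarse = mw.assemble_operator(array, slice_grid, mw.HEAD, field_maps=E)
        fine_grid = mw.make_grid(2.5, None)
        Ef = np.ones((10, fine_grid.n_voxels), complex)
        fine = mw.assemble_operator(array, fine_grid, mw.HEAD, field_maps=Ef)
        assert fine.matrix[0, 0] == pytest.approx(coarse.matrix[0, 0] / 8.0)

    def test_brute_force_entry_oracle(self, array):
        """Entries match an explicit loop over the Green's-product formula."""
        grid = mw.make_grid(25.0, None)
        op = mw.assemble_operator(array, grid, mw.HEAD)
        k_b = mw.background_wavenumber(mw.HEAD, 1e9)
        dV = grid.voxel_volume_mm3 * 1e-9
        for row, (m, n) in enumerate(channel_pairs()):
            for v in range(0, grid.n_voxels, 7):
                gm = mw.greens_function(array.positions[m], grid.centers[v], k_b)
                gn = mw.greens_function(array.positions[n], grid.centers[v], k_b)
                assert op.matrix[row, v] == pytest.approx(k_b**2 * gm * gn * dV, rel=1e-12)

    def test_near_antenna_voxel_dominates(self, array, slice_grid):
        """A voxel close to antenna 0 couples more strongly, on the channels
        that involve antenna 0, than the container-center voxel; its total
        column magnitude dominates as well."""
        op = mw.assemble_operator(array, slice_grid, mw.HEAD)
        a0 = array.positions[0]
        target = a0 + 10.0 * (np.array([0.0, 0.0, 100.0]) - a0) / np.linalg.norm(
            np.array([0.0, 0.0, 100.0]) - a0
        )
        near = int(np.argmin(np.linalg.norm(slice_grid.centers - target, axis=1)))
        center = int(np.argmin(np.linalg.norm(slice_grid.centers, axis=1) ** 2))
        pairs = channel_pairs()
        for row, (m, n) in enumerate(pairs):
            if m == 0 or n == 0:
                assert abs(op.matrix[row, near]) > abs(op.matrix[row, center])
        assert np.linalg.norm(op.matrix[:, near]) > np.linalg.norm(op.matrix[:, center])

    def test_reciprocity_by_construction(self, slice_operator, array, slice_grid):
        """The row for (m, n) equals the symmetric field product for (n, m)."""
        k_b = slice_operator.k_b
        dV = slice_grid.voxel_volume_mm3 * 1e-9
        pairs = channel_pairs()
        row = pairs.index((2, 7))
        gm = mw.greens_function(array.positions[7], slice_grid.centers, k_b)
        gn = mw.greens_function(array.positions[2], slice_grid.centers, k_b)
        assert np.allclose(slice_operator.matrix[row], k_b**2 * gm * gn * dV)


class TestForward:
    def test_zero_contrast_zero_signal(self, slice_operator, slice_grid):
        sc = mw.StrokeScenario("noStroke")
        dS = mw.forward_dS(slice_operator, mw.true_contrast(sc, slice_grid))
        assert np.all(dS == 0)

    def test_linearity(self, slice_operator, slice_grid):
        cmap = mw.true_contrast(mw.stroke_scenario("hStroke", (20, 30), 30), slice_grid)
        doubled = mw.ContrastMap(slice_grid, 2.0 * cmap.values)
        a = mw.forward_dS(slice_operator, cmap)
        b = mw.forward_dS(slice_operator, doubled)
        assert np.allclose(b, 2.0 * a, rtol=1e-14)

    def test_grid_mismatch_raises(self, slice_operator, slab_grid):
        cmap = mw.true_contrast(mw.stroke_scenario("hStroke", (20, 30), 30), slab_grid)
        with pytest.raises(ValueError, match="grid"):
            mw.forward_dS(slice_operator, cmap)

    def test_brute_force_product_oracle(self, array):
        """forward_dS agrees with an explicit per-channel voxel-sum loop."""
        grid = mw.make_grid(25.0, None)
        op = mw.assemble_operator(array, grid, mw.HEAD)
        cmap = mw.true_contrast(mw.stroke_scenario("iStroke", (20, 30), 40), grid)
        dS = mw.forward_dS(op, cmap)
        for row in (0, 17, 54):
            s = sum(op.matrix[row, v] * cmap.values[v] for v in range(grid.n_voxels))
            assert dS[row] == pytest.approx(s, rel=1e-10)

    def test_diameter_monotonicity_and_volume_bound(self, slab_operator):
        """Signal grows strictly with diameter; the 40/20 mm norm ratio lies
        between the fully destructive and fully coherent (volume-ratio 8)
        limits — phase variation over the sphere keeps it below 8."""
        n20, n30, n40 = (
            np.linalg.norm(forward_for(slab_operator, "iStroke", d, (20, 30, 100)))
            for d in (20, 30, 40)
        )
        assert n20 < n30 < n40
        assert 1.0 < n40 / n20 < 8.0

    def test_depth_attenuation(self, slab_operator):
        deep = np.linalg.norm(forward_for(slab_operator, "iStroke", 20, (10, 10, 100)))
        shallow = np.linalg.norm(forward_for(slab_operator, "iStroke", 20, (20, 30, 100)))
        assert deep < shallow

    def test_out_of_plane_attenuation(self, slab_operator):
        off = np.linalg.norm(forward_for(slab_operator, "iStroke", 40, (20, 30, 70)))
        on = np.linalg.norm(forward_for(slab_operator, "iStroke", 40, (20, 30, 100)))
        assert off < on

    def test_stroke_type_sign_opposition(self, slab_operator):
        """Ischemic and hemorrhagic responses point into opposite complex
        half-planes on the dominant channel (opposite-sign contrast)."""
        di = forward_for(slab_operator, "iStroke", 20, (20, 30, 100))
        dh = forward_for(slab_operator, "hStroke", 20, (20, 30, 100))
        k = int(np.argmax(np.abs(di)))
        assert (di[k] * np.conj(dh[k])).real < 0


class TestSynthesize:
    def test_noise_free_identity(self):
        bg = mw.default_background_smatrix()
        S = mw.synthesize_smatrix(bg, np.zeros(55), 0.0)
        assert np.array_equal(S.entries, bg.entries)

    def test_seed_reproducibility(self):
        bg = mw.default_background_smatrix()
        dS = np.full(55, 1e-4 + 1e-4j)
        a = mw.synthesize_smatrix(bg, dS, 1e-5, rng=42)
        b = mw.synthesize_smatrix(bg, dS, 1e-5, rng=42)
        c = mw.synthesize_smatrix(bg, dS, 1e-5, rng=43)
        assert np.array_equal(a.entries, b.entries)
        assert not np.array_equal(a.entries, c.entries)

    def test_exact_reciprocity(self):
        bg = mw.default_background_smatrix()
        S = mw.synthesize_smatrix(bg, np.arange(55) * (1 + 1j) * 1e-4, 1e-4, rng=0)
        assert np.array_equal(S.entries, S.entries.T)

    def test_noise_std_monte_carlo(self):
        """Empirical complex-entry std matches the request within 5%."""
        bg = mw.SMatrix(np.zeros((10, 10)), 1e9)
        rng = np.random.default_rng(7)
        target = 1e-3
        draws = [
            pack_channels(mw.synthesize_smatrix(bg, np.zeros(55), target, rng).entries)
            for _ in range(200)
        ]
        z = np.concatenate(draws)  # 11000 independent complex samples
        assert np.sqrt(np.mean(np.abs(z) ** 2)) == pytest.approx(target, rel=0.05)


def test_pack_unpack_roundtrip():
    rng = np.random.default_rng(0)
    v = rng.normal(size=55) + 1j * rng.normal(size=55)
    S = unpack_channels(v)
    assert np.array_equal(S, S.T)
    assert np.array_equal(pack_channels(S), v)
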