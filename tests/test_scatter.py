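"""Energy-window and transmission-dependent scatter estimators."""

import numpy as np
import pytest

from acspect.phantom import make_kernel_table
from acspect.projector import Projector, ProjectorConfig
from acspect.scatter import (
    ScatterKernelTable,
    ScatterToPrimaryModel,
    WindowArithmetic,
    dew_estimate,
    fit_sf_model,
    fit_tail_monoexp,
    tdsc_scatter_projection,
    tdsc_scatter_projections,
    tew_estimate,
)
from acspect.volume import ProjectionSet, VolumeImage


def proj(data, **kw):
    data = np.asarray(data, dtype=float)
    return ProjectionSet(data, np.zeros(data.shape[0]), 4.8, **kw)


class TestDew:
    wa = WindowArithmetic(peak_width_kev=88.0, lower_width_kev=44.0)

    def test_zero_counts_give_zero_scatter(self):
        assert np.all(dew_estimate(proj(np.zeros((2, 4, 4))), self.wa).data == 0)

    def test_width_ratio_scaling(self):
        """44 keV lower window, 88 keV peak: 10 counts -> 20 estimated."""
        est = dew_estimate(proj(np.full((1, 2, 2), 10.0)), self.wa)
        assert np.allclose(est.data, 20.0)

    def test_linearity(self, rng):
        x = rng.random((3, 8, 8))
        a = dew_estimate(proj(x), self.wa).data
        b = dew_estimate(proj(2 * x), self.wa).data
        assert np.allclose(b, 2 * a)

    def test_missing_width_rejected(self):
        with pytest.raises(ValueError, match="lower"):
            dew_estimate(proj(np.zeros((1, 2, 2))), WindowArithmetic(88.0))


class TestTew:
    wa = WindowArithmetic(43.6, 35.6, 53.4)

    def test_zero_windows_give_zero(self):
        z = proj(np.zeros((1, 3, 3)))
        assert np.all(tew_estimate(z, proj(np.zeros((1, 3, 3))), self.wa).data == 0)

    def test_trapezoid_worked_example(self):
        """C_l = 356 in a 35.6 keV window, C_u = 0, W_p = 43.6 -> 218."""
        lo = proj(np.full((1, 1, 1), 356.0))
        up = proj(np.zeros((1, 1, 1)))
        est = tew_estimate(lo, up, self.wa)
        assert est.data[0, 0, 0] == pytest.approx(218.0)

    def test_flat_spectrum_case(self):
        """Equal count rates per keV in both windows: scatter = r * W_p."""
        r = 3.7
        lo = proj(np.full((1, 2, 2), r * 35.6))
        up = proj(np.full((1, 2, 2), r * 53.4))
        est = tew_estimate(lo, up, self.wa)
        assert np.allclose(est.data, r * 43.6)

    def test_geometry_mismatch_rejected(self):
        with pytest.raises(ValueError, match="geometry"):
            tew_estimate(proj(np.zeros((1, 2, 2))), proj(np.zeros((1, 3, 3))), self.wa)


class TestTailFit:
    def test_noiseless_identity(self):
        x = np.linspace(0, 20, 30)
        y = 5.0 * np.exp(-0.3 * x)
        a, b, rep = fit_tail_monoexp(x, y)
        assert a == pytest.approx(5.0, abs=1e-6)
        assert b == pytest.approx(0.3, abs=1e-6)

    def test_multiplicative_noise_recovers_slope(self):
        rng = np.random.default_rng(42)
        x = np.linspace(0, 20, 30)
        y = 5.0 * np.exp(-0.3 * x) * (1 + 0.05 * rng.standard_normal(30))
        _, b, _ = fit_tail_monoexp(x, y)
        assert abs(b - 0.3) / 0.3 < 0.10

    def test_all_zero_tail_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            fit_tail_monoexp(np.arange(5.0), np.zeros(5))

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            fit_tail_monoexp(np.arange(2.0), np.ones(2))


class TestSfModel:
    def test_noiseless_parameter_recovery(self):
        A, B, g = 3.0, 2.0, 0.5
        p = np.linspace(0.0, 4.0, 25)
        sf = A - B * np.exp(-p) ** g - 1.0
        model = fit_sf_model(p, sf)
        assert model.A == pytest.approx(A, abs=1e-4)
        assert model.B == pytest.approx(B, abs=1e-4)
        assert model.gamma == pytest.approx(g, abs=1e-4)

    def test_zero_path_value_is_A_minus_B_minus_1(self):
        model = ScatterToPrimaryModel(3.0, 2.0, 0.5)
        assert model(0.0) == pytest.approx(3.0 - 2.0 - 1.0)

    def test_degenerate_B_zero_gives_constant(self):
        p = np.linspace(0.0, 4.0, 10)
        sf = np.full(10, 1.5 - 1.0)  # A=1.5, B=0
        model = fit_sf_model(p, sf)
        assert np.allclose(model(p), 0.5, atol=1e-6)

    def test_insufficient_samples_rejected(self):
        with pytest.raises(ValueError, match="4 samples"):
            fit_sf_model([0.0, 1.0, 2.0], [0.1, 0.2, 0.3])


class TestKernelTable:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError, match="increasing"):
            ScatterKernelTable([2.0, 2.0], [0.1, 0.1], [1.0, 1.0])
        with pytest.raises(ValueError, match="slopes"):
            ScatterKernelTable([2.0, 4.0], [0.1, -0.1], [1.0, 1.0])

    def test_unit_sum_normalization(self):
        table, _ = make_kernel_table()
        k = table.kernel_2d(10.0, 0.72)
        assert k.sum() == pytest.approx(table.params_at(10.0)[1], rel=1e-12)

    def test_shallow_depth_warns_and_clamps(self):
        table, _ = make_kernel_table()
        with pytest.warns(UserWarning, match="below tabulated"):
            got = table.params_at(0.5)
        assert got == (table.slopes[0], table.amplitudes[0])


class TestTdsc:
    def test_zero_image_gives_zero_scatter(self):
        table, sf = make_kernel_table()
        img = np.zeros((8, 8, 8))
        rmu = np.full((8, 8, 8), 0.15)
        path = np.ones((8, 8, 8))
        out = tdsc_scatter_projection(img, path, rmu, table, sf, 1.0)
        assert np.all(out == 0)

    def test_single_voxel_hand_assembled_oracle(self):
        """Unit voxel 10 cm deep in uniform water: the scatter projection
        is exactly the 10 cm kernel centred on the voxel, scaled by
        SF(mu * 10)."""
        vox_cm = 4.0
        n, ny = 15, 5
        mu_val = 0.15
        table, sf = make_kernel_table()
        img = np.zeros((n, ny, n))
        rmu = np.full((n, ny, n), mu_val)
        # voxel at y=2; surface index 4 -> depth (4 - 2 + 0.5) * 4 = 10 cm
        img[7, 2, 7] = 1.0
        # interleaved path: (4 - 2 + 0.5) * 4 * mu = 1.5
        dx = vox_cm
        cum = np.cumsum(rmu[:, ::-1, :], axis=1)[:, ::-1, :]
        path = dx * (cum - 0.5 * rmu)
        assert path[7, 2, 7] == pytest.approx(1.5)

        out = tdsc_scatter_projection(img, path, rmu, table, sf, vox_cm)

        # independent hand assembly
        kern = table.kernel_2d(10.0, vox_cm)
        expected = np.zeros((n, n))
        h = kern.shape[0] // 2
        for di in range(-h, h + 1):
            for dj in range(-h, h + 1):
                i, j = 7 + di, 7 + dj
                if 0 <= i < n and 0 <= j < n:
                    expected[i, j] = kern[h + di, h + dj]
        expected *= sf(1.5)
        assert np.allclose(out, expected, rtol=1e-10, atol=1e-12)

    def test_depth_clamp_beyond_40cm(self):
        """A source deeper than 40 cm uses the 40 cm kernel."""
        vox_cm = 6.0
        n, ny = 9, 9
        table, sf = make_kernel_table()
        img = np.zeros((n, ny, n))
        rmu = np.full((n, ny, n), 0.1)
        img[4, 1, 4] = 1.0  # depth (8 - 1 + 0.5) * 6 = 45 cm
        dx = vox_cm
        cum = np.cumsum(rmu[:, ::-1, :], axis=1)[:, ::-1, :]
        path = dx * (cum - 0.5 * rmu)
        out = tdsc_scatter_projection(img, path, rmu, table, sf, vox_cm)
        k45 = table.kernel_2d(45.0, vox_cm)
        k40 = table.kernel_2d(40.0, vox_cm)
        assert np.array_equal(k45, k40)
        assert out[4, 4] == pytest.approx(
            k40[k40.shape[0] // 2, k40.shape[1] // 2] * sf(path[4, 1, 4])
        )

    def test_deeper_source_scatters_more_under_increasing_sf(self):
        """With SF increasing in path length, the deeper of two identical
        sources contributes more integrated scatter."""
        vox_cm = 2.0
        n, ny = 21, 21
        table, sf = make_kernel_table()
        rmu = np.full((n, ny, n), 0.15)
        dx = vox_cm
        cum = np.cumsum(rmu[:, ::-1, :], axis=1)[:, ::-1, :]
        path = dx * (cum - 0.5 * rmu)
        shallow = np.zeros((n, ny, n))
        shallow[10, 15, 10] = 1.0  # depth (20-15+0.5)*2 = 11 cm
        deep = np.zeros((n, ny, n))
        deep[10, 10, 10] = 1.0  # depth 21 cm
        s_shallow = tdsc_scatter_projection(shallow, path, rmu, table, sf, vox_cm)
        s_deep = tdsc_scatter_projection(deep, path, rmu, table, sf, vox_cm)
        assert s_deep.sum() > s_shallow.sum()

    def test_all_angle_operator_is_noise_free_functional(self, rng):
        """Same estimate in -> identical scatter projections out."""
        n = 16
        mu = VolumeImage(np.full((n, n, n), 0.1), 14.4)
        table, sf = make_kernel_table(voxel_size_cm=1.44)
        P = Projector(mu, ProjectorConfig(), [0.0, 90.0, 180.0])
        op = tdsc_scatter_projections(P, table, sf)
        x = rng.random((n, n, n))
        assert np.array_equal(op(x), op(x))
        # linear-ish sanity: scaling the image scales the scatter
        assert np.allclose(op(2 * x), 2 * op(x), rtol=1e-9)


class TestTableIO:
    def test_kernel_table_csv_round_trip(self, tmp_path):
        table, sf = make_kernel_table()
        table.to_csv(tmp_path / "k.csv")
        back = ScatterKernelTable.from_csv(tmp_path / "k.csv")
        assert np.allclose(back.depths_cm, table.depths_cm)
        assert np.allclose(back.slopes, table.slopes)
        assert np.allclose(back.amplitudes, table.amplitudes)

    def test_sf_model_yaml_round_trip(self, tmp_path):
        _, sf = make_kernel_table()
        sf.to_yaml(tmp_path / "sf.yaml")
        back = ScatterToPrimaryModel.from_yaml(tmp_path / "sf.yaml")
        assert (back.A, back.B, back.gamma) == (sf.A, sf.B, sf.gamma)
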