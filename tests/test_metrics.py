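"""RC/CNR metrics, background VOIs and isocontour segmentation."""

import numpy as np
import pytest
from scipy.ndimage import gaussian_filter

from acspect.metrics import (
    calibrate_isocontour_threshold,
    compute_cnr,
    compute_rc,
    isocontour_segment,
    place_background_vois,
    voi_stats,
)
from acspect.phantom import build_phantom, default_phantom_spec
from acspect.volume import VolumeImage


@pytest.fixture(scope="module")
def phantom():
    spec = default_phantom_spec(voxel_size_mm=7.2, grid=64)
    act, mu, labels = build_phantom(spec)
    return spec, act, labels


class TestRc:
    def test_constant_at_truth_gives_100(self, phantom):
        _, act, labels = phantom
        img = act.with_data(np.full(act.shape, 4.2))
        assert compute_rc(img, labels.data == 1, 4.2) == pytest.approx(100.0)

    def test_constant_at_half_truth_gives_50(self, phantom):
        _, act, labels = phantom
        img = act.with_data(np.full(act.shape, 2.1))
        assert compute_rc(img, labels.data == 1, 4.2) == pytest.approx(50.0)

    def test_empty_mask_rejected(self, phantom):
        _, act, labels = phantom
        with pytest.raises(ValueError, match="empty"):
            compute_rc(act, np.zeros(act.shape, dtype=bool), 4.2)

    def test_linear_in_image_scale(self, phantom):
        _, act, labels = phantom
        blurred = act.with_data(gaussian_filter(act.data, 1.5, mode="constant"))
        rc1 = compute_rc(blurred, labels.data == 3, 4.2)
        rc2 = compute_rc(blurred.with_data(blurred.data * 3.0), labels.data == 3, 4.2)
        assert rc2 == pytest.approx(3 * rc1)

    def test_blurred_sphere_rc_matches_dense_convolution_oracle(self, phantom):
        """RC of the 48 ml sphere after a sigma = 1.27 cm blur, vs an
        independent fine-grid numeric convolution of the analytic sphere
        with the Gaussian."""
        spec, act, labels = phantom
        sigma = 1.27
        blurred = act.with_data(
            gaussian_filter(act.data, sigma * 10 / act.voxel_size_mm,
                            mode="constant", truncate=6.0)
        )
        got = compute_rc(blurred, labels.data == 3, spec.sphere_ac_kbq_ml)

        # oracle: mean over the sphere of (bg + (hot-bg) * (sphere ∗ G)),
        # computed on a fine 2 mm grid around the sphere centre
        r = spec.sphere_radii_cm[2]
        c = np.asarray(spec.sphere_centers_cm[2])
        h = 0.2  # cm
        half = int(np.ceil((r + 6 * sigma) / h))
        ax = (np.arange(-half, half + 1)) * h
        X, Y, Z = np.meshgrid(ax, ax, ax, indexing="ij", sparse=True)
        inside = (X**2 + Y**2 + Z**2) <= r**2
        ind = gaussian_filter(inside.astype(float), sigma / h, mode="constant",
                              truncate=6.0)
        hot, bg = spec.sphere_ac_kbq_ml, spec.background_ac_kbq_ml
        vals = bg + (hot - bg) * ind
        want = 100.0 * vals[inside].mean() / hot
        assert got == pytest.approx(want, rel=0.01)


class TestCnr:
    def _bg_boxes(self, shape):
        m1 = np.zeros(shape, dtype=bool); m1[2:6, 2:6, 2:6] = True
        m2 = np.zeros(shape, dtype=bool); m2[10:14, 2:6, 2:6] = True
        m3 = np.zeros(shape, dtype=bool); m3[2:6, 10:14, 2:6] = True
        m4 = np.zeros(shape, dtype=bool); m4[10:14, 10:14, 2:6] = True
        return [m1, m2, m3, m4]

    def test_equal_means_give_zero(self, rng):
        n = 16
        img = VolumeImage(np.ones((n, n, n)), 7.2)
        img.data += rng.normal(0, 0.1, img.shape)
        voi = np.zeros((n, n, n), dtype=bool)
        voi[7:10, 7:10, 7:10] = True
        bgs = self._bg_boxes((n, n, n))
        cnr = compute_cnr(img, voi, bgs)
        assert abs(cnr) < 1.5  # zero contrast up to noise

    def test_worked_arithmetic(self):
        n = 16
        data = np.ones((n, n, n))
        img = VolumeImage(data, 7.2)
        bgs = self._bg_boxes((n, n, n))
        # background: means 1, deterministic "noise" pattern sd=2
        for m in bgs:
            idx = np.where(m)
            signs = np.resize([2.0, -2.0], idx[0].size)
            data[idx] = 1.0 + signs
        voi = np.zeros((n, n, n), dtype=bool)
        voi[7:10, 7:10, 7:10] = True
        data[voi] = 9.0
        assert compute_cnr(img, voi, bgs) == pytest.approx((9 - 1) / 2)

    def test_scale_invariance(self, rng):
        n = 16
        img = VolumeImage(rng.random((n, n, n)) + 1.0, 7.2)
        voi = np.zeros((n, n, n), dtype=bool)
        voi[7:10, 7:10, 7:10] = True
        bgs = self._bg_boxes((n, n, n))
        c1 = compute_cnr(img, voi, bgs)
        c2 = compute_cnr(img.with_data(img.data * 7.3), voi, bgs)
        assert c2 == pytest.approx(c1)

    def test_zero_background_sd_rejected(self):
        n = 16
        img = VolumeImage(np.ones((n, n, n)), 7.2)
        voi = np.zeros((n, n, n), dtype=bool)
        voi[7:10, 7:10, 7:10] = True
        with pytest.raises(ValueError, match="zero"):
            compute_cnr(img, voi, self._bg_boxes((n, n, n)))


class TestBackgroundVois:
    def test_placement_constraints(self, phantom):
        spec, act, labels = phantom
        rng = np.random.default_rng(3)
        vois = place_background_vois(labels, (1, 2, 3), 4, rng=rng)
        assert len(vois) == 4
        sphere = np.isin(labels.data, (1, 2, 3))
        for i, m in enumerate(vois):
            # fully inside background compartment
            assert np.all(labels.data[m] == 4)
            assert not (m & sphere).any()
            # pairwise disjoint
            for other in vois[i + 1:]:
                assert not (m & other).any()

    def test_volumes_close_to_requested(self, phantom):
        spec, act, labels = phantom
        vois = place_background_vois(labels, (1, 2, 3), 4,
                                     rng=np.random.default_rng(4))
        for m, want in zip(vois, (54.0, 145.0, 260.0, 280.0)):
            got = m.sum() * act.voxel_volume_ml
            assert abs(got - want) / want < 0.25  # voxelisation granularity


class TestIsocontour:
    def _blob(self, n=40, vox=4.8, sigma_cm=1.5):
        img = VolumeImage(np.zeros((n, n, n)), vox)
        img.data[n // 2, n // 2, n // 2] = 1.0
        img.data = gaussian_filter(img.data, sigma_cm * 10 / vox)
        return img

    def test_threshold_100_keeps_only_max(self):
        img = self._blob()
        mask = isocontour_segment(img, np.ones(img.shape, dtype=bool), 100.0)
        assert mask.sum() == 1

    def test_half_maximum_diameter_matches_fwhm(self):
        """50% isocontour of a Gaussian blob spans the FWHM."""
        img = self._blob(sigma_cm=1.5)
        mask = isocontour_segment(img, np.ones(img.shape, dtype=bool), 50.0)
        n = img.shape[0]
        prof = mask[:, n // 2, n // 2]
        extent_mm = prof.sum() * img.voxel_size_mm
        want = 2 * np.sqrt(2 * np.log(2)) * 15.0  # sigma 1.5 cm -> FWHM mm
        assert abs(extent_mm - want) <= img.voxel_size_mm

    def test_only_component_with_global_max_returned(self):
        n = 32
        img = VolumeImage(np.zeros((n, n, n)), 4.8)
        img.data[5:8, 5:8, 5:8] = 0.9  # second hot spot above threshold
        img.data[20:23, 20:23, 20:23] = 1.0
        mask = isocontour_segment(img, np.ones(img.shape, dtype=bool), 80.0)
        assert mask[21, 21, 21] and not mask[6, 6, 6]

    def test_volume_monotone_in_threshold(self):
        img = self._blob()
        search = np.ones(img.shape, dtype=bool)
        vols = [isocontour_segment(img, search, p).sum() for p in (30, 50, 70, 90)]
        assert np.all(np.diff(vols) < 0)

    def test_empty_search_region_rejected(self):
        img = self._blob()
        with pytest.raises(ValueError, match="empty"):
            isocontour_segment(img, np.zeros(img.shape, dtype=bool), 50.0)


class TestThresholdCalibration:
    def test_single_candidate_returned(self):
        img = VolumeImage(np.random.default_rng(0).random((8, 8, 8)), 4.8)
        got = calibrate_isocontour_threshold(
            img, np.ones(img.shape, dtype=bool), 48.0, [70]
        )
        assert got == 70.0

    def test_constructed_blob_returns_matching_threshold(self):
        """Blob built so that its 70% isocontour volume equals the target
        volume exactly."""
        n, vox = 40, 4.8
        img = VolumeImage(np.zeros((n, n, n)), vox)
        img.data[n // 2, n // 2, n // 2] = 1.0
        img.data = gaussian_filter(img.data, 1.5 * 10 / vox)
        search = np.ones((n, n, n), dtype=bool)
        target_vol = isocontour_segment(img, search, 70.0).sum() * img.voxel_volume_ml
        got = calibrate_isocontour_threshold(img, search, target_vol,
                                             [40, 55, 70, 85])
        assert got == 70.0

    def test_empty_candidates_rejected(self):
        img = VolumeImage(np.ones((4, 4, 4)), 4.8)
        with pytest.raises(ValueError, match="empty"):
            calibrate_isocontour_threshold(img, np.ones((4, 4, 4), bool), 48.0, [])


def test_voi_stats_reports_volume():
    img = VolumeImage(np.ones((10, 10, 10)), 10.0)
    mask = np.zeros((10, 10, 10), dtype=bool)
    mask[:5] = True
    s = voi_stats(img, mask, "half")
    assert s.volume_ml == pytest.approx(500.0)
    assert s.mean == 1.0 and s.sd == 0.0
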