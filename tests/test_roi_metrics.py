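"""ROI statistics: definitions, invariances, Monte-Carlo recovery."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mriqa import roi_metrics as roi

from _oracles import masked_stats_bruteforce


def stats(label, mean, sd, n=10):
    return roi.RegionStats(label=label, mean=mean, sd=sd, n=n)


class TestRegionStats:
    def test_hand_arithmetic(self):
        img = np.array([[1.0, 2.0], [3.0, 4.0]])
        mask = np.full((2, 2), roi.LABEL_CODES["pos1"])
        out = roi.region_stats(img, mask, "pos1")
        assert out.mean == 2.5
        assert out.sd == pytest.approx(1.2909944, abs=1e-6)

    def test_uniform_region_sd_zero(self):
        img = np.full((4, 4), 7.0)
        mask = np.full((4, 4), roi.LABEL_CODES["BG"])
        assert roi.region_stats(img, mask, "BG").sd == 0.0

    def test_too_few_voxels_rejected(self):
        img = np.zeros((4, 4))
        mask = np.zeros((4, 4), int)
        mask[0, 0] = roi.LABEL_CODES["pos1"]
        with pytest.raises(ValueError, match=">= 2"):
            roi.region_stats(img, mask, "pos1")

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, derandomize=True, deadline=None)
    def test_matches_bruteforce_loop(self, seed):
        rng = np.random.default_rng(seed)
        img = rng.normal(50, 20, (12, 12))
        mask = rng.integers(0, 5, (12, 12))
        code = roi.LABEL_CODES["pos2"]
        if (mask == code).sum() < 2:
            mask[:2, :2] = code
        out = roi.region_stats(img, mask, "pos2")
        mean_bf, sd_bf, n_bf = masked_stats_bruteforce(img, mask, code)
        assert out.mean == pytest.approx(mean_bf, abs=1e-9)
        assert out.sd == pytest.approx(sd_bf, abs=1e-9)
        assert out.n == n_bf


class TestIndices:
    def test_snr_definition(self):
        assert roi.snr(stats("pos1", 100, 5), stats("BG", 0, 2)) == 50.0

    def test_snr_zero_mean_tissue(self):
        assert roi.snr(stats("pos1", 0, 5), stats("BG", 0, 2)) == 0.0

    def test_snr_degenerate_background_rejected(self):
        with pytest.raises(ValueError, match="degenerate background"):
            roi.snr(stats("pos1", 100, 5), stats("BG", 0, 0))

    def test_cnr_definition_and_symmetry(self):
        p1, p2, bg = stats("pos1", 100, 5), stats("pos2", 50, 5), stats("BG", 0, 2)
        assert roi.cnr(p1, p2, bg) == 25.0
        assert roi.cnr(p2, p1, bg) == 25.0

    def test_cnr_no_contrast(self):
        p = stats("pos1", 80, 5)
        assert roi.cnr(p, stats("pos2", 80, 3), stats("BG", 0, 2)) == 0.0

    def test_cvp_definition(self):
        assert roi.cvp(stats("FG", 100, 10)) == pytest.approx(0.1)
        assert roi.cvp(stats("FG", 100, 0)) == 0.0

    def test_cjv_definition(self):
        assert roi.cjv(stats("pos1", 100, 10), stats("pos2", 50, 5)) \
            == pytest.approx(0.3)
        assert roi.cjv(stats("pos1", 100, 0), stats("pos2", 50, 0)) == 0.0

    def test_cjv_equal_means_rejected(self):
        with pytest.raises(ValueError, match="indistinguishable"):
            roi.cjv(stats("pos1", 50, 1), stats("pos2", 50, 1))

    def test_relative_snr_reduces_to_mean_ratio(self):
        p1, p2, bg = stats("pos1", 100, 4), stats("pos2", 50, 4), stats("BG", 0, 2)
        assert roi.relative_snr(p1, p2, bg) == pytest.approx(2.0)
        assert roi.relative_snr(p1, p1, bg) == pytest.approx(1.0)

    def test_scale_invariance(self):
        p1, p2, bg = stats("pos1", 100, 10), stats("pos2", 40, 5), stats("BG", 0, 2)
        a = 3.7
        scaled = (stats("pos1", 100 * a, 10 * a), stats("pos2", 40 * a, 5 * a),
                  stats("BG", 0, 2 * a))
        assert roi.snr(p1, bg) == pytest.approx(roi.snr(scaled[0], scaled[2]))
        assert roi.cnr(p1, p2, bg) == pytest.approx(roi.cnr(*scaled))
        assert roi.cjv(p1, p2) == pytest.approx(roi.cjv(scaled[0], scaled[1]))
        assert roi.relative_snr(p1, p2, bg) == pytest.approx(
            roi.relative_snr(*scaled))


class TestHistogramInit:
    def test_three_level_partition(self):
        img = np.repeat([0.0, 100.0, 200.0], 10).reshape(3, 10)
        labels = roi.init_rois_by_histogram(img, (50.0, 150.0))
        assert np.all(labels[0] == roi.LABEL_CODES["BG"])
        assert np.all(labels[1] == roi.LABEL_CODES["pos1"])
        assert np.all(labels[2] == roi.LABEL_CODES["pos2"])

    def test_every_voxel_labeled_exactly_once(self):
        rng = np.random.default_rng(3)
        img = rng.random((20, 20)) * 300
        labels = roi.init_rois_by_histogram(img, (100.0, 200.0))
        codes = {roi.LABEL_CODES[k] for k in ("BG", "pos1", "pos2")}
        assert set(np.unique(labels)) <= codes
        assert labels.size == img.size

    def test_fg_is_union_of_tissues(self):
        rng = np.random.default_rng(4)
        img = rng.random((20, 20)) * 300
        labels = roi.init_rois_by_histogram(img, (100.0, 200.0))
        fg = roi.foreground_mask(labels)
        union = (labels == roi.LABEL_CODES["pos1"]) | \
            (labels == roi.LABEL_CODES["pos2"])
        assert np.array_equal(fg, union)

    def test_non_ascending_thresholds_rejected(self):
        with pytest.raises(ValueError, match="ascending"):
            roi.init_rois_by_histogram(np.zeros((8, 8)), (150.0, 50.0))


class TestSphereMask:
    def test_radius_respected(self):
        mask = roi.sphere_mask((21, 21), (10, 10), radius_mm=5.0,
                               spacing=(1.0, 1.0))
        assert mask[10, 10] and mask[10, 15] and not mask[10, 16]

    def test_anisotropic_spacing(self):
        mask = roi.sphere_mask((21, 21), (10, 10), radius_mm=5.0,
                               spacing=(2.0, 1.0))
        assert mask[12, 10] and not mask[13, 10]
        assert mask[10, 15]


class TestMonteCarloRecovery:
    def test_analytic_recovery_on_gaussian_phantom(self):
        """SNR/CNR/CJV estimates land within 3 standard errors of truth."""
        rng = np.random.default_rng(11)
        mu1, mu2, sd_t, sd_bg = 400.0, 150.0, 12.0, 8.0
        n = 4000
        img = np.concatenate([
            rng.normal(mu1, sd_t, n), rng.normal(mu2, sd_t, n),
            rng.normal(0.0, sd_bg, n)]).reshape(3, n)
        labels = np.concatenate([
            np.full(n, roi.LABEL_CODES["pos1"]),
            np.full(n, roi.LABEL_CODES["pos2"]),
            np.full(n, roi.LABEL_CODES["BG"])]).reshape(3, n)
        report = roi.roi_report(img, labels)

        # delta-method standard errors at these voxel counts
        se_snr = np.sqrt(sd_t ** 2 / (n * sd_bg ** 2)
                         + mu1 ** 2 / (2 * n * sd_bg ** 2))
        assert report.snr_pos1 == pytest.approx(mu1 / sd_bg, abs=3 * se_snr)

        cnr_true = (mu1 - mu2) / sd_bg
        se_cnr = np.sqrt(2 * sd_t ** 2 / (n * sd_bg ** 2)
                         + cnr_true ** 2 / (2 * n))
        assert report.cnr == pytest.approx(cnr_true, abs=3 * se_cnr)

        cjv_true = 2 * sd_t / (mu1 - mu2)
        dmu = mu1 - mu2
        se_cjv = np.sqrt(2 * (sd_t ** 2 / (2 * n)) / dmu ** 2
                         + (2 * sd_t) ** 2 * 2 * sd_t ** 2 / (n * dmu ** 4))
        assert report.cjv == pytest.approx(cjv_true, abs=3 * se_cjv)

    def test_shading_gradient_raises_cvp(self):
        rng = np.random.default_rng(12)
        flat = rng.normal(200, 5, (40, 40))
        shading = np.linspace(0.8, 1.2, 40)[None, :]
        labels = np.full((40, 40), roi.LABEL_CODES["FG"])
        flat_stats = roi.region_stats(flat, labels, "FG")
        shaded_stats = roi.region_stats(flat * shading, labels, "FG")
        assert roi.cvp(shaded_stats) > roi.cvp(flat_stats)

    def test_added_noise_raises_cjv(self):
        rng = np.random.default_rng(13)
        base1 = np.full(2000, 300.0)
        base2 = np.full(2000, 100.0)
        img = np.stack([base1, base2])
        noisy = img + rng.normal(0, 20, img.shape)
        labels = np.stack([np.full(2000, roi.LABEL_CODES["pos1"]),
                           np.full(2000, roi.LABEL_CODES["pos2"])])
        cjv_clean = roi.cjv(roi.region_stats(img + rng.normal(0, 1, img.shape),
                                             labels, "pos1"),
                            roi.region_stats(img, labels, "pos2"))
        cjv_noisy = roi.cjv(roi.region_stats(noisy, labels, "pos1"),
                            roi.region_stats(noisy, labels, "pos2"))
        assert cjv_noisy > cjv_clean
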