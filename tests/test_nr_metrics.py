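"""No-reference metrics: TV convention, MSCN statistics, AGGD fits, BRISQUE."""

import numpy as np
import pytest

from mriqa import nr_metrics as nr
from mriqa.phantom import apply_gaussian_blur

from _oracles import (
    aggd_fit_bruteforce, brisque_features_bruteforce, mscn_bruteforce,
    sample_aggd, tv_bruteforce,
)


@pytest.fixture(scope="module")
def rng():
    return np.random.default_rng(7)


@pytest.fixture(scope="module")
def small_slice(textured_slice):
    return textured_slice[64:128, 64:128]


class TestTotalVariation:
    def test_constant_image_is_zero(self):
        assert nr.total_variation(np.full((16, 16), 5.0)) == 0.0

    def test_hand_computed_2x2(self):
        assert nr.total_variation(np.array([[0.0, 1.0], [0.0, 1.0]])) == 0.5

    def test_matches_bruteforce_oracle(self, rng):
        for _ in range(10):
            shape = rng.integers(8, 33, size=2)
            img = rng.random(tuple(shape)) * rng.uniform(1, 500)
            assert nr.total_variation(img) == pytest.approx(
                tv_bruteforce(img), abs=1e-9)

    def test_blur_strictly_decreases_tv(self, small_slice):
        assert nr.total_variation(apply_gaussian_blur(small_slice, 7)) \
            < nr.total_variation(small_slice)


class TestMscn:
    def test_constant_image_gives_zero_field(self):
        field = nr.mscn_coefficients(np.full((32, 32), 9.0))
        assert np.allclose(field, 0.0)

    def test_white_noise_field_mean_near_zero(self, rng):
        img = rng.normal(500, 40, (128, 128))
        assert abs(nr.mscn_coefficients(img).mean()) < 0.05

    def test_affine_invariance_up_to_stabiliser(self, small_slice):
        # local sigma must dominate the stabiliser C for invariance to show;
        # the large base amplitude puts both fields in that regime
        base = nr.mscn_coefficients(small_slice * 2000.0)
        shifted = nr.mscn_coefficients(small_slice * 2000.0 * 100.0 + 37.0)
        assert np.allclose(base, shifted, atol=1e-3)

    def test_matches_bruteforce_oracle(self, rng):
        img = rng.random((24, 24)) * 255
        assert np.allclose(nr.mscn_coefficients(img), mscn_bruteforce(img),
                           atol=1e-10)


class TestAggdFit:
    def test_gaussian_recovery(self, rng):
        params = nr.fit_aggd(rng.normal(0, 1, 100_000))
        assert params.alpha == pytest.approx(2.0, abs=0.1)
        assert params.sigma_l == pytest.approx(params.sigma_r, rel=0.05)

    def test_laplacian_recovery(self, rng):
        params = nr.fit_aggd(rng.laplace(0, 1, 100_000))
        assert params.alpha == pytest.approx(1.0, abs=0.1)

    @pytest.mark.parametrize("alpha", [0.6, 1.0, 2.0, 4.0])
    def test_parameter_recovery_from_sampler(self, alpha, rng):
        draws = sample_aggd(alpha, 0.8, 1.2, 100_000, rng)
        params = nr.fit_aggd(draws)
        assert params.alpha == pytest.approx(alpha, rel=0.10)
        assert params.sigma_l == pytest.approx(0.8, rel=0.10)
        assert params.sigma_r == pytest.approx(1.2, rel=0.10)

    def test_matches_bruteforce_grid_inversion(self, rng):
        draws = sample_aggd(1.4, 1.0, 0.7, 20_000, rng)
        params = nr.fit_aggd(draws)
        alpha_bf, eta_bf, sl_bf, sr_bf = aggd_fit_bruteforce(draws)
        assert params.alpha == pytest.approx(alpha_bf, abs=1e-3)
        assert params.eta == pytest.approx(eta_bf, abs=1e-3)
        assert (params.sigma_l, params.sigma_r) == (sl_bf, sr_bf)

    def test_one_sided_input_rejected(self, rng):
        with pytest.raises(ValueError, match="both sides"):
            nr.fit_aggd(np.abs(rng.normal(0, 1, 100)) + 0.1)


class TestBrisqueFeatures:
    def test_vector_length(self, small_slice):
        assert nr.brisque_features(small_slice).shape == (36,)

    def test_constant_image_rejected(self):
        with pytest.raises(ValueError, match="featureless"):
            nr.brisque_features(np.full((32, 32), 4.0))

    def test_intensity_scale_invariance(self, small_slice):
        f1 = nr.brisque_features(small_slice)
        f2 = nr.brisque_features(small_slice * 10.0)
        assert np.allclose(f1, f2, atol=1e-2)

    def test_matches_bruteforce_oracle(self):
        from mriqa.phantom import default_breast_spec, make_volume
        spec = default_breast_spec(shape=(10, 64, 64), seed=5)
        volume = make_volume(spec)
        for k in range(2, 7):
            img = volume.slices[k].pixels
            ours = nr.brisque_features(img)
            oracle = brisque_features_bruteforce(img)
            assert np.allclose(ours, oracle, atol=1e-3), f"slice {k}"


@pytest.fixture(scope="module")
def model():
    return nr.load_default_model()


class TestBrisqueScore:
    def test_deterministic(self, small_slice, model):
        feats = nr.brisque_features(small_slice)
        assert nr.brisque_score(feats, model) == nr.brisque_score(feats, model)

    def test_blur_raises_score(self, small_slice, model):
        clean = nr.brisque_score(nr.brisque_features(small_slice), model)
        blurred = nr.brisque_score(
            nr.brisque_features(apply_gaussian_blur(small_slice, 7)), model)
        assert blurred > clean

    def test_noise_raises_score(self, small_slice, model, rng):
        clean = nr.brisque_score(nr.brisque_features(small_slice), model)
        noisy_img = small_slice + rng.normal(
            0, 0.2 * np.ptp(small_slice), small_slice.shape)
        noisy = nr.brisque_score(nr.brisque_features(noisy_img), model)
        assert noisy > clean

    def test_dimension_mismatch_rejected(self, model):
        with pytest.raises(ValueError, match="36"):
            nr.brisque_score(np.zeros(18), model)


class TestModelFile:
    def test_roundtrip_through_loader(self, tmp_path):
        rng = np.random.default_rng(0)
        sv = rng.normal(size=(3, 36))
        lines = ["# test model", "gamma 0.25", "rho -1.5",
                 "feature_min 1 36", " ".join(["-1"] * 36),
                 "feature_max 1 36", " ".join(["1"] * 36),
                 "coefficients 3 1", "0.5", "-0.25", "1.0",
                 "support_vectors 3 36"]
        lines += [" ".join(f"{v:.17g}" for v in row) for row in sv]
        path = tmp_path / "model.txt"
        path.write_text("\n".join(lines) + "\n")
        model = nr.load_brisque_model(path)
        assert model.gamma == 0.25 and model.rho == -1.5
        assert np.allclose(model.support_vectors, sv)
        # hand-evaluated RBF expansion
        x = np.zeros(36)
        expected = sum(c * np.exp(-0.25 * np.sum(s ** 2))
                       for c, s in zip([0.5, -0.25, 1.0], sv)) + 1.5
        assert nr.brisque_score(x, model) == pytest.approx(expected)

    def test_scaling_range_validation(self):
        with pytest.raises(ValueError, match="min < max"):
            nr.BrisqueModel(
                support_vectors=np.zeros((1, 36)), coefficients=[1.0],
                gamma=0.1, rho=0.0,
                feature_min=np.ones(36), feature_max=np.ones(36))
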