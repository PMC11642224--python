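import numpy as np
import pytest

from oactool.enface_processing import (display_scale, local_mean_std, nlm_denoise,
                                       phansalkar_threshold, quantify_area)
from oactool.errors import DataError
from oactool.oct_io import EnFaceImage


def brute_force_local_stats(img, R, window="disk"):
    """Per-pixel loop over the circular neighbourhood with symmetric padding."""
    pad = np.pad(img, R, mode="symmetric")
    ys, xs = np.mgrid[-R:R + 1, -R:R + 1]
    fp = (ys ** 2 + xs ** 2 <= R ** 2) if window == "disk" else np.ones_like(ys, bool)
    mean = np.empty_like(img, dtype=np.float64)
    std = np.empty_like(img, dtype=np.float64)
    for i in range(img.shape[0]):
        for j in range(img.shape[1]):
            patch = pad[i:i + 2 * R + 1, j:j + 2 * R + 1][fp]
            mean[i, j] = patch.mean()
            std[i, j] = patch.std()  # population std
    return mean, std


def brute_force_nlm(img, patch=5, search=11, h=10.0):
    """Plain exhaustive nonlocal means with uniform patch weighting."""
    P, S = patch // 2, search // 2
    pad = np.pad(img, P + S, mode="reflect")
    out = np.zeros_like(img, dtype=np.float64)
    for i in range(img.shape[0]):
        for j in range(img.shape[1]):
            ci, cj = i + P + S, j + P + S
            ref = pad[ci - P:ci + P + 1, cj - P:cj + P + 1]
            wsum = vsum = 0.0
            for di in range(-S, S + 1):
                for dj in range(-S, S + 1):
                    cand = pad[ci + di - P:ci + di + P + 1,
                               cj + dj - P:cj + dj + P + 1]
                    d2 = ((ref - cand) ** 2).mean()
                    w = np.exp(-d2 / h ** 2)
                    wsum += w
                    vsum += w * pad[ci + di, cj + dj]
            out[i, j] = vsum / wsum
    return out


def edge_position(img):
    return np.argmax(np.abs(np.diff(img.mean(axis=0))))


class TestNLMDenoise:
    def test_constant_image_unchanged(self):
        img = EnFaceImage(np.full((16, 16), 3.3))
        out = nlm_denoise(img)
        np.testing.assert_array_equal(out.data, img.data)

    def test_reduces_noise_variance(self, rng):
        img = EnFaceImage(5.0 + 0.5 * rng.standard_normal((48, 48)))
        out = nlm_denoise(img)
        assert out.data.var() < img.data.var()

    def test_step_edge_survives_denoising(self, rng):
        base = np.zeros((32, 32))
        base[:, 16:] = 1.0
        noisy = base + 0.08 * rng.standard_normal(base.shape)
        ours = nlm_denoise(EnFaceImage(noisy)).data
        oracle = brute_force_nlm((noisy - noisy.min()) / np.ptp(noisy) * 255)
        assert edge_position(ours) == edge_position(base)
        assert edge_position(oracle) == edge_position(base)

    def test_preserves_kind_and_units(self, rng):
        img = EnFaceImage(rng.random((16, 16)), kind="attenuation", units="mm^-1")
        out = nlm_denoise(img)
        assert (out.kind, out.units) == ("attenuation", "mm^-1")

    def test_rejects_nonfinite(self):
        with pytest.raises(DataError):
            nlm_denoise(EnFaceImage(np.array([[1.0, np.nan], [0.0, 0.0]])))


class TestPhansalkar:
    def test_uniform_image_hand_threshold(self):
        # value 0.6, k = 0.475, std = 0: t = 0.6*(1 + 3 e^-6 - 0.475) ~ 0.3195
        img = np.full((40, 40), 0.6)
        mask = phansalkar_threshold(img, k=0.475, normalize=False)
        assert quantify_area(mask).percent_white == 100.0
        mean, std = local_mean_std(img, 13)
        t = mean * (1 + 3 * np.exp(-10 * mean) + 0.475 * (std / 0.5 - 1))
        # std picks up sqrt(roundoff) from the two-pass variance: atol ~ 1e-6
        np.testing.assert_allclose(t, 0.6 * (1 + 3 * np.e ** -6 - 0.475), atol=1e-6)

    def test_checkerboard_splits_fifty_fifty(self):
        ij = np.add.outer(np.arange(64), np.arange(64))
        img = (ij % 2).astype(np.float64)
        mask = phansalkar_threshold(img, k=0.475, normalize=False)
        # balanced local statistics: threshold ~ 0.5101, so the 1-pixels win
        np.testing.assert_array_equal(mask.mask, img == 1.0)
        assert quantify_area(mask).percent_white == 50.0

    def test_window_stats_match_brute_force(self, rng):
        img = rng.random((32, 32))
        for window in ("disk", "square"):
            mean, std = local_mean_std(img, 5, window=window)
            bmean, bstd = brute_force_local_stats(img, 5, window=window)
            np.testing.assert_allclose(mean, bmean, atol=1e-10)
            np.testing.assert_allclose(std, bstd, atol=1e-10)

    def test_affine_rescale_invariance(self, rng):
        img = rng.random((32, 32))
        a = phansalkar_threshold(img).mask
        b = phansalkar_threshold(7.0 * img - 3.0).mask
        np.testing.assert_array_equal(a, b)

    def test_larger_k_lowers_threshold_in_unit_domain(self, rng):
        # normalized images have window std <= 0.5 = r, so the k-term is
        # non-positive and a larger k can only add white pixels
        img = rng.random((48, 48))
        white_small_k = phansalkar_threshold(img, k=0.475).mask
        white_large_k = phansalkar_threshold(img, k=1.0).mask
        assert np.all(white_large_k | ~white_small_k)

    def test_constant_image_goes_all_white_with_warning(self):
        with pytest.warns(UserWarning):
            mask = phansalkar_threshold(np.full((8, 8), 4.2))
        assert mask.mask.all()

    def test_params_recorded(self, rng):
        mask = phansalkar_threshold(rng.random((16, 16)), R=7, k=0.8)
        assert mask.params["R"] == 7
        assert mask.params["k"] == 0.8
        assert "vmin" in mask.params


class TestQuantifyArea:
    @pytest.mark.parametrize("n_true,n_total,white", [
        (512 * 512, 512 * 512, 100.0),
        (50, 100, 50.0),
        (41, 100, 41.0),
    ])
    def test_counting(self, n_true, n_total, white):
        mask = np.zeros(n_total, dtype=bool)
        mask[:n_true] = True
        m = quantify_area(mask.reshape(-1, 1))
        assert m.percent_white == white
        assert m.percent_black == 100.0 - white

    def test_conservation_on_random_masks(self, rng):
        for _ in range(100):
            m = quantify_area(rng.random((17, 13)) > rng.random())
            assert m.percent_white + m.percent_black == 100.0

    def test_empty_mask_rejected(self):
        with pytest.raises(DataError):
            quantify_area(np.zeros((0, 0), dtype=bool))


class TestDisplayScale:
    def test_fixed_bounds_clip(self):
        img = EnFaceImage(np.array([[-1.0, 5.0], [10.0, 20.0]]))
        out, bounds = display_scale(img, bounds=(0.0, 10.0))
        np.testing.assert_allclose(out.data, [[0.0, 0.5], [1.0, 1.0]])
        assert bounds == (0.0, 10.0)

    def test_percentile_bounds_saturate_tails(self, rng):
        data = rng.random((64, 64))
        data[0, 0] = 1000.0  # a speckle spike must not stretch the scale
        out, (lo, hi) = display_scale(EnFaceImage(data))
        assert hi < 2.0
        assert out.data[0, 0] == 1.0
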