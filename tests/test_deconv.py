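"""Richardson-Lucy correctness against a literal spatial-domain oracle,
flux/non-negativity/likelihood properties, and blind deconvolution."""

import numpy as np
import pytest

from atd import (
    DeconvParams,
    ImageVolume,
    InvalidInputError,
    InvalidParameterError,
    PointSpreadFunction,
    blind_richardson_lucy,
    central_pixel_fraction,
    deconvolve_volume,
    richardson_lucy,
    two_point_image,
)

RATIO_FLOOR = 1e-12


def rl_oracle(img, kernel, iterations, pad):
    """Brute-force RL: edge-replication pad + explicit-loop circular convolution.

    Independent re-derivation of the update rule
    estimate <- estimate * [mirror(psf) (*) (data / (psf (*) estimate))]
    with plain Python loops; used only to cross-check the FFT implementation.
    """
    d = np.pad(np.asarray(img, dtype=float), pad, mode="edge") if pad else np.array(img, float)
    H, W = d.shape
    kh, kw = kernel.shape

    def conv(a, k):
        out = np.zeros_like(a)
        for y in range(H):
            for x in range(W):
                s = 0.0
                for i in range(kh):
                    for j in range(kw):
                        s += k[i, j] * a[(y - (i - kh // 2)) % H, (x - (j - kw // 2)) % W]
                out[y, x] = s
        return out

    mirrored = kernel[::-1, ::-1]
    est = np.full((H, W), d.sum() / d.size)
    for _ in range(iterations):
        model = np.maximum(conv(est, kernel), RATIO_FLOOR)
        est = np.maximum(est * conv(d / model, mirrored), 0.0)
    if pad:
        est = est[pad:-pad, pad:-pad]
    return est


def _blurred_point(psf, canvas=41):
    img = np.zeros((canvas, canvas))
    k = psf.kernel
    y0 = canvas // 2 - k.shape[0] // 2
    img[y0 : y0 + k.shape[0], y0 : y0 + k.shape[1]] = k
    return img


class TestOracleEquivalence:
    def test_one_update_on_1d_spike_blur(self):
        # 9x1 image: unit spike convolved with (0.25, 0.5, 0.25)
        img = np.zeros((9, 1))
        img[3, 0], img[4, 0], img[5, 0] = 0.25, 0.5, 0.25
        kernel = np.array([[0.25], [0.5], [0.25]])
        psf = PointSpreadFunction(kernel, 100.0)
        ours = richardson_lucy(img, psf, DeconvParams(iterations=1)).restored
        theirs = rl_oracle(img, kernel, iterations=1, pad=1)
        np.testing.assert_allclose(ours, theirs, atol=1e-12)

    @pytest.mark.parametrize("kside,iters", [(3, 5), (5, 3)])
    def test_random_small_images(self, rng, kside, iters):
        img = rng.uniform(0.0, 10.0, size=(12, 12))
        k = rng.uniform(0.1, 1.0, size=(kside, kside))
        k[kside // 2, kside // 2] = k.max() + 1.0
        k /= k.sum()
        psf = PointSpreadFunction(k, 100.0)
        ours = richardson_lucy(img, psf, DeconvParams(iterations=iters)).restored
        theirs = rl_oracle(img, k, iterations=iters, pad=kside // 2)
        np.testing.assert_allclose(ours, theirs, atol=1e-10)


class TestRichardsonLucy:
    def test_delta_psf_is_identity_at_every_iteration(self, rng):
        img = rng.uniform(0.0, 5.0, size=(16, 16))
        delta = PointSpreadFunction(np.ones((1, 1)), 100.0)
        for iters in (1, 3, 10):
            res = richardson_lucy(img, delta, DeconvParams(iterations=iters))
            np.testing.assert_allclose(res.restored, img, atol=1e-12)

    def test_flux_conserved_and_nonnegative(self, gauss_psf):
        img = _blurred_point(gauss_psf)
        res = richardson_lucy(img, gauss_psf, DeconvParams(iterations=10))
        assert np.all(res.restored >= 0)
        total = img.sum()
        assert np.all(np.abs(res.flux_trace - total) / total < 1e-3)
        assert abs(res.restored.sum() - total) / total < 1e-3

    @pytest.mark.parametrize("noisy", [False, True])
    def test_poisson_likelihood_monotone(self, gauss_psf, rng, noisy):
        img = _blurred_point(gauss_psf) * 500.0
        if noisy:
            img = rng.poisson(img).astype(float)
        res = richardson_lucy(img, gauss_psf, DeconvParams(iterations=15))
        diffs = np.diff(res.nll_trace)
        assert np.all(diffs <= 1e-7 * np.abs(res.nll_trace[:-1]))

    def test_change_trace_settles(self, gauss_psf):
        # noiseless data with the true PSF: the per-iteration relative change
        # decays monotonically once the first transients have passed
        img = _blurred_point(gauss_psf)
        res = richardson_lucy(img, gauss_psf, DeconvParams(iterations=20))
        tail = res.change_trace[3:]
        assert np.all(np.diff(tail) <= 1e-9)

    def test_input_validation(self, gauss_psf):
        with pytest.raises(InvalidInputError):
            richardson_lucy(np.full((30, 30), -1.0), gauss_psf)
        with pytest.raises(InvalidInputError):
            richardson_lucy(np.ones((5, 5)), gauss_psf)  # PSF larger than image
        with pytest.raises(InvalidParameterError):
            DeconvParams(iterations=0)


class TestBlindRichardsonLucy:
    def test_delta_image_delta_psf_fixed_point(self):
        img = np.zeros((15, 15))
        img[7, 7] = 1.0
        k = np.zeros((5, 5))
        k[2, 2] = 1.0
        delta = PointSpreadFunction(k, 100.0)
        res, psf_out = blind_richardson_lucy(img, delta, DeconvParams(iterations=3))
        np.testing.assert_allclose(res.restored, img, atol=1e-9)
        np.testing.assert_allclose(psf_out.kernel, k, atol=1e-9)

    def test_recovers_generating_kernel_shape(self, bead_airy_psf, cfg_488):
        from atd import pearson_correlation, synthetic_psf

        img = _blurred_point(bead_airy_psf)
        init = synthetic_psf(cfg_488, "gaussian", fwhm_nm=250.0, window_px=15)
        _, psf_out = blind_richardson_lucy(img, init, DeconvParams(iterations=10))
        r = pearson_correlation(psf_out.kernel, bead_airy_psf.kernel)
        assert r > 0.9

    def test_true_psf_beats_blind_at_recentering_light(self, bead_airy_psf, cfg_488):
        from atd import synthetic_psf

        img = _blurred_point(bead_airy_psf)
        center = (img.shape[0] // 2, img.shape[1] // 2)
        true_res = richardson_lucy(img, bead_airy_psf, DeconvParams(iterations=10))
        init = synthetic_psf(cfg_488, "gaussian", fwhm_nm=250.0, window_px=15)
        blind_res, _ = blind_richardson_lucy(img, init, DeconvParams(iterations=10))
        assert central_pixel_fraction(true_res.restored, center) > central_pixel_fraction(
            blind_res.restored, center
        )


class TestCentralPixelFraction:
    def test_delta_and_uniform(self):
        img = np.zeros((9, 9))
        img[4, 4] = 7.0
        assert central_pixel_fraction(img, (4, 4)) == 1.0
        assert central_pixel_fraction(np.ones((9, 9)), (4, 4)) == pytest.approx(1 / 81)

    def test_rl_returns_light_to_the_center(self, gauss_psf):
        img = _blurred_point(gauss_psf)
        center = (img.shape[0] // 2, img.shape[1] // 2)
        before = central_pixel_fraction(img, center)
        restored = richardson_lucy(img, gauss_psf, DeconvParams(iterations=10)).restored
        assert central_pixel_fraction(restored, center) > before

    def test_zero_total_rejected(self):
        with pytest.raises(InvalidInputError):
            central_pixel_fraction(np.ones((5, 5)), (2, 2), background=1.0)


class TestDeconvolveVolume:
    def test_single_section_matches_2d_path(self, gauss_psf):
        img = _blurred_point(gauss_psf)
        vol = ImageVolume(img[None], pixel_nm=100.0)
        out = deconvolve_volume(vol, gauss_psf, DeconvParams(iterations=5))
        direct = richardson_lucy(img, gauss_psf, DeconvParams(iterations=5)).restored
        np.testing.assert_allclose(out.data[0], direct, atol=1e-12)
        assert out.n_sections == 1
        assert out.section_nm == vol.section_nm

    def test_sections_are_independent(self, gauss_psf):
        imgs = [two_point_image(gauss_psf, s, 1.0, 41) for s in (2, 4, 6)]
        vol = ImageVolume(np.stack(imgs), pixel_nm=100.0)
        out = deconvolve_volume(vol, gauss_psf, DeconvParams(iterations=3))
        flipped = ImageVolume(np.stack(imgs[::-1]), pixel_nm=100.0)
        out_flipped = deconvolve_volume(flipped, gauss_psf, DeconvParams(iterations=3))
        np.testing.assert_allclose(out.data, out_flipped.data[::-1], atol=1e-12)

    def test_per_section_flux_conservation(self, gauss_psf):
        from atd import SceneSpec, render_scene

        spec = SceneSpec(
            kind="puncta_volume", shape=(15, 64, 64), n_objects=12, min_separation_px=6, seed=3
        )
        _, observed, _ = render_scene(spec, gauss_psf)
        vol = ImageVolume(observed, pixel_nm=100.0)
        out = deconvolve_volume(vol, gauss_psf, DeconvParams(iterations=10))
        for before, after in zip(vol.sections, out.sections):
            if before.sum() == 0:
                continue
            assert abs(after.sum() - before.sum()) / before.sum() < 1e-3

    def test_pixel_size_mismatch_rejected(self, gauss_psf):
        vol = ImageVolume(np.ones((2, 30, 30)), pixel_nm=50.0)
        with pytest.raises(InvalidParameterError):
            deconvolve_volume(vol, gauss_psf)
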