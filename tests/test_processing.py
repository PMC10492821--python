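"""Boltzmann color mapping, ROF denoising, and grid calibration."""

import numpy as np
import pytest
from scipy import stats
from scipy.optimize import minimize

from msrelevance import (BoltzmannMapSpec, ROFSpec, add_gaussian_noise,
                         boltzmann_map, calibrate, rof_denoise, rof_energy)


class TestBoltzmannMap:
    def test_t0_nearest_color(self):
        img = np.full((10, 10), 0.2)
        out = boltzmann_map(img, BoltzmannMapSpec(palette=(0.0, 1.0), T=0.0, seed=0))
        assert np.all(out == 0.0)

    def test_t0_midpoint_fair_split(self):
        img = np.full((100, 100), 0.5)
        out = boltzmann_map(img, BoltzmannMapSpec(T=0.0, seed=1))
        frac = (out == 1.0).mean()
        assert abs(frac - 0.5) < 0.02  # binomial error at n = 10^4

    def test_symmetric_point_any_temperature(self):
        img = np.full((100, 100), 0.5)
        out = boltzmann_map(img, BoltzmannMapSpec(T=0.3, seed=2))
        assert abs((out == 1.0).mean() - 0.5) < 0.02

    def test_high_temperature_uniform(self):
        img = np.full((100, 100), 0.2)
        out = boltzmann_map(img, BoltzmannMapSpec(T=1e6, seed=3))
        counts = [(out == c).sum() for c in (0.0, 1.0)]
        assert stats.chisquare(counts).pvalue > 0.01

    def test_boltzmann_law_frequencies(self):
        h, T = 0.3, 0.2
        img = np.full((100, 100), h)
        out = boltzmann_map(img, BoltzmannMapSpec(T=T, seed=4))
        w = np.exp(-np.array([(h - 0.0) ** 2, (h - 1.0) ** 2]) / T)
        p_white = w[1] / w.sum()
        n_white = (out == 1.0).sum()
        assert stats.binomtest(int(n_white), 10000, p_white).pvalue > 1e-3

    def test_palette_only_output(self, rng):
        img = rng.random((20, 20))
        pal = (0.0, 0.5, 1.0)
        out = boltzmann_map(img, BoltzmannMapSpec(palette=pal, T=0.1, seed=5))
        assert set(np.unique(out)).issubset(set(pal))

    def test_reproducible(self, rng):
        img = rng.random((16, 16))
        s = BoltzmannMapSpec(T=0.2, seed=9)
        assert np.array_equal(boltzmann_map(img, s), boltzmann_map(img, s))

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            BoltzmannMapSpec(T=-0.1)
        with pytest.raises(ValueError):
            boltzmann_map(np.full((4, 4), 2.0), BoltzmannMapSpec(T=0.1))


class TestROF:
    def test_lambda_zero_identity(self, rng):
        img = rng.random((16, 16))
        assert np.array_equal(rof_denoise(img, ROFSpec(lam=0.0)), img)

    def test_constant_input_fixed_point(self):
        img = np.full((16, 16), 0.4)
        out = rof_denoise(img, ROFSpec(lam=0.5))
        np.testing.assert_allclose(out, img, atol=1e-12)

    def test_2x2_brute_force_oracle(self, rng):
        h = rng.random((2, 2))
        lam = 0.3
        f = rof_denoise(h, ROFSpec(lam=lam, tol=1e-10, max_iter=20000))
        ref = minimize(lambda x: rof_energy(x.reshape(2, 2), h, lam), h.ravel(),
                       method="Nelder-Mead",
                       options={"xatol": 1e-12, "fatol": 1e-14, "maxiter": 50000})
        assert rof_energy(f, h, lam) == pytest.approx(ref.fun, abs=1e-3)

    def test_energy_monotone_decrease(self, rng):
        h = rng.random((32, 32))
        _, info = rof_denoise(h, ROFSpec(lam=0.2), return_info=True)
        E = np.array(info["energies"])
        assert np.all(np.diff(E) <= 1e-9)
        assert E[-1] <= E[0]

    def test_mean_preserved(self, rng):
        h = rng.random((32, 32))
        f = rof_denoise(h, ROFSpec(lam=0.4))
        assert f.mean() == pytest.approx(h.mean(), abs=1e-6)

    def test_large_lambda_flattens_to_mean(self, rng):
        h = rng.random((8, 8))
        f = rof_denoise(h, ROFSpec(lam=1e4, tol=1e-12, max_iter=5000))
        np.testing.assert_allclose(f, h.mean(), atol=1e-3)

    def test_skimage_chambolle_cross_check(self, rng):
        """Independent oracle: skimage's Chambolle solver (weight = lam/2
        in its convention) reaches the same minimizer."""
        from skimage.restoration import denoise_tv_chambolle
        h = rng.random((24, 24))
        lam = 0.3
        f = rof_denoise(h, ROFSpec(lam=lam, tol=1e-9, max_iter=5000))
        sk = denoise_tv_chambolle(h, weight=lam / 2, eps=1e-10, max_num_iter=5000)
        assert np.abs(f - sk).max() < 1e-3

    def test_rof_energy_examples(self, rng):
        h = np.full((8, 8), 2.0)
        assert rof_energy(h, h, 0.7) == 0.0
        g = rng.random((8, 8))
        from msrelevance.processing import tv_iso
        assert rof_energy(g, g, 0.7) == pytest.approx(0.7 * tv_iso(g))
        with pytest.raises(ValueError):
            rof_energy(np.zeros((2, 2)), np.zeros((3, 3)), 0.1)


class TestCalibrate:
    def test_colormap_psnr_argmax_at_zero_temperature(self, rng):
        img = (rng.random((64, 64)) * 255).astype(np.uint8)
        res = calibrate(img, "colormap", grid=[0.0, 0.1, 0.2, 0.4],
                        metrics=["psnr"], realizations=3, seed=0)
        assert res.argmax["psnr"] == 0.0

    def test_denoise_clean_image_prefers_lambda_zero(self, rng):
        img = rng.random((16, 16))
        res = calibrate(img, "denoise", grid=[0.0, 0.1, 0.3], metrics=["psnr"], seed=0)
        assert res.argmax["psnr"] == 0.0
        assert res.scores["psnr"][0] == float("inf")

    def test_scores_table_contract(self, rng):
        img = (rng.random((32, 32)) * 255).astype(np.uint8)
        res = calibrate(img, "colormap", grid=[0.3, 0.0, 0.1], metrics=["psnr", "ssim"],
                        realizations=2, seed=1)
        assert res.grid == [0.0, 0.1, 0.3]  # sorted ascending
        assert set(res.scores) == {"psnr", "ssim"}
        assert all(len(v) == 3 for v in res.scores.values())
        assert all(res.argmax[m] in res.grid for m in res.scores)

    def test_empty_metrics_rejected(self, rng):
        with pytest.raises(ValueError):
            calibrate(rng.random((8, 8)), "colormap", [0.1], metrics=[])

    def test_noise_fixture_clipped_8bit(self):
        img = np.full((32, 32), 128, dtype=np.uint8)
        noisy = add_gaussian_noise(img, sigma=100.0, seed=0)
        assert noisy.min() >= 0 and noisy.max() <= 255
        assert noisy.std() > 50  # strong noise survives clipping
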