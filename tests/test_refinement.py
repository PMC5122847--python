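import math

import numpy as np
import pytest

from smtrack.refinement import (Localization, PSFParams, crlb_position,
                                fisher_information, fit_mle,
                                integrated_gaussian_model,
                                localization_precision, psf_sigma_from_optics,
                                radial_symmetry_center)

GRID15 = np.arange(15.0)


class TestIntegratedGaussianModel:
    def test_zero_photons_gives_background(self):
        img = integrated_gaussian_model(GRID15, GRID15, PSFParams(7, 7, 0.0, 3.5, 1.0))
        np.testing.assert_allclose(img, 3.5)

    def test_signal_sums_to_n_against_numerical_integration(self):
        """Window sum of the signal term equals N; individual pixels agree
        with brute-force 2D integration of the Gaussian density."""
        p = PSFParams(7.0, 7.0, 50.0, 0.0, 1.0)
        img = integrated_gaussian_model(GRID15, GRID15, p)
        assert img.sum() == pytest.approx(50.0, rel=1e-4)
        from scipy.integrate import dblquad
        for (px, py) in [(7, 7), (8, 6), (5, 9)]:
            val, _ = dblquad(
                lambda y, x: math.exp(-((x - 7) ** 2 + (y - 7) ** 2) / 2.0)
                / (2 * math.pi),
                px - 0.5, px + 0.5, py - 0.5, py + 0.5, epsabs=1e-12)
            assert img[py, px] == pytest.approx(50.0 * val, rel=1e-10)

    def test_centered_spot_mirror_symmetric(self):
        img = integrated_gaussian_model(GRID15, GRID15, PSFParams(7, 7, 100, 2, 1.2))
        np.testing.assert_allclose(img, img[::-1, :])
        np.testing.assert_allclose(img, img[:, ::-1])

    def test_invalid_sigma(self):
        with pytest.raises(ValueError):
            PSFParams(0, 0, 1, 0, -1.0)


class TestPsfSigmaFromOptics:
    def test_standard_conditions(self):
        assert psf_sigma_from_optics(670, 1.4, 100) == pytest.approx(1.005)

    def test_nm_grid(self):
        assert psf_sigma_from_optics(670, 1.4, 1) == pytest.approx(100.5)

    def test_doubling_pixel_halves_sigma(self):
        assert psf_sigma_from_optics(670, 1.4, 200) == pytest.approx(
            psf_sigma_from_optics(670, 1.4, 100) / 2)


class TestFitMLE:
    def test_noiseless_recovery(self, spot_image):
        img, p = spot_image
        loc = fit_mle(img, (7, 7), window=15, sigma_init=1.2)
        assert loc.converged
        assert loc.x == pytest.approx(p.mu_x, abs=1e-3)
        assert loc.y == pytest.approx(p.mu_y, abs=1e-3)
        assert loc.params.n_photons == pytest.approx(p.n_photons, rel=0.01)
        assert loc.params.background == pytest.approx(p.background, rel=0.01)
        assert loc.params.sigma_x == pytest.approx(p.sigma_x, rel=0.01)

    def test_astigmatic_recovery(self):
        p = PSFParams(7.2, 7.1, 300.0, 5.0, 1.5, 1.0, 0.4)
        img = integrated_gaussian_model(GRID15, GRID15, p)
        loc = fit_mle(img, (7, 7), window=15, model="astigmatic", sigma_init=1.2)
        assert loc.converged
        assert loc.params.sigma_x == pytest.approx(1.5, rel=0.02)
        assert loc.params.sigma_y == pytest.approx(1.0, rel=0.02)
        assert loc.params.theta == pytest.approx(0.4, rel=0.02)

    def test_isotropic_and_astigmatic_agree_on_round_spot(self, spot_image):
        img, p = spot_image
        iso = fit_mle(img, (7, 7), window=15, sigma_init=1.2)
        ast = fit_mle(img, (7, 7), window=15, model="astigmatic", sigma_init=1.2)
        assert abs(iso.x - ast.x) < 1e-2
        assert abs(iso.y - ast.y) < 1e-2

    def test_all_zero_window_flagged_not_raised(self):
        loc = fit_mle(np.zeros((15, 15)), (7, 7), window=9)
        assert not loc.converged

    def test_translation_equivariance(self, spot_image):
        img, p = spot_image
        frame = np.zeros((40, 40))
        frame[5:20, 5:20] = img
        frame[frame == 0] = p.background
        loc = fit_mle(frame, (12, 12), window=15, sigma_init=1.2)
        assert loc.x == pytest.approx(p.mu_x + 5, abs=1e-3)
        assert loc.y == pytest.approx(p.mu_y + 5, abs=1e-3)

    def test_window_must_fit(self, spot_image):
        img, _ = spot_image
        with pytest.raises(ValueError, match="does not fit"):
            fit_mle(img, (1, 1), window=9)

    def test_scatter_matches_crlb_at_moderate_signal(self, rng):
        """The MLE is efficient in its asymptotic regime: at N=500, b=10 the
        empirical position std matches the CRLB."""
        p = PSFParams(7.3, 6.8, 500.0, 10.0, 1.0)
        img = integrated_gaussian_model(GRID15, GRID15, p)
        fitted = []
        for _ in range(400):
            loc = fit_mle(rng.poisson(img).astype(float), (7, 7), window=9,
                          sigma_init=1.0)
            if loc.converged:
                fitted.append(loc.x)
        crlb_x, _ = crlb_position(p, 9, (7, 7))
        ratio = np.std(fitted, ddof=1) / crlb_x
        assert 0.85 < ratio < 1.15

    def test_rmse_improves_with_snr(self, rng):
        """Position error decreases as the photon yield grows."""
        errors = []
        for n_photons in (50, 200, 800):
            p = PSFParams(7.3, 6.8, n_photons, 10.0, 1.0)
            img = integrated_gaussian_model(GRID15, GRID15, p)
            errs = []
            for _ in range(150):
                loc = fit_mle(rng.poisson(img).astype(float), (7, 7), window=9)
                errs.append((loc.x - 7.3) ** 2 + (loc.y - 6.8) ** 2)
            errors.append(math.sqrt(np.mean(errs)))
        assert errors[0] > errors[1] > errors[2]


class TestRadialSymmetry:
    def _render(self, mu_x, mu_y):
        p = PSFParams(mu_x, mu_y, 1000.0, 0.0, 1.3)
        return integrated_gaussian_model(GRID15, GRID15, p)

    def test_exact_for_centered_spot(self):
        rc = radial_symmetry_center(self._render(7.0, 7.0))
        assert not rc.degenerate
        assert rc.x == pytest.approx(7.0, abs=1e-6)
        assert rc.y == pytest.approx(7.0, abs=1e-6)

    def test_subpixel_shift_recovered(self):
        rc = radial_symmetry_center(self._render(7.25, 7.4))
        assert rc.x == pytest.approx(7.25, abs=0.02)
        assert rc.y == pytest.approx(7.4, abs=0.02)

    def test_constant_window_degenerate(self):
        rc = radial_symmetry_center(np.full((9, 9), 3.0))
        assert rc.degenerate
        assert (rc.x, rc.y) == (4.0, 4.0)

    def test_too_small_window(self):
        with pytest.raises(ValueError):
            radial_symmetry_center(np.zeros((2, 2)))


class TestLocalizationPrecision:
    def _loc(self, n_photons, background=10.0, sigma=1.0):
        p = PSFParams(7.0, 7.0, n_photons, background, sigma)
        return Localization(0, p, 1.0, True, 10, 15, (7, 7))

    def test_monotone_in_photons(self):
        precisions = [localization_precision(self._loc(n), 100.0)[0]
                      for n in (50, 100, 400, 1600)]
        assert precisions == sorted(precisions, reverse=True)

    def test_shot_noise_limit(self):
        """With negligible background the precision approaches
        sigma * a / sqrt(N)."""
        got = localization_precision(self._loc(50, background=1e-9), 100.0)[0]
        assert got == pytest.approx(1.0 * 100.0 / math.sqrt(50), rel=0.10)

    def test_crlb_agrees_with_monte_carlo(self, rng):
        """Predicted precision matches the observed refit scatter (bright
        spot, where the estimator is efficient)."""
        p = PSFParams(7.3, 6.8, 500.0, 10.0, 1.0)
        img = integrated_gaussian_model(GRID15, GRID15, p)
        xs = [fit_mle(rng.poisson(img).astype(float), (7, 7), window=9).x
              for _ in range(300)]
        predicted = crlb_position(p, 9, (7, 7))[0]
        assert np.std(xs, ddof=1) == pytest.approx(predicted, rel=0.15)

    def test_nonconverged_rejected(self):
        loc = self._loc(50)
        loc.converged = False
        with pytest.raises(ValueError):
            localization_precision(loc, 100.0)
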