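import numpy as np
import pytest

import smlmq
from smlmq import (
    CorrelationCurve,
    EstimationError,
    ParameterError,
    autocorrelation_bruteforce,
    autocorrelation_fft,
    decompose_curve,
    fit_clustered,
    fit_random,
    model_clustered,
    model_random,
    select_model,
    thomas_pair_correlation,
)


def _csr_points(n_target_per_um2, box, seed):
    t = smlmq.simulate_molecules("random", box, box, n_target_per_um2, seed=seed)
    return t.molecules[["x_nm", "y_nm"]].to_numpy()


def _aligned(ca, cb, r_min):
    common, ia, ib = np.intersect1d(np.round(ca.r, 6), np.round(cb.r, 6),
                                    return_indices=True)
    sel = common >= r_min
    return ca.g[ia][sel], cb.g[ib][sel]


class TestEstimators:
    def test_two_points_single_nonzero_bin(self):
        pts = np.array([[500.0, 500.0], [500.0, 572.0]])  # distance 72
        c = autocorrelation_bruteforce(pts, (0, 0, 2000, 2000), r_max=200, dr=5)
        nz = np.nonzero(c.g)[0]
        assert len(nz) == 1
        assert c.r[nz[0]] == 72.5

    def test_csr_curve_is_flat_at_one(self):
        # mean curve over replicates within 3 SE of 1 on 20-500 nm; the
        # per-bin SE profile is smoothed over neighbouring bins because a
        # 10-replicate sample sd is itself ~45% noisy
        curves = []
        for seed in range(10):
            pts = _csr_points(700.0, 4000.0, seed)
            curves.append(autocorrelation_fft(pts, (0, 0, 4000, 4000)).g)
        g = np.array(curves)
        mean = g.mean(0)
        se = np.convolve(g.std(0, ddof=1), np.ones(7) / 7, mode="same") / np.sqrt(len(g))
        c = autocorrelation_fft(_csr_points(700.0, 4000.0, 0), (0, 0, 4000, 4000))
        sel = (c.r >= 20) & (c.r <= 500)
        assert np.abs((mean[sel] - 1) / se[sel]).max() < 3.0

    def test_fft_matches_thomas_closed_form(self):
        kappa, s, dens = 50.0, 20.0, 300.0
        lam, area = dens / 1e6, 3000.0 * 3000.0
        curves = []
        for seed in range(20):
            t = smlmq.simulate_molecules("clustered", 3000.0, 3000.0, dens, kappa, s,
                                         seed=seed)
            pts = t.molecules[["x_nm", "y_nm"]].to_numpy()
            c = autocorrelation_fft(pts, (0, 0, 3000, 3000), 5, 400, 10)
            # known-intensity normalization avoids the ratio-estimator bias
            n = len(pts)
            curves.append(c.g * (n * (n - 1) / area**2) / lam**2)
        g = np.array(curves)
        mean, se = g.mean(0), g.std(0, ddof=1) / np.sqrt(len(g))
        c = autocorrelation_fft(pts, (0, 0, 3000, 3000), 5, 400, 10)
        expected = thomas_pair_correlation(c.r, kappa, s)
        sel = c.r > 15  # below ~3 grid bins discretization dominates
        assert np.abs((mean[sel] - expected[sel]) / se[sel]).max() < 3.5

    def test_fft_agrees_with_bruteforce_oracle(self):
        # <= 2000-point patterns, CSR and clustered
        for seed, mode in [(0, "random"), (1, "clustered")]:
            if mode == "random":
                t = smlmq.simulate_molecules("random", 1400.0, 1400.0, 1000.0, seed=seed)
            else:
                t = smlmq.simulate_molecules("clustered", 1400.0, 1400.0, 1000.0,
                                             100.0, 30.0, seed=seed)
            pts = t.molecules[["x_nm", "y_nm"]].to_numpy()[:2000]
            cb = autocorrelation_bruteforce(pts, (0, 0, 1400, 1400), r_max=500, dr=10)
            cf = autocorrelation_fft(pts, (0, 0, 1400, 1400), bin_nm=2, r_max=500, dr=10)
            gb, gf = _aligned(cb, cf, 3 * 2)
            assert np.abs(gb - gf).max() <= 0.05

    def test_half_mask_consistent_with_full_rectangle(self):
        pts = _csr_points(700.0, 4000.0, 3)
        full = autocorrelation_fft(pts, (0, 0, 4000, 4000), 5, 400, 10)
        mask = np.ones((800, 800))
        mask[:, 400:] = 0.0
        half = autocorrelation_fft(pts, (0, 0, 4000, 4000), 5, 400, 10, mask=mask)
        sel = full.r >= 20
        # edge correction keeps both flat; agree within combined noise
        diff = np.abs(full.g[sel] - half.g[sel])
        tol = 4 * np.hypot(full.g_se[sel], half.g_se[sel])
        assert np.all(diff < np.maximum(tol, 0.08))

    def test_too_few_points_is_estimation_error(self):
        with pytest.raises(EstimationError):
            autocorrelation_fft(np.random.default_rng(0).uniform(0, 1000, (50, 2)),
                                (0, 0, 1000, 1000), r_max=200)

    def test_r_max_beyond_half_extent_rejected(self):
        pts = _csr_points(700.0, 2000.0, 1)
        with pytest.raises(ParameterError):
            autocorrelation_fft(pts, (0, 0, 2000, 2000), r_max=1500)


class TestModels:
    def test_random_model_printed_value_and_limit(self):
        assert model_random(0.0, 10.0, 0.001) == pytest.approx(1.79577, abs=1e-4)
        assert model_random(1e6, 10.0, 0.001) == pytest.approx(1.0)

    def test_doubling_rho_halves_excess(self):
        r = np.linspace(0, 200, 50)
        e1 = model_random(r, 15.0, 1e-4) - 1
        e2 = model_random(r, 15.0, 2e-4) - 1
        np.testing.assert_allclose(e2, e1 / 2, rtol=1e-12, atol=1e-14)

    def test_clustered_reduces_to_random_at_zero_amplitude(self):
        r = np.arange(2.5, 500, 5.0)
        np.testing.assert_allclose(
            model_clustered(r, 0.0, 39.0, 12.0, 1e-4),
            model_random(r, 12.0, 1e-4),
            atol=1e-10,
        )

    def test_small_sigma_limit_recovers_exponential(self):
        r = np.linspace(30, 300, 30)
        got = model_clustered(r, 5.0, 39.0, 0.5, 1e-4)
        want = 5.0 * np.exp(-r / 39.0) + 1.0  # g_stoch negligible at these r
        np.testing.assert_allclose(got, want, rtol=0.02)

    def test_quadrature_matches_2d_grid_convolution(self):
        from scipy.signal import fftconvolve

        from smlmq.paircorr import _exp_conv_psf

        xi, sigma = 39.0, 12.0
        L, h = 700.0, 1.0
        ax = np.arange(-L, L + h, h)
        X, Y = np.meshgrid(ax, ax)
        R = np.hypot(X, Y)
        conv = fftconvolve(np.exp(-R / xi),
                           np.exp(-(R**2) / (4 * sigma**2)) / (4 * np.pi * sigma**2),
                           mode="same") * h * h
        c = conv.shape[0] // 2
        r_test = np.array([5.0, 20.0, 39.0, 100.0, 200.0])
        grid_vals = conv[c, c + (r_test / h).astype(int)]
        np.testing.assert_allclose(_exp_conv_psf(r_test, xi, sigma), grid_vals, rtol=0.01)


class TestFitting:
    def _synth_curve(self, A, xi, sigma, rho, noise, seed):
        r = np.arange(5.0, 500.0, 5.0) + 2.5
        g = model_clustered(r, A, xi, sigma, rho) if A > 0 else model_random(r, sigma, rho)
        rng = np.random.default_rng(seed)
        noisy = g * (1 + noise * rng.standard_normal(len(r)))
        return CorrelationCurve(r=r, g=noisy, g_se=noise * g, n_points=10_000,
                                roi_area_um2=4.0, estimator="fft_mask")

    def test_random_fit_recovers_sigma_from_synthetic_curve(self):
        curve = self._synth_curve(0.0, 0.0, 12.0, 2e-4, 0.01, 5)
        fit = fit_random(curve, rho=2e-4, sigma0=20.0)
        assert fit.success
        assert abs(fit.sigma_nm - 12.0) / 12.0 < 0.05

    def test_flat_curve_flagged_unidentifiable(self):
        r = np.arange(5.0, 500.0, 5.0)
        curve = CorrelationCurve(r=r, g=np.ones_like(r), g_se=None, n_points=1000,
                                 roi_area_um2=1.0, estimator="fft_mask")
        assert not fit_random(curve, rho=1e-4).success

    def test_blinking_csr_points_recover_generator_precision(self):
        t = smlmq.simulate_molecules("random", 3200.0, 3200.0, 150.0, seed=21)
        tab = smlmq.simulate_localizations(t, mean_blinks=4.0, precision_sigma_nm=20.0,
                                           frames_total=5000, seed=22)
        curve = autocorrelation_fft(tab, (100, 100, 3100, 3100), 5, 500, 10)
        fit = fit_random(curve, rho="free", sigma0=15.0)
        assert abs(fit.sigma_nm - 20.0) / 20.0 < 0.25

    def test_clustered_fit_recovers_curve_parameters(self):
        errs_xi, errs_a = [], []
        for seed in range(10):
            curve = self._synth_curve(5.0, 39.0, 12.0, 2e-4, 0.01, seed)
            fit = fit_clustered(curve, rho=2e-4, sigma0=15.0)
            errs_xi.append(abs(fit.xi_nm - 39.0) / 39.0)
            errs_a.append(abs(fit.A - 5.0) / 5.0)
        assert np.median(errs_xi) < 0.10
        assert np.median(errs_a) < 0.15

    def test_zero_amplitude_curve_fits_like_random(self):
        curve = self._synth_curve(0.0, 0.0, 12.0, 2e-4, 0.005, 9)
        rfit = fit_random(curve, rho=2e-4, sigma0=15.0)
        cfit = fit_clustered(curve, rho=2e-4, sigma0=15.0)
        assert cfit.A < 0.3
        assert cfit.rss <= rfit.rss * 1.05

    def test_thomas_xi_monotone_in_generator_scale(self):
        # median fitted correlation length over seeds grows with the
        # generator displacement scale
        xis = []
        for s in (10.0, 20.0, 40.0):
            per_seed = []
            for seed in range(3):
                t = smlmq.simulate_molecules("clustered", 5000.0, 5000.0, 300.0, 30.0,
                                             s, seed=30 + seed)
                tab = smlmq.simulate_localizations(t, mean_blinks=3.0,
                                                   precision_sigma_nm=12.0,
                                                   frames_total=5000, seed=130 + seed)
                curve = autocorrelation_fft(tab, (0, 0, 5000, 5000), 5, 500, 5)
                per_seed.append(fit_clustered(curve, rho="free", sigma0=12.0).xi_nm)
            xis.append(np.median(per_seed))
        assert xis[0] < xis[1] < xis[2]


class TestModelSelection:
    def test_identical_residuals_choose_random_by_parsimony(self):
        from smlmq.paircorr import ClusterFitResult, RandomFitResult

        r = RandomFitResult(12.0, 1e-4, 5.0, True, 2)
        c = ClusterFitResult(0.0, 39.0, 12.0, 1e-4, 5.0, True, 4)
        sel = select_model(r, c, 50)
        assert sel.model == "random"
        assert sel.p_value == 1.0

    def test_strong_cluster_curve_selects_clustered(self):
        curve = TestFitting()._synth_curve(5.0, 39.0, 12.0, 2e-4, 0.01, 3)
        rfit = fit_random(curve, rho=2e-4, sigma0=15.0)
        cfit = fit_clustered(curve, rho=2e-4, sigma0=15.0)
        sel = select_model(rfit, cfit, len(curve.r))
        assert sel.model == "clustered"
        assert sel.p_value < 1e-6


class TestDecomposition:
    def test_protein_curve_tends_to_one_at_large_r(self):
        t = smlmq.simulate_molecules("random", 3200.0, 3200.0, 150.0, seed=41)
        tab = smlmq.simulate_localizations(t, mean_blinks=4.0, precision_sigma_nm=20.0,
                                           frames_total=5000, seed=42)
        curve = autocorrelation_fft(tab, (100, 100, 3100, 3100), 5, 500, 10)
        fit = fit_random(curve, rho="free", sigma0=20.0)
        dec = decompose_curve(curve, fit.sigma_nm, fit.rho_per_nm2)
        tail = dec[dec["r_nm"] > 300]["g_protein"]
        assert abs(tail.mean() - 1.0) < 0.05
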