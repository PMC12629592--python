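"""Sub-pixel end/molecule localization, binding-region distributions,
two-colour distances, and precision deconvolution."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import optimize, special, stats

from tiptrack.localization import (
    FWHM_FACTOR,
    EndFit,
    LineProfile,
    PeakFit,
    deconvolve_precision,
    estimate_psf_sigma,
    fit_end_profile,
    fit_molecule_peak,
    fit_position_distribution,
    localize_event,
    population_precision,
    two_color_distance,
)
from tiptrack.simulate import SimulationConfig, render_bead_stack


def erfc_edge(x, bg, amp, xe, sigma):
    return bg + 0.5 * amp * special.erfc((x - xe) / (np.sqrt(2) * sigma))


class TestEndFit:
    def test_noiseless_edge_recovered_to_subnanometer(self):
        """Noiseless erfc edge at x_e=0, sigma=120 nm, 160 nm sampling."""
        x = np.arange(-1600.0, 1760.0, 160.0)
        y = erfc_edge(x, 10.0, 60.0, 0.0, 120.0)
        fit = fit_end_profile(LineProfile(x, y), psf_guess=120.0)
        assert fit.ok
        assert abs(fit.edge_position) < 0.1
        assert fit.edge_sigma == pytest.approx(120.0, abs=0.1)

    def test_mirrored_orientation(self):
        x = np.arange(-1600.0, 1760.0, 160.0)
        y = erfc_edge(-x, 10.0, 60.0, -250.0, 120.0)  # end toward -x at +250
        fit = fit_end_profile(LineProfile(x, y), 120.0, orientation=-1)
        assert fit.edge_position == pytest.approx(250.0, abs=0.1)

    def test_noisy_edge_bias_and_grid_oracle(self):
        """Shot noise at paper-like SNR: mean bias < 2 nm over 200
        replicates, and curve_fit agrees with a brute-force grid search
        over x_e at 0.1 nm steps."""
        rng = np.random.default_rng(21)
        x = np.arange(0.0, 3200.0, 160.0)
        # a densely labeled microtubule is bright: this SNR puts the
        # per-frame edge scatter in the few-nm range that averages to the
        # ~1.3 nm per-event precision of the real instrument
        xe_true, bg, amp, sig = 1512.3, 50.0, 1000.0, 120.0
        estimates = []
        for _ in range(200):
            y = rng.poisson(erfc_edge(x, bg, amp, xe_true, sig)).astype(float)
            fit = fit_end_profile(LineProfile(x, y), 120.0)
            if fit.ok:
                estimates.append(fit.edge_position)
        assert len(estimates) > 190
        assert 1.0 < np.std(estimates) < 15.0  # per-frame scatter, nm
        assert abs(np.mean(estimates) - xe_true) < 2.0

        # grid-search oracle on one replicate: for each candidate x_e the
        # model is linear in (bg, amp), solved exactly; sigma held at truth
        y = rng.poisson(erfc_edge(x, bg, amp, xe_true, sig)).astype(float)
        grid = np.arange(xe_true - 200.0, xe_true + 200.0, 0.1)
        sse = np.empty(grid.size)
        for i, xe in enumerate(grid):
            basis = np.column_stack(
                [np.ones_like(x), 0.5 * special.erfc((x - xe) / (np.sqrt(2) * sig))]
            )
            coef, res, *_ = np.linalg.lstsq(basis, y, rcond=None)
            sse[i] = np.sum((basis @ coef - y) ** 2)
        xe_grid = grid[np.argmin(sse)]
        fit = fit_end_profile(LineProfile(x, y), 120.0)
        assert abs(fit.edge_position - xe_grid) < 5.0

    def test_unconverged_fit_is_flagged(self):
        rng = np.random.default_rng(22)
        x = np.arange(0.0, 1600.0, 160.0)
        y = rng.random(x.size)  # pure noise, no edge
        fit = fit_end_profile(LineProfile(x, y), 120.0)
        # either flagged outright or pinned at the span boundary
        assert (not fit.ok) or (x[0] < fit.edge_position < x[-1])


class TestPeakFit:
    def test_noiseless_gaussian_center(self):
        x = np.arange(0.0, 3200.0, 160.0)
        y = 5.0 + 80.0 * np.exp(-0.5 * ((x - 1000.0) / 130.0) ** 2)
        fit = fit_molecule_peak(LineProfile(x, y))
        assert fit.ok
        assert fit.center == pytest.approx(1000.0, abs=0.1)

    def test_flat_profile_flagged(self):
        x = np.arange(0.0, 1600.0, 160.0)
        fit = fit_molecule_peak(LineProfile(x, np.full(x.size, 7.0)))
        assert fit.flag == "no_peak"

    def test_two_comparable_maxima_flagged(self):
        x = np.arange(0.0, 6400.0, 160.0)
        y = (
            5.0
            + 80.0 * np.exp(-0.5 * ((x - 1500.0) / 130.0) ** 2)
            + 75.0 * np.exp(-0.5 * ((x - 4500.0) / 130.0) ** 2)
        )
        fit = fit_molecule_peak(LineProfile(x, y))
        assert fit.flag == "ambiguous_peak"

    def test_noisy_center_scatter_order_of_magnitude(self):
        """Poisson noise at single-molecule SNR: per-frame center scatter
        in the tens of nm, the regime of the population precision."""
        rng = np.random.default_rng(23)
        x = np.arange(0.0, 3200.0, 160.0)
        centers = []
        for _ in range(300):
            y = rng.poisson(
                20.0 + 120.0 * np.exp(-0.5 * ((x - 1600.0) / 120.0) ** 2)
            ).astype(float)
            fit = fit_molecule_peak(LineProfile(x, y))
            if fit.ok:
                centers.append(fit.center)
        scatter = np.std(centers)
        assert 5.0 < scatter < 60.0


class TestLocalizeEvent:
    def _fits(self, peaks, edges, flags=None):
        flags = flags or [None] * len(peaks)
        e = [EndFit(ed, 120.0, 50.0, 5.0, 0.0) for ed in edges]
        p = [PeakFit(pk, 120.0, 50.0, 5.0, 0.0, flag=f) for pk, f in zip(peaks, flags)]
        return e, p

    def test_mean_of_frame_positions(self):
        e, p = self._fits([-60.0, -70.0], [0.0, 0.0])
        ev = localize_event(1, e, p)
        assert ev.position == pytest.approx(-65.0)
        assert ev.n_frames == 2

    def test_single_valid_frame_rejected(self):
        e, p = self._fits([-60.0, -70.0], [0.0, 0.0], flags=[None, "no_peak"])
        assert localize_event(1, e, p) is None

    def test_moving_end_lab_frame_molecule(self):
        """A lab-frame-stationary molecule against a growing end: the
        relative position decreases at the growth rate."""
        growth_nm_per_frame = 5.0
        edges = [100.0 + growth_nm_per_frame * i for i in range(5)]
        peaks = [120.0] * 5
        e, p = self._fits(peaks, edges)
        ev = localize_event(2, e, p)
        steps = np.diff(ev.frame_positions)
        assert np.allclose(steps, -growth_nm_per_frame)

    @settings(max_examples=50, deadline=None)
    @given(shift=st.floats(-1e4, 1e4, allow_nan=False))
    def test_translation_invariance(self, shift):
        """Adding a constant to both peak and edge leaves the event
        position unchanged."""
        e, p = self._fits([-60.0, -70.0], [10.0, 20.0])
        e2, p2 = self._fits([-60.0 + shift, -70.0 + shift], [10.0 + shift, 20.0 + shift])
        a = localize_event(1, e, p).position
        b = localize_event(1, e2, p2).position
        assert a == pytest.approx(b, abs=1e-6)


class TestPositionDistribution:
    def test_gaussian_fwhm_identity_and_recovery(self, rng):
        """FWHM = 2 sqrt(2 ln 2) sigma exactly; samples at sigma=68.8 nm
        recover the 162 nm binding-region width within sampling error."""
        positions = rng.normal(0.0, 68.8, size=2000)
        dist = fit_position_distribution(positions, "gaussian", bin_width=20.0)
        assert dist.fwhm == pytest.approx(FWHM_FACTOR * dist.params["sigma"], rel=1e-12)
        se_fwhm = FWHM_FACTOR * 68.8 / np.sqrt(2 * 2000)
        assert abs(dist.fwhm - 162.0) < 4 * se_fwhm
        lo, hi = dist.region_bounds
        assert hi - lo == pytest.approx(dist.fwhm)

    def test_emg_fwhm_matches_halfmax_root_oracle(self, rng):
        """EMG FWHM agrees with an independent root-finding oracle on the
        fitted density to < 0.1 nm."""
        samples = rng.normal(-30.0, 40.0, 500) + rng.exponential(60.0, 500)
        dist = fit_position_distribution(samples, "emg", bin_width=20.0)
        mu, sig, lam = dist.params["mu"], dist.params["sigma"], dist.params["lambda"]

        def pdf(x):
            return stats.exponnorm.pdf(x, K=1 / (lam * sig), loc=mu, scale=sig)

        mode = optimize.minimize_scalar(
            lambda x: -pdf(x), bounds=(mu - 300, mu + 300), method="bounded",
            options={"xatol": 1e-6},
        ).x
        half = pdf(mode) / 2
        left = optimize.brentq(lambda x: pdf(x) - half, mode - 2000, mode, xtol=1e-8)
        right = optimize.brentq(lambda x: pdf(x) - half, mode, mode + 2000, xtol=1e-8)
        assert dist.fwhm == pytest.approx(right - left, abs=0.1)

    def test_too_few_events_rejected(self, rng):
        with pytest.raises(ValueError):
            fit_position_distribution(rng.normal(0, 50, 10))


class TestTwoColor:
    def test_identical_positions_give_zero(self):
        peaks = [np.array([100.0, 110.0])] * 10
        res = two_color_distance(peaks, peaks)
        assert np.all(res.event_distances == 0.0)

    def test_offset_recovered_as_mode(self, rng):
        """62 events at a true -65 nm separation (SD 40 nm) with 18 nm
        per-channel localization noise peak near -65 nm."""
        sep = rng.normal(-65.0, 40.0, 62)
        pa = [rng.normal(0.0, 18.0, 6) for _ in range(62)]
        pb = [pa[i] + sep[i] + rng.normal(0.0, 18.0, 6) for i in range(62)]
        res = two_color_distance(pa, pb)
        assert abs(res.mode - (-65.0)) < res.bin_width

    def test_fraction_positive_matches_normal_cdf(self, rng):
        """On a -65 nm Gaussian with SD 40, P(d > 0) = Phi(-65/40) ~ 5%."""
        d = rng.normal(-65.0, 40.0, 20_000)
        res = two_color_distance([np.zeros(1)] * d.size, [np.array([v]) for v in d])
        p = stats.norm.cdf(-65.0 / 40.0)
        se = np.sqrt(p * (1 - p) / d.size)
        assert abs(res.fraction_positive - (1 - stats.norm.cdf(65.0 / 40.0))) < 3 * se
        assert res.fraction_positive == pytest.approx(p, abs=3 * se)


class TestPSFAndPrecision:
    def test_noiseless_beads_recover_configured_width(self, config):
        stack, truth = render_bead_stack(config, n_beads=12, noise=False, seed=31)
        est = estimate_psf_sigma(stack)
        for role, sig in truth["psf_sigma"].items():
            assert est[role] == pytest.approx(sig, abs=0.5)

    def test_two_channels_two_widths(self):
        cfg = SimulationConfig(psf_sigma={"microtubule": 140.0, "molecule": 110.0})
        stack, _ = render_bead_stack(cfg, n_beads=12, noise=False, seed=32)
        est = estimate_psf_sigma(stack)
        assert est["microtubule"] == pytest.approx(140.0, abs=1.0)
        assert est["molecule"] == pytest.approx(110.0, abs=1.0)

    def test_width_scatter_shrinks_with_photons(self, config):
        """CRLB-style scaling: per-bead width scatter decreases with
        brightness roughly as 1/sqrt(photons)."""
        def scatter(brightness, seed):
            sigmas = []
            for s in range(seed, seed + 6):
                stack, _ = render_bead_stack(
                    config, n_beads=10, brightness=brightness, seed=s
                )
                est = estimate_psf_sigma(stack)
                sigmas.append(est["molecule"])
            return np.std(sigmas)

        lo = scatter(2_000.0, 40)
        hi = scatter(200_000.0, 60)
        assert hi < lo

    def test_deconvolution_inverse_of_quadrature(self):
        sigma_i = np.hypot(18.0, 120.0)  # 121.34
        assert sigma_i == pytest.approx(121.34, abs=0.005)
        assert deconvolve_precision(sigma_i, 120.0) == pytest.approx(18.0, rel=1e-12)
        assert deconvolve_precision(120.0, 120.0) == 0.0

    def test_noise_dominated_record_raises(self):
        with pytest.raises(ValueError):
            deconvolve_precision(100.0, 120.0)

    def test_population_precision_from_observed_widths(self, rng):
        """Per-event observed widths built from true errors ~N(18, 3) in
        quadrature with a 120 nm PSF: the fitted population SD recovers
        the error spread and tallies noise-dominated records."""
        true_err = rng.normal(18.0, 3.0, 400).clip(min=0.1)
        sigma_i = np.hypot(true_err, 120.0)
        sigma_i[:5] = 119.0  # noise-dominated
        precision, n_excluded = population_precision(sigma_i, 120.0)
        assert n_excluded == 5
        assert precision == pytest.approx(3.0, abs=1.5)
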