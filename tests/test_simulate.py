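"""The synthetic generator must have the statistical structure the
estimators assume: gamma lifetimes, Poisson arrivals, exponential
dwells, Brownian lattice motion, photon-conserving rendering, and
bit-identical output under a fixed seed."""

import numpy as np
import pytest

from tiptrack.simulate import (
    BindingTruth,
    MicrotubuleTruth,
    SimulationConfig,
    TruthBundle,
    render_bead_stack,
    render_movie,
    simulate_binding,
    simulate_dwell_samples,
    simulate_dynamics,
    simulate_trajectories,
)


class TestSimulateDynamics:
    def test_gamma_shape_one_is_exponential(self, config):
        mts = simulate_dynamics(
            config, lifetime_shape=1.0, lifetime_scale=300.0,
            n_microtubules=4000, rng=np.random.default_rng(0),
        )
        lifetimes = np.array([m.lifetime for m in mts])
        # exponential mean 300 s, SEM 300/sqrt(n)
        assert abs(lifetimes.mean() - 300.0) < 3 * 300.0 / np.sqrt(4000)

    def test_control_lifetime_world(self, config):
        """shape 3, scale 107.8 matches the ~323 s control mean at n=443."""
        mts = simulate_dynamics(
            config, lifetime_shape=3.0, lifetime_scale=107.8,
            n_microtubules=443, rng=np.random.default_rng(1),
        )
        lifetimes = np.array([m.lifetime for m in mts])
        sem = 107.8 * np.sqrt(3.0) / np.sqrt(443)
        assert abs(lifetimes.mean() - 323.4) < 3 * sem

    def test_linear_growth(self):
        mt = MicrotubuleTruth(
            id=0, anchor_row=0.0, anchor_col=0.0, orientation=1,
            growth_rate=0.8, lifetime=1e9, censored=True, seed_length=0.0,
        )
        assert mt.end_col(60.0) == pytest.approx(800.0)

    def test_censoring_flagged_not_dropped(self, config):
        mts = simulate_dynamics(
            config, lifetime_shape=3.0, lifetime_scale=1e4,
            n_microtubules=20, rng=np.random.default_rng(2),
        )
        assert len(mts) == 20
        assert all(m.censored for m in mts)  # movie is only 20 s

    def test_invalid_parameters(self, config):
        with pytest.raises(ValueError):
            simulate_dynamics(config, lifetime_shape=0.0)
        with pytest.raises(ValueError):
            simulate_dynamics(config, lifetime_scale=-1.0)


def _immortal_microtubules(n, length_nm=4000.0):
    return [
        MicrotubuleTruth(
            id=i, anchor_row=1000.0, anchor_col=0.0, orientation=1,
            growth_rate=0.0, lifetime=1e9, censored=True,
            seed_length=length_nm,
        )
        for i in range(n)
    ]


class TestSimulateBinding:
    def test_end_arrival_rate_matches_poisson_mean(self):
        """kon_end=22.6e-6, C=10 nM, 260 sites, T=100 s -> 5.876 end
        arrivals per microtubule on average (Poisson-mean arithmetic)."""
        cfg = SimulationConfig(n_frames=1000)  # 100 s movie
        n_mt = 200
        mts = _immortal_microtubules(n_mt)
        events = simulate_binding(
            cfg, mts, kon_end=22.6e-6, kon_lattice=0.0, concentration=10.0,
            rng=np.random.default_rng(3),
        )
        expected = 22.6e-6 * 10.0 * 260 * 100.0  # per microtubule
        total = sum(1 for e in events if e.site_class == "end")
        se = np.sqrt(expected * n_mt)
        assert abs(total - expected * n_mt) < 3 * se

    def test_zero_on_rates_give_no_events(self, config):
        events = simulate_binding(
            config, _immortal_microtubules(5), kon_end=0.0, kon_lattice=0.0,
            rng=np.random.default_rng(4),
        )
        assert events == []

    def test_lattice_steps_have_brownian_variance(self):
        """Per-frame lattice step SD = sqrt(2 D dt) ~ 67.8 nm at the
        measured D and 0.1 s frames."""
        cfg = SimulationConfig(n_frames=600)
        mts = _immortal_microtubules(30, length_nm=20_000.0)
        events = simulate_binding(
            cfg, mts, kon_end=0.0, kon_lattice=50e-6, tau_lattice=3.0,
            D=0.023, concentration=10.0, rng=np.random.default_rng(5),
        )
        steps = np.concatenate(
            [
                np.diff(e.axial_position_trace[:, 1])
                for e in events
                if e.axial_position_trace.shape[0] >= 2
            ]
        )
        assert steps.size > 3000
        expected_sd = np.sqrt(2 * 0.023 * 0.1) * 1e3  # 67.8 nm
        se = expected_sd / np.sqrt(2 * steps.size)
        assert abs(steps.std() - expected_sd) < 3 * se

    def test_end_molecules_track_the_moving_end(self):
        cfg = SimulationConfig(n_frames=300)
        mts = [
            MicrotubuleTruth(
                id=0, anchor_row=1000.0, anchor_col=0.0, orientation=1,
                growth_rate=2.0, lifetime=1e9, censored=True,
                seed_length=2000.0,
            )
        ]
        events = simulate_binding(
            cfg, mts, kon_end=200e-6, kon_lattice=0.0, tau_end=2.0,
            concentration=10.0, rng=np.random.default_rng(6),
        )
        multi = [e for e in events if e.axial_position_trace.shape[0] >= 3]
        assert multi
        for e in multi:
            rel = e.axial_position_trace[:, 1]
            assert np.allclose(rel, rel[0])  # stationary relative to the end
            assert -160.0 <= rel[0] <= 0.0


class TestDwellSamples:
    def test_untruncated_mean(self):
        d = simulate_dwell_samples(1.0, 20_000, seed=7)
        assert abs(d.mean() - 1.0) < 3 / np.sqrt(20_000)

    def test_truncated_mean_is_floor_plus_tau(self):
        """Memorylessness: conditioning on exceeding 0.2 s shifts the
        observed mean of a 0.55 s exponential to 0.75 s."""
        d = simulate_dwell_samples(0.55, 50_000, min_dwell=0.2, seed=8)
        assert d.min() >= 0.2
        assert abs(d.mean() - 0.75) < 3 * 0.55 / np.sqrt(50_000)

    def test_empty_and_invalid(self):
        assert simulate_dwell_samples(1.0, 0).size == 0
        with pytest.raises(ValueError):
            simulate_dwell_samples(0.0, 10)


class TestTrajectories:
    def test_zero_diffusion_is_static(self):
        trajs = simulate_trajectories(0.0, 5, 10, seed=9)
        for tr in trajs:
            assert np.all(tr.positions == tr.positions[0])

    def test_track_length_floor(self):
        with pytest.raises(ValueError):
            simulate_trajectories(0.01, 5, 3)
        with pytest.raises(ValueError):
            simulate_trajectories(0.01, 5, (2, 10))

    def test_increment_variance(self):
        trajs = simulate_trajectories(0.023, 200, 51, dt=0.1, seed=10)
        steps = np.concatenate([np.diff(tr.positions) for tr in trajs])
        d_hat = steps.var() / (2 * 0.1)
        se = 0.023 * np.sqrt(2.0 / steps.size)
        assert abs(d_hat - 0.023) < 3 * se


class TestRenderMovie:
    def _one_emitter_bundle(self, cfg, col_nm, brightness=500.0):
        mt = MicrotubuleTruth(
            id=0, anchor_row=16 * cfg.pixel_size, anchor_col=0.0,
            orientation=1, growth_rate=0.0, lifetime=1e9, censored=True,
            seed_length=col_nm + 160.0,
        )
        b = BindingTruth(
            molecule_id=0, microtubule_id=0, channel="molecule",
            site_class="end", arrival_time=0.0, dwell=0.5,
            axial_position_trace=np.array([[0.0, col_nm - mt.end_col(0.0)]]),
            intensity=brightness,
        )
        return TruthBundle(cfg, [mt], [b])

    def test_noiseless_emitter_centroid_matches_truth(self):
        cfg = SimulationConfig(n_frames=1, background=0.0)
        col_true = 52.3 * cfg.pixel_size / cfg.pixel_size  # sub-pixel in px
        col_nm = 52.3 * cfg.pixel_size
        bundle = self._one_emitter_bundle(cfg, col_nm)
        movie = render_movie(cfg, bundle, noise=False)
        frame = movie.channel("molecule")[0]
        cols = np.arange(frame.shape[1])
        centroid_px = (frame.sum(axis=0) * cols).sum() / frame.sum()
        assert abs(centroid_px * cfg.pixel_size - col_nm) < 0.1

    def test_photon_conservation(self):
        """Noiseless molecule-channel frame sums to background * pixels
        plus the total emitter brightness."""
        cfg = SimulationConfig(n_frames=1, background=7.0)
        bundle = self._one_emitter_bundle(cfg, 52.3 * cfg.pixel_size, 321.0)
        movie = render_movie(cfg, bundle, noise=False)
        frame = movie.channel("molecule")[0]
        expected = 7.0 * frame.size + 321.0
        assert frame.sum() == pytest.approx(expected, rel=1e-4)

    def test_noiseless_end_edge_at_truth(self):
        """The rendered axial profile crosses half-max at the true end."""
        cfg = SimulationConfig(n_frames=1, background=0.0)
        mt = MicrotubuleTruth(
            id=0, anchor_row=16 * cfg.pixel_size, anchor_col=0.0,
            orientation=1, growth_rate=0.0, lifetime=1e9, censored=True,
            seed_length=60.25 * cfg.pixel_size,
        )
        movie = render_movie(cfg, TruthBundle(cfg, [mt], []), noise=False)
        profile = movie.channel("microtubule")[0].sum(axis=0)
        half = profile.max() / 2.0
        i = np.flatnonzero(np.diff(np.sign(profile - half)))[-1]
        x_half = i + (half - profile[i]) / (profile[i + 1] - profile[i])
        assert abs(x_half * cfg.pixel_size - mt.end_col(0.0)) < 0.05 * cfg.pixel_size

    def test_seeded_determinism_bit_identical(self, config):
        mts = simulate_dynamics(config, n_microtubules=2, rng=np.random.default_rng(11))
        events = simulate_binding(config, mts, rng=np.random.default_rng(12))
        bundle = TruthBundle(config, mts, events)
        a = render_movie(config, bundle, noise=True)
        b = render_movie(config, bundle, noise=True)
        assert np.array_equal(a.pixels, b.pixels)


class TestTruthBundle:
    def test_json_round_trip(self, config, tmp_path):
        mts = simulate_dynamics(config, n_microtubules=3, rng=np.random.default_rng(13))
        events = simulate_binding(config, mts, rng=np.random.default_rng(14))
        bundle = TruthBundle(config, mts, events)
        path = tmp_path / "truth.json"
        bundle.to_json(path)
        back = TruthBundle.from_json(path)
        assert back.config == config
        assert [m.__dict__ for m in back.microtubules] == [m.__dict__ for m in mts]
        assert len(back.bindings) == len(events)
        for x, y in zip(back.bindings, events):
            assert x.site_class == y.site_class
            assert x.dwell == y.dwell
            assert np.array_equal(x.axial_position_trace, y.axial_position_trace)


class TestBeadStack:
    def test_config_invariants(self):
        with pytest.raises(ValueError):
            SimulationConfig(frame_interval=0.04, exposure=0.05)
        with pytest.raises(ValueError):
            SimulationConfig(pixel_size=0.0)

    def test_truth_records_psf(self, config):
        stack, truth = render_bead_stack(config, n_beads=5, noise=False, seed=15)
        assert truth["psf_sigma"] == config.psf_sigma
        assert truth["positions_nm"].shape == (5, 2)
        assert stack.pixels.shape[0] == len(config.channels)
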