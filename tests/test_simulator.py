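import math

import numpy as np
import pandas as pd
import pytest

from smtrack.simulator import (BlinkKinetics, OpticsConfig, in_star_sector,
                               make_grid_movie, make_siemens_movie,
                               render_movie, sample_blink_trace,
                               siemens_star_positions, simulate_blinking,
                               simulate_brownian_movie)


class TestSiemensStar:
    def test_positions_inside_on_sectors(self):
        pos = siemens_star_positions(n_arms=10, grid=128, seed=0, n_emitters=500)
        center = (128 - 1) / 2.0
        assert in_star_sector(pos[:, 0], pos[:, 1], center, 10).all()
        r = np.hypot(pos[:, 0] - center, pos[:, 1] - center)
        assert (r <= 64.0).all()

    def test_rotational_symmetry_chi2(self):
        """The angular distribution is invariant under rotation by 2 pi / n:
        counts per 'on' sector are uniform (chi-square at alpha=0.01)."""
        from scipy.stats import chi2
        n_arms = 10
        pos = siemens_star_positions(n_arms=n_arms, grid=256, seed=3,
                                     n_emitters=5000)
        center = (256 - 1) / 2.0
        phi = np.mod(np.arctan2(pos[:, 1] - center, pos[:, 0] - center),
                     2 * math.pi)
        sector = np.floor(phi / (math.pi / n_arms)).astype(int)
        counts = np.bincount(sector // 2, minlength=n_arms)
        expected = len(pos) / n_arms
        stat = ((counts - expected) ** 2 / expected).sum()
        assert stat < chi2.ppf(0.99, df=n_arms - 1)

    def test_density_doubling_doubles_expected_count(self):
        """Counts are Poisson in the density: doubling the density doubles
        the mean count within 3 sigma over 20 seeds."""
        counts1 = [len(siemens_star_positions(10, 64, density=0.05, seed=s))
                   for s in range(20)]
        counts2 = [len(siemens_star_positions(10, 64, density=0.10, seed=s + 100))
                   for s in range(20)]
        m1, m2 = np.mean(counts1), np.mean(counts2)
        sem = math.sqrt(np.var(counts1) / 20 + 4 * np.var(counts2) / 20)
        assert abs(2 * m1 - m2) < 3 * max(sem, 1.0) + 3 * math.sqrt(m2 / 20)


class TestBlinkKinetics:
    def test_derived_quantities(self):
        kin = BlinkKinetics(k_on=1 / 37.5, k_off=1.0, k_bleach=0.15)
        assert kin.k_deactivate == pytest.approx(1.15)
        assert kin.p_bleach == pytest.approx(0.15 / 1.15)

    def test_k_on_zero_never_activates(self):
        truth = simulate_blinking(np.array([[5.0, 5.0]]),
                                  BlinkKinetics(k_on=0.0), 100, seed=0)
        assert len(truth) == 0

    def test_geometric_and_exponential_identities(self):
        """Mean activations per emitter = 1/p_bleach and mean on-time =
        1/k_deactivate, each within 3 sigma at 4000 emitters."""
        kin = BlinkKinetics.storm_default()  # k_off=1, k_bleach=0.15
        rng = np.random.default_rng(11)
        n_act, durs = [], []
        for _ in range(4000):
            trace = sample_blink_trace(kin, rng)
            n_act.append(len(trace))
            durs.extend(t1 - t0 for t0, t1 in trace)
        n_act = np.asarray(n_act)
        durs = np.asarray(durs)
        exp_act = 1.0 / kin.p_bleach  # 7.667
        assert abs(n_act.mean() - exp_act) < 3 * n_act.std() / math.sqrt(len(n_act))
        exp_on = 1.0 / kin.k_deactivate  # 0.8696
        assert abs(durs.mean() - exp_on) < 3 * durs.std() / math.sqrt(len(durs))

    def test_active_fraction_in_unit_interval(self):
        truth = simulate_blinking(
            np.random.default_rng(0).uniform(0, 64, (50, 2)),
            BlinkKinetics.storm_default(), 50, seed=1)
        assert ((truth["A"] > 0) & (truth["A"] <= 1)).all()
        assert truth["frame"].between(0, 49).all()


class TestRenderMovie:
    def test_single_emitter_photon_conservation(self):
        truth = pd.DataFrame({"frame": [0], "emitter_id": [0],
                              "x": [32.0], "y": [32.0], "A": [1.0]})
        optics = OpticsConfig()
        _, ref = render_movie(truth, optics, (64, 64), 1, seed=0)
        signal = ref[0].sum() - optics.background * 64 * 64
        assert signal == pytest.approx(optics.n_photons, rel=1e-3)

    def test_empty_truth_constant_background(self):
        truth = pd.DataFrame({"frame": [], "emitter_id": [], "x": [], "y": [],
                              "A": []})
        movie, ref = render_movie(truth, OpticsConfig(), (32, 32), 3, seed=0)
        np.testing.assert_allclose(ref, 10.0)

    def test_poisson_mean_converges_to_reference(self):
        """Mean over many noisy frames of a static scene approaches the
        noiseless reference within 3 sigma / sqrt(n) per pixel."""
        n = 100
        truth = pd.DataFrame({
            "frame": np.arange(n), "emitter_id": np.zeros(n, dtype=int),
            "x": np.full(n, 16.0), "y": np.full(n, 16.0), "A": np.ones(n)})
        movie, ref = render_movie(truth, OpticsConfig(n_photons=200), (32, 32),
                                  n, seed=5)
        mean_img = movie.data.mean(axis=0)
        tol = 3 * np.sqrt(ref[0] / n)
        assert (np.abs(mean_img - ref[0]) <= tol).mean() > 0.99

    def test_determinism(self):
        a, _, _ = make_siemens_movie(grid=32, n_frames=3, n_emitters=20, seed=9)
        b, _, _ = make_siemens_movie(grid=32, n_frames=3, n_emitters=20, seed=9)
        np.testing.assert_array_equal(a.data, b.data)

    def test_bad_snr_rejected(self):
        truth = pd.DataFrame({"frame": [0], "emitter_id": [0], "x": [5.0],
                              "y": [5.0], "A": [1.0]})
        with pytest.raises(ValueError):
            render_movie(truth, OpticsConfig(), (16, 16), 1, target_snr=-1)


class TestGridMovie:
    def test_default_ground_truth_count(self):
        _, truth = make_grid_movie(render=False)
        assert len(truth) == 896_000

    def test_small_grid_row_count(self):
        _, truth = make_grid_movie(frame_px=64, n_side=2, n_frames=3,
                                   render=False)
        assert len(truth) == 12

    def test_no_blinking_all_active(self):
        _, truth = make_grid_movie(frame_px=64, n_side=2, n_frames=3,
                                   render=False)
        assert (truth["A"] == 1.0).all()

    def test_noise_redrawn_per_frame(self):
        movie, _ = make_grid_movie(frame_px=64, n_side=2, n_frames=2,
                                   snr=10, seed=0)
        assert not np.array_equal(movie.data[0], movie.data[1])


class TestBrownianMovie:
    def test_zero_diffusion_stationary(self):
        _, tracks = simulate_brownian_movie(0.0, 1e-3, n_particles=5,
                                            n_frames=4, grid=32, seed=0)
        for _, g in tracks.groupby("track_id"):
            assert g["x"].nunique() == 1
            assert g["y"].nunique() == 1

    def test_step_variance_matches_theory(self):
        """Per-axis step variance = 2 D t_a (in px^2), chi-square bounds."""
        from scipy.stats import chi2
        d_um2_s, t_a = 5.0, 1e-3
        _, tracks = simulate_brownian_movie(d_um2_s, t_a, n_particles=100,
                                            n_frames=100, grid=4096, seed=4,
                                            render=False)
        steps = []
        for _, g in tracks.groupby("track_id"):
            g = g.sort_values("frame")
            steps.extend(np.diff(g["x"]))
            steps.extend(np.diff(g["y"]))
        steps = np.asarray(steps)
        px_um = 0.1
        expected = 2 * d_um2_s * t_a / px_um ** 2
        n = len(steps)
        stat = (steps ** 2).sum() / expected
        assert chi2.ppf(0.0015, n) < stat < chi2.ppf(0.9985, n)  # ~3 sigma

    def test_determinism(self):
        a, ta = simulate_brownian_movie(2.0, 1e-3, n_particles=3, n_frames=3,
                                        grid=32, seed=7)
        b, tb = simulate_brownian_movie(2.0, 1e-3, n_particles=3, n_frames=3,
                                        grid=32, seed=7)
        np.testing.assert_array_equal(a.data, b.data)
        pd.testing.assert_frame_equal(ta, tb)

    def test_positions_stay_in_field(self):
        _, tracks = simulate_brownian_movie(50.0, 1e-2, n_particles=10,
                                            n_frames=50, grid=32, seed=1)
        assert tracks["x"].between(0, 31).all()
        assert tracks["y"].between(0, 31).all()
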