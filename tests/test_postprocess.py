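import math

import numpy as np
import pandas as pd
import pytest

from smtrack.postprocess import (compute_displacements, discard_cluster_tracks,
                                 estimate_diffusion, filter_localizations,
                                 render_super_resolution)

from conftest import make_locs


class TestFilterLocalizations:
    def _locs(self, sbr, sigma):
        return make_locs(np.zeros(len(sbr), dtype=int),
                         np.arange(len(sbr), dtype=float),
                         np.zeros(len(sbr)), sbr=sbr, sigma_x=sigma)

    def test_sbr_cutoff(self):
        out = filter_localizations(self._locs([0.5, 0.9], [1.42, 1.42]),
                                   0.8, 1.42, 0.4)
        assert len(out) == 1
        assert out.sbr.iloc[0] == 0.9

    def test_sigma_window(self):
        out = filter_localizations(self._locs([1.0, 1.0, 1.0],
                                              [0.9, 1.42, 1.9]),
                                   0.8, 1.42, 0.4)
        # window is 1.02..1.82: only 1.42 survives
        assert out.sigma_x.tolist() == [1.42]

    def test_boundary_inclusive_on_sigma(self):
        out = filter_localizations(self._locs([1.0, 1.0], [1.0, 2.0]),
                                   0.8, 1.5, 0.5)
        assert len(out) == 2

    def test_wide_open_filter_is_identity(self):
        locs = self._locs([0.1, 5.0], [0.5, 3.0])
        out = filter_localizations(locs, 0.0, 1.42, math.inf)
        pd.testing.assert_frame_equal(out, locs)


class TestDiscardClusterTracks:
    def _tracks(self, lengths):
        rows = []
        li = 0
        for tid, n in enumerate(lengths):
            for f in range(n):
                rows.append((tid, f, 0.0, 0.0, li))
                li += 1
        return pd.DataFrame(rows, columns=["track_id", "frame", "x", "y",
                                           "loc_index"])

    def test_long_track_removed(self):
        tracks = self._tracks([30])
        locs = make_locs(range(30), np.zeros(30), np.zeros(30))
        out = discard_cluster_tracks(locs, tracks, 25)
        assert len(out) == 0

    def test_exactly_threshold_kept(self):
        tracks = self._tracks([25])
        locs = make_locs(range(25), np.zeros(25), np.zeros(25))
        out = discard_cluster_tracks(locs, tracks, 25)
        assert len(out) == 25

    def test_no_tracks_identity(self):
        locs = make_locs([0, 1], [1.0, 2.0], [3.0, 4.0])
        out = discard_cluster_tracks(locs, self._tracks([]), 25)
        assert len(out) == 2

    def test_untracked_localizations_kept(self):
        tracks = self._tracks([30])
        locs = make_locs(range(31), np.zeros(31), np.zeros(31))
        out = discard_cluster_tracks(locs, tracks, 25)
        assert len(out) == 1


class TestRenderSuperResolution:
    def test_counts_single_pixel(self):
        locs = make_locs([0], [2.0], [3.0])
        img = render_super_resolution(locs, out_pixel_nm=100,
                                      pixel_size_nm=100, field_nm=1000)
        assert img.sum() == 1.0
        assert img[3, 2] == 1.0

    def test_weighted_unit_integral(self):
        locs = make_locs([0], [5.0], [5.0],
                         precision_x=[10.0], precision_y=[10.0])
        img = render_super_resolution(locs, out_pixel_nm=10.0,
                                      mode="precision_weighted",
                                      pixel_size_nm=100, field_nm=1000)
        assert img.sum() == pytest.approx(1.0, abs=1e-3)

    def test_additivity(self):
        one = make_locs([0], [5.0], [5.0], precision_x=[15.0], precision_y=[15.0])
        two = pd.concat([one, one], ignore_index=True)
        img1 = render_super_resolution(one, 10.0, "precision_weighted",
                                       pixel_size_nm=100, field_nm=1000)
        img2 = render_super_resolution(two, 10.0, "precision_weighted",
                                       pixel_size_nm=100, field_nm=1000)
        np.testing.assert_allclose(img2, 2 * img1)

    def test_weighted_requires_precision(self):
        with pytest.raises(ValueError, match="precision"):
            render_super_resolution(make_locs([0], [1.0], [1.0]), 10.0,
                                    "precision_weighted", field_nm=500)


class TestComputeDisplacements:
    def _track(self, xs, frames=None):
        n = len(xs)
        frames = frames if frames is not None else range(n)
        return pd.DataFrame({"track_id": [0] * n, "frame": list(frames),
                             "x": xs, "y": [0.0] * n})

    def test_stationary_track_zero(self):
        disp = compute_displacements(self._track([5.0, 5.0, 5.0]), max_lag=2)
        assert (disp[1] == 0).all()
        assert (disp[2] == 0).all()

    def test_hand_enumeration_along_x(self):
        disp = compute_displacements(self._track([0.0, 1.0, 2.0, 3.0]),
                                     max_lag=3)
        # x components interleave with zero y components
        assert sorted(disp[1][disp[1] != 0]) == [1.0, 1.0, 1.0]
        assert sorted(disp[2][disp[2] != 0]) == [2.0, 2.0]
        assert sorted(disp[3][disp[3] != 0]) == [3.0]

    def test_sample_counts(self):
        n = 12
        disp = compute_displacements(self._track(list(np.arange(n) * 0.5)),
                                     max_lag=4)
        for k in range(1, 5):
            assert len(disp[k]) == 2 * (n - k)  # both axes pooled

    def test_gap_bridged_interval_excluded(self):
        track = self._track([0.0, 1.0, 3.0], frames=[0, 1, 3])
        disp = compute_displacements(track, max_lag=2)
        assert len(disp[1]) == 2      # only the 0->1 step
        assert len(disp[2]) == 0      # 1->3 spans a bridged gap


class TestEstimateDiffusion:
    def test_exact_line_recovered(self):
        d_true, eps_true, t_a = 10.0, 0.001, 1.05e-3
        px_um = 0.1
        disp = {}
        for k in range(1, 6):
            var_um2 = 2 * d_true * k * t_a + eps_true
            mag_px = math.sqrt(var_um2) / px_um
            disp[k] = np.array([mag_px, -mag_px] * 50)
        fit = estimate_diffusion(disp, t_a, pixel_size_nm=100)
        assert fit.diffusion_um2_s == pytest.approx(d_true, rel=1e-9)
        assert fit.epsilon_um2 == pytest.approx(eps_true, rel=1e-6)

    def test_all_zero_displacements(self):
        disp = {k: np.zeros(100) for k in range(1, 6)}
        fit = estimate_diffusion(disp, 1e-3, pixel_size_nm=100)
        assert fit.diffusion_um2_s == 0.0
        assert fit.epsilon_um2 == 0.0

    def test_too_few_lags_rejected(self):
        with pytest.raises(ValueError, match="lags"):
            estimate_diffusion({1: np.zeros(100)}, 1e-3, 100)

    def test_invariance_under_translation_and_rotation(self, rng):
        n = 200
        steps = rng.normal(0, 1.2, (n, 2))
        pos = np.cumsum(steps, axis=0)
        base = pd.DataFrame({"track_id": 0, "frame": np.arange(n),
                             "x": pos[:, 0], "y": pos[:, 1]})
        rotated = base.copy()
        rotated["x"], rotated["y"] = -base["y"] + 40.0, base["x"] + 7.0
        f1 = estimate_diffusion(compute_displacements(base), 1e-3, 100)
        f2 = estimate_diffusion(compute_displacements(rotated), 1e-3, 100)
        assert f1.diffusion_um2_s == pytest.approx(f2.diffusion_um2_s)

    def test_estimate_scales_linearly_with_d(self):
        """D-hat tracks the simulator's D over a decade (true tracks)."""
        from smtrack.simulator import simulate_brownian_movie
        t_a = 1.05e-3
        estimates = []
        for i, d in enumerate((1.0, 5.0, 10.0)):
            _, tracks = simulate_brownian_movie(d, t_a, n_particles=60,
                                                n_frames=120, grid=2048,
                                                seed=20 + i, render=False)
            fit = estimate_diffusion(compute_displacements(tracks), t_a,
                                     pixel_size_nm=100)
            estimates.append(fit.diffusion_um2_s)
        for d, est in zip((1.0, 5.0, 10.0), estimates):
            assert est == pytest.approx(d, rel=0.10)

    def test_histogram_mode_agrees_with_mle(self, rng):
        disp = {k: rng.normal(0, math.sqrt(k), 20000) for k in range(1, 6)}
        f1 = estimate_diffusion(disp, 1e-3, 100, variance_mode="mle")
        f2 = estimate_diffusion(disp, 1e-3, 100, variance_mode="histogram")
        assert f2.diffusion_um2_s == pytest.approx(f1.diffusion_um2_s, rel=0.05)
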