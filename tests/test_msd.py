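"""MSD computation, filtering rules and diffusion-model fits."""

import numpy as np
import pandas as pd
import pytest

from memclust import (DiffusionStateModel, FilterRules, MSDCurve,
                      SimulationConfig, TrackSet, compute_msd, filter_tracks,
                      fit_brownian, fit_confined, simulate_confined_track,
                      simulate_tracks)
from memclust.msd import EmptyTrackSetError, _corral_msd


def _tracks_from_arrays(arrays, dt=0.01):
    rows = []
    for tid, (frames, xy) in enumerate(arrays):
        rows.append(pd.DataFrame({"track_id": tid, "frame": frames,
                                  "x_um": xy[:, 0], "y_um": xy[:, 1]}))
    return TrackSet(data=pd.concat(rows, ignore_index=True), dt=dt)


def brute_force_msd(tracks, max_lag):
    """Naive double loop over all displacement pairs, no gap spanning."""
    sums = np.zeros(max_lag)
    counts = np.zeros(max_lag, dtype=int)
    for _, _, xy in tracks.contiguous_segments():
        m = len(xy)
        for n in range(1, min(m, max_lag + 1)):
            for i in range(m - n):
                sums[n - 1] += ((xy[i + n] - xy[i]) ** 2).sum()
                counts[n - 1] += 1
    mask = counts > 0
    return sums[mask] / counts[mask], counts[mask]


class TestFilterTracks:
    def test_six_frame_track_removed(self):
        frames = np.arange(6)
        xy = np.zeros((6, 2))
        tr = _tracks_from_arrays([(frames, xy), (np.arange(7), np.zeros((7, 2)))])
        out, rep = filter_tracks(tr, FilterRules())
        assert out.n_tracks == 1
        assert rep.n_removed_short == 1

    def test_split_on_jump_above_five_pixels(self):
        xy = np.zeros((16, 2))
        xy[8:, 0] = 5.1 * 0.16   # one 5.1-pixel jump mid-track
        tr = _tracks_from_arrays([(np.arange(16), xy)])
        out, rep = filter_tracks(tr, FilterRules())
        assert rep.n_split_jump == 1
        assert out.n_tracks == 2

    def test_jump_at_exactly_five_pixels_kept(self):
        xy = np.zeros((16, 2))
        xy[8:, 0] = 5.0 * 0.16
        _, rep = filter_tracks(_tracks_from_arrays([(np.arange(16), xy)]))
        assert rep.n_split_jump == 0

    def test_two_frame_gap_splits_one_frame_gap_kept(self):
        frames = np.concatenate([np.arange(8), np.arange(10, 18)])
        tr = _tracks_from_arrays([(frames, np.zeros((16, 2)))])
        out, rep = filter_tracks(tr)
        assert rep.n_split_gap == 1 and out.n_tracks == 2
        frames2 = np.concatenate([np.arange(8), np.arange(9, 16)])
        out2, rep2 = filter_tracks(_tracks_from_arrays([(frames2, np.zeros((15, 2)))]))
        assert rep2.n_split_gap == 0 and rep2.n_gaps_retained == 1
        assert out2.n_tracks == 1

    def test_empty_result_is_loud(self):
        tr = _tracks_from_arrays([(np.arange(3), np.zeros((3, 2)))])
        with pytest.raises(EmptyTrackSetError):
            filter_tracks(tr)


class TestComputeMSD:
    def test_straight_line_walk_exact(self, straight_track):
        curve, _ = compute_msd(straight_track, max_lag_frames=5)
        # step s=0.1 per frame: MSD(n) = (n s)^2 exactly
        assert np.allclose(curve.msd, (np.arange(1, 6) * 0.1) ** 2)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(0)
        arrays = []
        for _ in range(20):
            m = rng.integers(5, 25)
            frames = np.sort(rng.choice(np.arange(2 * m), size=m, replace=False))
            arrays.append((frames, rng.normal(size=(m, 2))))
        tr = _tracks_from_arrays(arrays)
        curve, _ = compute_msd(tr, max_lag_frames=10)
        msd_bf, n_bf = brute_force_msd(tr, 10)
        assert np.allclose(curve.msd, msd_bf, atol=1e-12)
        assert np.array_equal(curve.n_pairs, n_bf)

    def test_ensemble_is_paircount_weighted_mean(self, brownian_tracks):
        ensemble, per_track = compute_msd(brownian_tracks, max_lag_frames=6)
        for k, lag in enumerate(ensemble.lag):
            num = den = 0.0
            for c in per_track.values():
                sel = np.isclose(c.lag, lag)
                if sel.any():
                    num += (c.msd[sel] * c.n_pairs[sel]).sum()
                    den += c.n_pairs[sel].sum()
            assert ensemble.msd[k] == pytest.approx(num / den, abs=1e-12)

    def test_invariant_under_rigid_motion(self, brownian_tracks):
        curve0, _ = compute_msd(brownian_tracks, max_lag_frames=5)
        th = 0.7
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        xy = brownian_tracks.data[["x_um", "y_um"]].to_numpy() @ R.T + [5.0, -3.0]
        moved = TrackSet(data=brownian_tracks.data.assign(
            x_um=xy[:, 0], y_um=xy[:, 1]), dt=brownian_tracks.dt)
        curve1, _ = compute_msd(moved, max_lag_frames=5)
        assert np.allclose(curve0.msd, curve1.msd, atol=1e-9)

    def test_localization_noise_raises_every_lag_by_4_sigma_sq(self):
        sigma = 0.05
        model = DiffusionStateModel(D=[1.0], pi=[1.0], tau=[1.0], Q=[[0.0]],
                                    dt=0.01, sigma_loc=0.0)
        cfg = SimulationConfig(n_tracks=600, mean_track_length=30, seed=21)
        clean = simulate_tracks(model, cfg)
        rng = np.random.default_rng(1)
        noisy_xy = clean.data[["x_um", "y_um"]].to_numpy() \
            + rng.normal(scale=sigma, size=(len(clean.data), 2))
        noisy = TrackSet(data=clean.data.assign(x_um=noisy_xy[:, 0],
                                                y_um=noisy_xy[:, 1]),
                         dt=clean.dt)
        c0, _ = compute_msd(clean, max_lag_frames=4)
        c1, _ = compute_msd(noisy, max_lag_frames=4)
        lift = c1.msd - c0.msd
        assert np.allclose(lift, 4 * sigma ** 2, rtol=0.12)


class TestBrownianFit:
    def test_exact_line(self):
        t = np.arange(1, 7) * 0.01
        curve = MSDCurve(lag=t, msd=4 * 2.0 * t, n_pairs=np.full(6, 100))
        fit = fit_brownian(curve)
        assert fit.D == pytest.approx(2.0, abs=1e-12)
        assert fit.offset == pytest.approx(0.0, abs=1e-12)

    def test_exact_line_with_noise_offset(self):
        t = np.arange(1, 7) * 0.01
        b = 4 * 0.02 ** 2
        curve = MSDCurve(lag=t, msd=4 * 2.0 * t + b, n_pairs=np.full(6, 100))
        fit = fit_brownian(curve)
        assert fit.D == pytest.approx(2.0, abs=1e-9)
        assert fit.offset == pytest.approx(1.6e-3, abs=1e-9)

    def test_recovery_from_simulated_tracks(self, brownian_tracks):
        curve, _ = compute_msd(brownian_tracks, max_lag_frames=10)
        fit = fit_brownian(curve)
        assert fit.D == pytest.approx(3.0, rel=0.05)
        assert not fit.negative_D


class TestConfinedFit:
    def test_exact_recovery_from_closed_form(self):
        t = np.arange(1, 30) * 0.01
        L, D = 0.4, 1.5
        curve = MSDCurve(lag=t, msd=_corral_msd(t, L, D),
                         n_pairs=np.full(len(t), 50))
        fit = fit_confined(curve)
        assert fit.converged
        assert fit.L == pytest.approx(L, rel=1e-6)
        assert fit.D == pytest.approx(D, rel=1e-6)

    def test_corral_simulation_recovers_L(self):
        L = 0.5
        tr = simulate_confined_track(D=1.0, L=L, dt=0.01, n_frames=300,
                                     seed=8, n_tracks=300)
        curve, _ = compute_msd(tr, max_lag_frames=60)
        fit = fit_confined(curve)
        assert fit.converged
        assert fit.L == pytest.approx(L, rel=0.10)
        assert fit.classification == "confined"

    def test_free_diffusion_classified_brownian(self, brownian_tracks):
        curve, _ = compute_msd(brownian_tracks, max_lag_frames=8)
        fit = fit_confined(curve)
        assert fit.classification == "brownian"
        assert fit.curvature_ratio == pytest.approx(1.0, abs=0.2)
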