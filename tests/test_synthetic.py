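"""Generator correctness: rate matrices, trajectories, toy fixtures."""

import io as _io

import numpy as np
import pandas as pd
import pytest
from scipy.linalg import expm

from memclust import (DiffusionStateModel, SimulationConfig,
                      build_rate_matrix, compute_dz, make_peak_table,
                      make_toy_structure, simulate_confined_track,
                      simulate_tracks, three_state_kras,
                      three_state_kras_rbdcrd)
from memclust.io import write_tracks
from memclust.synthetic import RateMatrixInfeasibleError


class TestBuildRateMatrix:
    def test_single_state_has_no_switching(self):
        assert build_rate_matrix([1.0], [5.0]).tolist() == [[0.0]]

    def test_symmetric_two_state_rates(self):
        Q = build_rate_matrix([0.5, 0.5], [1.0, 1.0])
        assert Q[0, 1] == pytest.approx(1.0)
        assert Q[1, 0] == pytest.approx(1.0)

    @pytest.mark.parametrize("model_fn", [three_state_kras,
                                          three_state_kras_rbdcrd])
    def test_three_state_stationarity_and_exit_rates(self, model_fn):
        # independent check: stationary distribution of exp(Q t) at large t
        m = model_fn()
        assert np.abs(m.pi @ m.Q).max() < 1e-9
        assert np.allclose(-np.diag(m.Q), 1.0 / m.tau)
        P_long = expm(m.Q * 50.0)
        for row in P_long:
            assert np.allclose(row, m.pi, atol=1e-8)
        # detailed balance
        flux = m.pi[:, None] * m.Q
        assert np.allclose(flux, flux.T, atol=1e-12)

    def test_infeasible_combination_raises(self):
        # two-state chain requires flux balance pi1/tau1 == pi2/tau2
        with pytest.raises(RateMatrixInfeasibleError):
            build_rate_matrix([0.9, 0.1], [0.1, 10.0])

    def test_rejects_bad_distributions(self):
        with pytest.raises(ValueError):
            build_rate_matrix([0.5, 0.6], [1.0, 1.0])
        with pytest.raises(ValueError):
            build_rate_matrix([0.5, 0.5], [1.0, -1.0])


class TestSimulateTracks:
    def test_zero_diffusion_zero_noise_is_static(self):
        m = DiffusionStateModel(D=[0.0], pi=[1.0], tau=[1.0], Q=[[0.0]],
                                sigma_loc=0.0)
        tr = simulate_tracks(m, SimulationConfig(n_tracks=5, seed=0))
        for _, t in tr.iter_tracks():
            assert t["x_um"].nunique() == 1
            assert t["y_um"].nunique() == 1

    def test_one_lag_msd_matches_closed_form(self):
        # E|dr|^2 = 4 D dt for a single free state without noise
        m = DiffusionStateModel(D=[3.0], pi=[1.0], tau=[1.0], Q=[[0.0]],
                                dt=0.01, sigma_loc=0.0)
        tr = simulate_tracks(m, SimulationConfig(
            n_tracks=1, mean_track_length=10000, seed=2))
        d = np.diff(tr.data[["x_um", "y_um"]].to_numpy(), axis=0)
        msd1 = (d ** 2).sum(axis=1)
        se = msd1.std(ddof=1) / np.sqrt(len(msd1))
        assert abs(msd1.mean() - 4 * 3.0 * 0.01) < 3 * se

    def test_state_occupancy_matches_pi(self):
        m = three_state_kras()
        tr = simulate_tracks(m, SimulationConfig(n_tracks=5000,
                                                 mean_track_length=50, seed=7))
        occ = tr.data.groupby("state").size() / len(tr)
        assert np.abs(occ.to_numpy() - m.pi).max() < 0.01

    def test_seeded_determinism_byte_identical(self, tmp_path):
        m = three_state_kras()
        cfg = SimulationConfig(n_tracks=20, blink_probability=0.05, seed=42)
        payloads = []
        for rep in range(2):
            buf = _io.StringIO()
            write_tracks(simulate_tracks(m, cfg), buf)
            payloads.append(buf.getvalue())
        assert payloads[0] == payloads[1]

    def test_blinking_creates_gaps_not_reordering(self):
        m = three_state_kras()
        tr = simulate_tracks(m, SimulationConfig(
            n_tracks=50, blink_probability=0.2, seed=3))
        gaps = tr.data.groupby("track_id")["frame"].diff().dropna()
        assert (gaps >= 1).all()
        assert (gaps > 1).any()

    def test_minimum_emitted_length(self):
        m = three_state_kras()
        tr = simulate_tracks(m, SimulationConfig(
            n_tracks=300, mean_track_length=8, seed=1))
        lengths = tr.data.groupby("track_id").size()
        assert lengths.min() >= 7


class TestConfinedTracks:
    def test_large_corral_matches_free_diffusion_first_lag(self):
        free = simulate_confined_track(D=1.0, L=1e4, dt=0.01, n_frames=5000,
                                       seed=9, n_tracks=4)
        d = []
        for _, _, xy in free.contiguous_segments():
            d.append(((xy[1:] - xy[:-1]) ** 2).sum(axis=1))
        msd1 = np.concatenate(d).mean()
        assert msd1 == pytest.approx(4 * 1.0 * 0.01, rel=0.01 * 3)

    def test_long_time_plateau_is_Lsq_over_3(self):
        L = 0.5
        tr = simulate_confined_track(D=1.0, L=L, dt=0.01, n_frames=400,
                                     seed=4, n_tracks=200)
        pos = tr.data.pivot_table(index="track_id", columns="frame",
                                  values=["x_um", "y_um"]).to_numpy()
        x = pos[:, :400]
        y = pos[:, 400:]
        lag = 300
        msd = ((x[:, lag:] - x[:, :-lag]) ** 2
               + (y[:, lag:] - y[:, :-lag]) ** 2).mean()
        assert msd == pytest.approx(L ** 2 / 3, rel=0.1)

    def test_zero_diffusion_zero_msd(self):
        tr = simulate_confined_track(D=0.0, L=1.0, dt=0.01, n_frames=50,
                                     seed=0)
        xy = tr.data[["x_um", "y_um"]].to_numpy()
        assert np.allclose(xy, xy[0])


class TestToyStructure:
    def test_contact_rule_boundaries(self):
        from memclust.structure import ContactSpec, contact_probability

        spec = ContactSpec(contact_range=(145, 146), dz_max=8.0)
        ca = {145: (0.0, 0.0, 8.4), 146: (0.0, 0.0, 8.6),
              147: (0.0, 0.0, 8.5), 148: (0.0, 0.0, 8.5),
              158: (0.0, 0.0, 8.5), 159: (0.0, 0.0, 8.5),
              160: (0.0, 0.0, 8.5), 161: (0.0, 0.0, 8.5)}
        frame = make_toy_structure(ca)
        out = contact_probability([frame], spec)
        by_res = out.set_index("residue")["probability"]
        assert by_res[145] == 1.0   # 8.4 Å <= 8.5 Å
        assert by_res[146] == 0.0   # 8.6 Å > 8.5 Å

    def test_beta_string_counting(self):
        codes = "CCEEEECCEEECC"
        resids = range(141, 141 + len(codes))
        assert sum(c == "E" for c in codes) == 7
        ss = {r: c for r, c in zip(resids, codes)}
        frame = make_toy_structure(
            {r: (0.0, 0.0, 30.0) for r in range(141, 165)},
            ss_codes={**{r: "C" for r in range(141, 165)}, **ss})
        from memclust.structure import ContactSpec, _frame_beta_length

        total, longest = _frame_beta_length(frame, ContactSpec())
        assert total == 7
        assert longest == 4

    def test_dz_hand_computed(self):
        spec_resids = list(range(145, 149)) + list(range(158, 162))
        frame = make_toy_structure(
            {r: (0.0, 0.0, 60.0) for r in spec_resids}, p_plane_z=(20.0,))
        assert compute_dz(frame) == pytest.approx(4.0)


class TestPeakTableFixture:
    def test_encodes_requested_truth(self):
        from memclust.nmr import csp, pre_ratio

        truth = pd.DataFrame({
            "residue": [10, 11, 12],
            "d_dH": [0.1, 0.0, 0.02],
            "d_dN": [0.5, 0.0, 0.30],
            "pre_ratio": [1.0, 0.5, 0.2],
        })
        table = make_peak_table(truth)
        out = csp(table)
        assert out["delta_nh"].tolist() == pytest.approx(
            [0.1, 0.0, np.sqrt(0.002)], abs=1e-12)
        ratios = pre_ratio(table)
        assert ratios["ratio"].tolist() == pytest.approx([1.0, 0.5, 0.2])
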