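"""Displacement-HMM inference: oracles, recovery, model selection."""

from itertools import product

import numpy as np
import pytest

from memclust import (DiffusionStateModel, DisplacementHMM, SimulationConfig,
                      fit_hmm, select_model, simulate_tracks,
                      three_state_kras)
from memclust.hmm import DisplacementHMMResults


def brute_force_loglik(segments, v, P, pi):
    """Likelihood by explicit enumeration of all hidden state paths."""
    K = len(v)
    total = 0.0
    for d in segments:
        r2 = (d ** 2).sum(axis=1)
        emis = np.exp(-r2[:, None] / (2 * v)) / (2 * np.pi * v)
        like = 0.0
        for path in product(range(K), repeat=len(d)):
            p = pi[path[0]] * emis[0, path[0]]
            for t in range(1, len(d)):
                p *= P[path[t - 1], path[t]] * emis[t, path[t]]
            like += p
        total += np.log(like)
    return total


def _small_tracks(model, n_tracks, mean_len, seed):
    return simulate_tracks(model, SimulationConfig(
        n_tracks=n_tracks, mean_track_length=mean_len, seed=seed))


def two_state_model(d_fast=2.0, d_slow=0.1, tau=0.2):
    return DiffusionStateModel.from_occupancies(
        pi=[0.5, 0.5], tau=[tau, tau], D=[d_fast, d_slow],
        dt=0.01, sigma_loc=0.0)


class TestForwardOracle:
    @pytest.mark.parametrize("K", [1, 2, 3])
    def test_forward_equals_path_enumeration(self, K):
        rng = np.random.default_rng(K)
        model = DiffusionStateModel(
            D=np.linspace(2.0, 0.2, K), pi=np.full(K, 1 / K),
            tau=np.full(K, np.inf),
            Q=np.zeros((K, K)), dt=0.01, sigma_loc=0.0)
        cfg = SimulationConfig(n_tracks=6, mean_track_length=7,
                               min_track_length=4, seed=K)
        tracks = simulate_tracks(model, cfg)
        from memclust import TrackSet
        tracks = TrackSet(data=tracks.data[tracks.data.frame < 9],
                          dt=tracks.dt)
        segments = tracks.displacement_segments()
        assert segments and max(len(s) for s in segments) <= 8
        hmm = DisplacementHMM(tracks, K, sigma_loc=0.0)
        v = 2 * model.D * model.dt
        P = rng.dirichlet(np.full(K, 2.0), size=K)
        pi = rng.dirichlet(np.full(K, 2.0))
        ll_forward = hmm.score_params(v, P, pi)
        ll_brute = brute_force_loglik(tracks.displacement_segments(), v, P, pi)
        assert ll_forward == pytest.approx(ll_brute, abs=1e-9)

    def test_matches_hmmlearn_scoring(self, kras_tracks_small):
        hmmlearn = pytest.importorskip("hmmlearn.hmm")
        K = 3
        hmm = DisplacementHMM(kras_tracks_small, K, sigma_loc=0.0)
        rng = np.random.default_rng(0)
        v = np.array([8e-2, 1.3e-2, 3.6e-3])
        P = rng.dirichlet(np.full(K, 5.0), size=K)
        pi = rng.dirichlet(np.full(K, 5.0))
        ref = hmmlearn.GaussianHMM(n_components=K, covariance_type="spherical",
                                   init_params="")
        ref.startprob_ = pi
        ref.transmat_ = P
        ref.means_ = np.zeros((K, 2))
        ref.covars_ = np.column_stack([v, v])
        segs = kras_tracks_small.displacement_segments()
        X = np.concatenate(segs)
        ll_ref = ref.score(X, [len(s) for s in segs])
        assert hmm.score_params(v, P, pi) == pytest.approx(ll_ref, abs=1e-6)


class TestRecovery:
    def test_single_state_brownian(self, brownian_tracks):
        res = fit_hmm(brownian_tracks, 1, seed=0, sigma_loc=0.0)
        assert res.model.D[0] == pytest.approx(3.0, rel=0.03)
        assert res.transition_matrix.tolist() == [[1.0]]

    def test_two_state_parameters_within_ten_percent(self):
        tracks = _small_tracks(two_state_model(), n_tracks=2500,
                               mean_len=50, seed=13)
        res = fit_hmm(tracks, 2, seed=1, sigma_loc=0.0)
        assert res.model.D[0] == pytest.approx(2.0, rel=0.10)
        assert res.model.D[1] == pytest.approx(0.1, rel=0.10)
        assert res.occupancy[0] == pytest.approx(0.5, abs=0.05)
        # lifetimes via tau = dt/(1-P_ii) against the generator's own chain
        P_true = two_state_model().transition_matrix()
        tau_true = 0.01 / (1 - np.diag(P_true))
        assert np.allclose(res.lifetimes(), tau_true, rtol=0.10)

    def test_overfit_on_one_state_data_gives_twin_states(self, brownian_tracks):
        res = fit_hmm(brownian_tracks, 2, seed=3, sigma_loc=0.0)
        d1, d2 = res.model.D
        assert abs(d1 - d2) / max(d2, 1e-9) < 0.10

    def test_states_sorted_by_descending_D(self, kras_tracks_small):
        res = fit_hmm(kras_tracks_small, 3, seed=0, sigma_loc=0.02)
        assert np.all(np.diff(res.model.D) <= 0)

    def test_restart_label_invariance(self, kras_tracks_small):
        r1 = fit_hmm(kras_tracks_small, 3, seed=1, sigma_loc=0.02)
        r2 = fit_hmm(kras_tracks_small, 3, seed=2, sigma_loc=0.02)
        assert np.allclose(r1.model.D, r2.model.D, rtol=1e-3)
        assert np.allclose(r1.occupancy, r2.occupancy, atol=1e-3)


class TestModelSelection:
    def test_one_state_data_selects_one_state(self, brownian_tracks):
        res = select_model(brownian_tracks, k_max=3, seed=0, sigma_loc=0.0)
        assert res.K == 1

    def test_twenty_fold_two_state_selected(self):
        hits = 0
        for seed in range(5):
            tracks = _small_tracks(two_state_model(2.0, 0.1), n_tracks=500,
                                   mean_len=40, seed=seed)
            res = select_model(tracks, k_max=3, seed=seed, sigma_loc=0.0)
            hits += res.K == 2
        assert hits >= 4

    def test_criterion_table_is_attached(self, brownian_tracks):
        res = select_model(brownian_tracks, k_max=2, seed=0, sigma_loc=0.0)
        assert set(res.criterion_table.columns) >= {"K", "bic", "aic"}
        assert len(res.criterion_table) == 2


class TestSummaries:
    @staticmethod
    def _manual_results(P, dt=0.01):
        P = np.asarray(P, float)
        K = len(P)
        occ = np.full(K, 1.0 / K)
        Q = P / dt
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        with np.errstate(divide="ignore"):
            tau = np.where(np.diag(P) < 1, dt / (1 - np.diag(P)), np.inf)
        model = DiffusionStateModel(D=np.linspace(1.0, 0.1, K), pi=occ,
                                    tau=tau, Q=Q, dt=dt,
                                    check_stationarity=False)
        return DisplacementHMMResults(
            model=model, transition_matrix=P, log_likelihood=0.0,
            occupancy=occ, D_raw=model.D, sigma_loc=0.0, dt=dt,
            n_displacements=100, n_iter=1, converged=True,
            degenerate=np.zeros(K, bool))

    def test_lifetime_formula(self):
        res = self._manual_results([[0.9, 0.1], [0.1, 0.9]])
        assert res.lifetimes().tolist() == pytest.approx([0.1, 0.1])

    def test_pairwise_rate_convention(self):
        # P_ij = 0.225 at dt = 10 ms -> 22.5 per second
        res = self._manual_results([[0.775, 0.225], [0.0, 1.0]])
        rates = res.transition_rates()
        r12 = rates.query("from_state == 1 and to_state == '2'")
        assert r12["rate_per_s"].iloc[0] == pytest.approx(22.5, abs=1e-12)
        exit1 = rates.query("from_state == 1 and to_state == 'any'")
        assert exit1["rate_per_s"].iloc[0] == pytest.approx(22.5, abs=1e-12)

    def test_symmetric_chain_equal_occupancy(self):
        tracks = _small_tracks(two_state_model(), n_tracks=1500,
                               mean_len=40, seed=17)
        res = fit_hmm(tracks, 2, seed=0, sigma_loc=0.0)
        assert res.occupancy[0] == pytest.approx(0.5, abs=0.05)
        table = res.summary()
        assert list(table.columns) == ["state", "D_um2_s", "occupancy_pct",
                                       "lifetime_s"]
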