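"""Hidden-Markov inference of diffusive states from displacement sequences.

The generative model is the one the simulator implements: a particle
switches between K hidden diffusive states at frame boundaries following a
Markov chain, and the observed 2D displacement over a frame interval is a
zero-mean isotropic Gaussian whose per-axis variance in state k is
2·D_k·Δt + 2·σ_loc² (two independent localization errors per
displacement).  Blink gaps break a track into independent observation
sequences.

Fitting is Baum–Welch EM with multiple restarts; the number of states is
chosen by BIC over K = 1..K_max.  This plays the role that a variational-
Bayes treatment plays in the SPT literature: the same likelihood, with
explicit rather than implicit Occam pressure.  States are always reported
sorted by descending D (fast state first).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synthetic import DiffusionStateModel
from .tracks import TrackSet

__all__ = ["DisplacementHMM", "DisplacementHMMResults", "fit_hmm",
           "select_model", "summarize_states"]


class EMConvergenceError(RuntimeError):
    """EM decreased the likelihood — an internal consistency failure."""


def _pack_segments(segments):
    """Sort displacement segments by length (desc) and pad to rectangles.

    Returns ``(r2, mask, lengths)`` where r2[s, t] is the squared
    displacement magnitude of sequence s at step t.  Sorting means the set
    of sequences alive at step t is always a prefix, so the forward and
    backward recursions can run on shrinking array views.
    """
    segments = sorted(segments, key=len, reverse=True)
    S = len(segments)
    T = len(segments[0])
    r2 = np.zeros((S, T))
    lengths = np.empty(S, dtype=int)
    for s, d in enumerate(segments):
        lengths[s] = len(d)
        r2[s, :len(d)] = (d ** 2).sum(axis=1)
    mask = np.arange(T)[None, :] < lengths[:, None]
    return r2, mask, lengths


def _emission_probs(r2_t, v):
    """p(displacement | state) for 2D isotropic Gaussian steps, one column."""
    B = np.exp(-r2_t[:, None] / (2.0 * v[None, :])) / (2.0 * np.pi * v[None, :])
    np.clip(B, 1e-300, None, out=B)
    return B


def _em(r2, lengths, v0, P0, pi0, max_iter, tol):
    """Scaled Baum–Welch on padded sequences; returns params + posteriors.

    Sequences are length-sorted so the alive set at step t is a prefix;
    emissions are computed column-by-column to avoid padded work.  The
    log-likelihood is asserted non-decreasing at every iteration.
    """
    S, T = r2.shape
    K = len(v0)
    counts_alive = (np.arange(T)[None, :] < lengths[:, None]).sum(axis=0)
    v, P, pi = v0.copy(), P0.copy(), pi0.copy()
    prev_ll = -np.inf
    alpha = np.zeros((S, T, K))
    c = np.ones((S, T))
    gamma_full = np.zeros((S, T, K))
    for it in range(max_iter):
        # forward
        a = pi[None, :] * _emission_probs(r2[:, 0], v)
        c[:, 0] = a.sum(axis=1)
        alpha[:, 0, :] = a / c[:, 0, None]
        for t in range(1, T):
            n = counts_alive[t]
            if n == 0:
                break
            a = (alpha[:n, t - 1, :] @ P) * _emission_probs(r2[:n, t], v)
            c[:n, t] = a.sum(axis=1)
            alpha[:n, t, :] = a / c[:n, t, None]
        ll = float(np.log(c[np.arange(T)[None, :] < lengths[:, None]]).sum())
        if ll < prev_ll - 1e-6 * max(1.0, abs(prev_ll)):
            raise EMConvergenceError(
                f"EM likelihood decreased at iteration {it}: {prev_ll} -> {ll}")
        # backward, accumulating sufficient statistics
        beta = np.ones((S, K))
        gamma_sum = np.zeros(K)
        gamma_r2 = np.zeros(K)
        xi_sum = np.zeros((K, K))
        gamma0 = np.zeros(K)
        for t in range(T - 1, -1, -1):
            n = counts_alive[t]
            g = alpha[:n, t, :] * beta[:n, :]
            g /= np.clip(g.sum(axis=1, keepdims=True), 1e-300, None)
            gamma_full[:n, t, :] = g
            gamma_sum += g.sum(axis=0)
            gamma_r2 += (g * r2[:n, t, None]).sum(axis=0)
            if t == 0:
                gamma0 += g.sum(axis=0)
            if t > 0:
                bb = _emission_probs(r2[:n, t], v) * beta[:n, :]
                bb /= c[:n, t, None]
                xi_sum += np.einsum("si,ij,sj->ij", alpha[:n, t - 1, :], P, bb)
                beta_new = bb @ P.T
                beta = np.ones((S, K))
                beta[:n, :] = beta_new
        converged = abs(ll - prev_ll) < tol * max(1.0, abs(ll))
        prev_ll = ll
        # M-step
        v = gamma_r2 / (2.0 * np.clip(gamma_sum, 1e-300, None))
        np.clip(v, 1e-12, None, out=v)
        if K > 1:
            rows = xi_sum.sum(axis=1, keepdims=True)
            P = np.where(rows > 0, xi_sum / np.clip(rows, 1e-300, None),
                         np.eye(K))
            pi = gamma0 / gamma0.sum()
        if converged and it > 0:
            break
    return v, P, pi, prev_ll, gamma_full, it + 1


@dataclass
class DisplacementHMMResults:
    """Estimates from a fitted displacement HMM.

    States are sorted by descending diffusion coefficient.  ``occupancy``
    is posterior-weighted over displacements (fraction of displacement
    posteriors assigned to each state).  ``model`` repackages the
    estimates as a :class:`DiffusionStateModel` with the rate convention
    Q_ij = P_ij/Δt (so Q_ii = −(1−P_ii)/Δt = −1/τ_i).
    """

    model: DiffusionStateModel
    transition_matrix: np.ndarray
    log_likelihood: float
    occupancy: np.ndarray
    D_raw: np.ndarray              # before the D >= 0 floor
    sigma_loc: float
    dt: float
    n_displacements: int
    n_iter: int
    converged: bool
    degenerate: np.ndarray         # per-state: occupancy below 1/n flag
    posteriors: list = field(default_factory=list, repr=False)
    criterion_table: pd.DataFrame | None = None
    meta: dict = field(default_factory=dict)

    @property
    def K(self) -> int:
        return self.model.K

    def lifetimes(self) -> np.ndarray:
        """Mean state lifetimes τ_i = Δt / (1 − P_ii)."""
        pii = np.diag(self.transition_matrix)
        with np.errstate(divide="ignore"):
            return np.where(pii < 1.0, self.dt / (1.0 - pii), np.inf)

    def transition_rates(self) -> pd.DataFrame:
        """Pairwise rates r_ij = P_ij/Δt (s⁻¹), tidy format.

        Exit rates (1−P_ii)/Δt are also reported (``to_state = "any"``);
        both conventions for a printed "transition probability in s⁻¹" are
        thus available.
        """
        K = self.K
        rows = []
        P = self.transition_matrix
        for i in range(K):
            for j in range(K):
                if i != j:
                    rows.append({"from_state": i + 1, "to_state": str(j + 1),
                                 "rate_per_s": P[i, j] / self.dt})
            rows.append({"from_state": i + 1, "to_state": "any",
                         "rate_per_s": (1.0 - P[i, i]) / self.dt})
        return pd.DataFrame(rows)

    def summary(self) -> pd.DataFrame:
        """Per-state table: D (µm²/s), occupancy (%), lifetime (s)."""
        return pd.DataFrame({
            "state": np.arange(1, self.K + 1),
            "D_um2_s": self.model.D,
            "occupancy_pct": 100.0 * self.occupancy,
            "lifetime_s": self.lifetimes(),
        })

    def to_dict(self) -> dict:
        return {
            "n_states": int(self.K),
            "D_um2_s": self.model.D.tolist(),
            "occupancy": self.occupancy.tolist(),
            "lifetime_s": self.lifetimes().tolist(),
            "transition_matrix": self.transition_matrix.tolist(),
            "log_likelihood": self.log_likelihood,
            "sigma_loc_um": self.sigma_loc,
            "dt_s": self.dt,
            "n_displacements": int(self.n_displacements),
            "converged": bool(self.converged),
            "method": "baum_welch_em_bic",
        }


class DisplacementHMM:
    """K-state displacement HMM over a :class:`~memclust.tracks.TrackSet`.

    Parameters
    ----------
    tracks : TrackSet
        Should already be filtered; blink gaps break sequences.
    n_states : int
        Number of diffusive states K ≥ 1.
    sigma_loc : float, optional
        Known 1D localization error (µm) subtracted when converting
        emission variances to diffusion coefficients,
        D_k = (v_k/2 − σ_loc²)/Δt.  Defaults to the value recorded by the
        simulator in ``tracks.meta`` or 0.
    n_restarts : int
        Random EM restarts (≥ 10 by default).  Restarts are initialized by
        quantile-splitting the observed squared displacements, then
        perturbed; each runs a short burn-in and only the best continues
        to convergence.
    """

    def __init__(self, tracks: TrackSet, n_states: int,
                 sigma_loc: float | None = None, n_restarts: int = 10,
                 max_iter: int = 300, burn_iter: int = 8, tol: float = 1e-7,
                 keep_posteriors: bool = False):
        if n_states < 1:
            raise ValueError("n_states must be >= 1")
        self.tracks = tracks
        self.K = n_states
        self.sigma_loc = (tracks.meta.get("sigma_loc", 0.0)
                          if sigma_loc is None else sigma_loc)
        self.n_restarts = n_restarts
        self.max_iter = max_iter
        self.burn_iter = burn_iter
        self.tol = tol
        self.keep_posteriors = keep_posteriors
        segments = tracks.displacement_segments()
        if not segments:
            raise ValueError("tracks contain no displacements")
        self._r2, self._mask, self._lengths = _pack_segments(segments)
        self.dt = tracks.dt

    # -- initialization --------------------------------------------------
    def _initial_params(self, rng: np.random.Generator, perturb: bool):
        r2 = self._r2[self._mask]
        qs = np.quantile(r2, np.linspace(0, 1, self.K + 1))
        v = np.empty(self.K)
        for k in range(self.K):
            sel = r2[(r2 >= qs[k]) & (r2 <= qs[k + 1])]
            v[k] = max(sel.mean() / 2.0 if sel.size else r2.mean() / 2.0, 1e-10)
        P = np.full((self.K, self.K), 0.1 / max(self.K - 1, 1))
        np.fill_diagonal(P, 0.9)
        P /= P.sum(axis=1, keepdims=True)
        pi = np.full(self.K, 1.0 / self.K)
        if perturb:
            v = v * np.exp(rng.normal(scale=0.5, size=self.K))
            P = P * np.exp(rng.normal(scale=0.3, size=P.shape))
            P /= P.sum(axis=1, keepdims=True)
            pi = rng.dirichlet(np.full(self.K, 5.0))
        return v, P, pi

    def score_params(self, v, P, pi) -> float:
        """Forward-algorithm log-likelihood at the given parameters.

        ``v`` are per-axis emission variances, ``P`` the per-frame
        transition matrix, ``pi`` the initial distribution.  Useful for
        cross-checks against independent likelihood implementations.
        """
        out = _em(self._r2, self._lengths, np.asarray(v, float),
                  np.asarray(P, float), np.asarray(pi, float),
                  max_iter=1, tol=0.0)
        return out[3]

    # -- fitting ---------------------------------------------------------
    def fit(self, seed: int = 0) -> DisplacementHMMResults:
        rng = np.random.default_rng(seed)
        candidates = []
        for r in range(self.n_restarts):
            v0, P0, pi0 = self._initial_params(rng, perturb=(r > 0))
            out = _em(self._r2, self._lengths, v0, P0, pi0,
                      max_iter=self.burn_iter, tol=self.tol)
            candidates.append(out)
        best = max(candidates, key=lambda o: o[3])
        v, P, pi, ll, gamma, n_burn = best
        v, P, pi, ll, gamma, n_iter = _em(self._r2, self._lengths, v, P, pi,
                                          max_iter=self.max_iter, tol=self.tol)
        return self._package(v, P, ll, gamma, n_burn + n_iter)

    def _package(self, v, P, ll, gamma, n_iter) -> DisplacementHMMResults:
        mask = self._mask
        n_disp = int(mask.sum())
        occ = gamma[mask].sum(axis=0) / n_disp
        occ = occ / occ.sum()
        D_raw = (v / 2.0 - self.sigma_loc ** 2) / self.dt
        order = np.argsort(-D_raw, kind="stable")
        D_raw, occ = D_raw[order], occ[order]
        P = P[np.ix_(order, order)]
        gamma = gamma[:, :, order]
        D = np.clip(D_raw, 0.0, None)
        pii = np.diag(P)
        with np.errstate(divide="ignore"):
            tau = np.where(pii < 1.0, self.dt / (1.0 - pii), np.inf)
        Q = P / self.dt
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        model = DiffusionStateModel(D=D, pi=occ, tau=tau, Q=Q, dt=self.dt,
                                    sigma_loc=self.sigma_loc,
                                    check_stationarity=False)
        posteriors = []
        if self.keep_posteriors:
            for s, L in enumerate(self._lengths):
                posteriors.append(gamma[s, :L, :])
        return DisplacementHMMResults(
            model=model, transition_matrix=P, log_likelihood=ll,
            occupancy=occ, D_raw=D_raw, sigma_loc=self.sigma_loc, dt=self.dt,
            n_displacements=n_disp, n_iter=n_iter,
            converged=n_iter < self.max_iter + self.burn_iter,
            degenerate=occ < 1.0 / n_disp, posteriors=posteriors,
            meta={"n_restarts": self.n_restarts})

    # -- model selection -------------------------------------------------
    def n_parameters(self) -> int:
        return self.K + self.K * (self.K - 1) + (self.K - 1)


def fit_hmm(tracks: TrackSet, n_states: int, seed: int = 0,
            **kwargs) -> DisplacementHMMResults:
    """Fit a K-state displacement HMM (convenience wrapper)."""
    return DisplacementHMM(tracks, n_states, **kwargs).fit(seed=seed)


def select_model(tracks: TrackSet, k_max: int = 4, criterion: str = "bic",
                 seed: int = 0, **kwargs) -> DisplacementHMMResults:
    """Fit K = 1..k_max and return the fit minimizing BIC (or AIC).

    Ties break toward smaller K.  The full criterion table is attached to
    the returned results for audit.
    """
    if criterion not in ("bic", "aic"):
        raise ValueError("criterion must be 'bic' or 'aic'")
    fits, rows = [], []
    for K in range(1, k_max + 1):
        hmm = DisplacementHMM(tracks, K, **kwargs)
        res = hmm.fit(seed=seed)
        p = hmm.n_parameters()
        n = res.n_displacements
        bic = -2.0 * res.log_likelihood + p * np.log(n)
        aic = -2.0 * res.log_likelihood + 2.0 * p
        fits.append(res)
        rows.append({"K": K, "log_likelihood": res.log_likelihood,
                     "n_params": p, "bic": bic, "aic": aic})
    table = pd.DataFrame(rows)
    vals = table[criterion].to_numpy()
    best = int(np.argmin(vals))  # argmin takes the first (= smallest K) on ties
    res = fits[best]
    res.criterion_table = table
    res.meta["selection_criterion"] = criterion
    return res


def summarize_states(results: DisplacementHMMResults) -> pd.DataFrame:
    """Per-state table (D, occupancy %, lifetime) of a fit."""
    return results.summary()
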