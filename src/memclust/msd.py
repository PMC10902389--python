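"""Mean-square-displacement analysis of single-particle tracks.

Pipeline: raw tracks are filtered with the standard SPT retention rules
(minimum length, maximum single-step jump, maximum blink gap), per-track
time-averaged MSD curves are computed over all displacement pairs that do
not span a gap, and the ensemble curve (pair-count-weighted mean) is fitted
with either a free-diffusion line MSD = 4·D·t + b or the square-corral
confinement form MSD(t) = (L²/3)(1 − exp(−12·D·t/L²)) + 4σ_loc².

The offset b of the Brownian fit absorbs the localization-noise floor:
independent errors at both ends of a displacement raise every lag by 4σ².
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import curve_fit

from .tracks import TrackSet


class EmptyTrackSetError(ValueError):
    """Filtering removed every track."""


@dataclass
class FilterRules:
    """Track-retention rules (camera-calibration aware).

    ``min_track_frames=7`` keeps tracks persisting for more than 6 frames;
    ``max_jump=5`` pixels caps the displacement between consecutive
    observations; ``max_blink_frames=1`` tolerates a single dark frame
    before a track is split.
    """

    min_track_frames: int = 7
    max_jump: float = 5.0          # pixels
    max_blink_frames: int = 1
    pixel_size: float = 0.16       # µm / pixel

    def __post_init__(self) -> None:
        if min(self.min_track_frames, self.max_jump,
               self.max_blink_frames, self.pixel_size) <= 0:
            raise ValueError("all filter parameters must be positive")


@dataclass
class FilterReport:
    n_tracks_in: int = 0
    n_tracks_out: int = 0
    n_removed_short: int = 0
    n_split_jump: int = 0
    n_split_gap: int = 0
    n_gaps_retained: int = 0


def filter_tracks(tracks: TrackSet, rules: FilterRules | None = None):
    """Apply retention rules; returns ``(TrackSet, FilterReport)``.

    Tracks are split wherever the displacement between consecutive
    observations exceeds ``max_jump`` pixels or a gap exceeds
    ``max_blink_frames``; gaps within the blink allowance are retained
    (counted in the report).  Pieces shorter than ``min_track_frames``
    observations are dropped.  Raises :class:`EmptyTrackSetError` if
    nothing survives.
    """
    rules = rules or FilterRules()
    report = FilterReport(n_tracks_in=tracks.n_tracks)
    max_jump_um = rules.max_jump * rules.pixel_size
    pieces = []
    new_id = 0
    for tid, tr in tracks.iter_tracks():
        frames = tr["frame"].to_numpy(int)
        xy = tr[["x_um", "y_um"]].to_numpy(float)
        gaps = np.diff(frames) - 1
        jumps = np.linalg.norm(np.diff(xy, axis=0), axis=1)
        split_gap = gaps > rules.max_blink_frames
        split_jump = (~split_gap) & (jumps > max_jump_um)
        report.n_split_gap += int(split_gap.sum())
        report.n_split_jump += int(split_jump.sum())
        cut = np.flatnonzero(split_gap | split_jump)
        start = 0
        for c in list(cut) + [len(frames) - 1]:
            stop = c + 1
            if stop - start >= rules.min_track_frames:
                piece = tr.iloc[start:stop].copy()
                piece["track_id"] = new_id
                report.n_gaps_retained += int(
                    ((np.diff(frames[start:stop]) - 1) > 0).sum())
                pieces.append(piece)
                new_id += 1
            else:
                report.n_removed_short += 1
            start = stop
    if not pieces:
        raise EmptyTrackSetError("no tracks survive the filter rules")
    report.n_tracks_out = len(pieces)
    out = TrackSet(data=pd.concat(pieces, ignore_index=True), dt=tracks.dt,
                   pixel_size=tracks.pixel_size,
                   meta={**tracks.meta, "filtered": True})
    return out, report


@dataclass
class MSDCurve:
    """An MSD curve: lags (s), values (µm²) and pair counts."""

    lag: np.ndarray
    msd: np.ndarray
    n_pairs: np.ndarray
    scope: str = "ensemble"        # "ensemble" | "track"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.lag = np.asarray(self.lag, float)
        self.msd = np.asarray(self.msd, float)
        self.n_pairs = np.asarray(self.n_pairs, int)
        if np.any(np.diff(self.lag) <= 0):
            raise ValueError("lags must strictly increase")
        if np.any(self.msd < 0):
            raise ValueError("MSD values must be >= 0")
        if np.any(self.n_pairs < 1):
            raise ValueError("every reported lag needs at least one pair")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"lag_s": self.lag, "msd_um2": self.msd,
                             "n_pairs": self.n_pairs})

    def plot(self, ax=None, **kwargs):
        import matplotlib.pyplot as plt

        ax = ax or plt.gca()
        ax.plot(self.lag, self.msd, marker="o", **kwargs)
        ax.set_xlabel("lag (s)")
        ax.set_ylabel(r"MSD ($\mu m^2$)")
        return ax


def compute_msd(tracks: TrackSet, max_lag_frames: int = 20):
    """Time-averaged MSD per track plus the ensemble curve.

    For each track and each lag n, all displacement pairs (i, i+n) lying
    inside a contiguous (gap-free) run contribute; pairs spanning a blink
    gap are excluded.  The ensemble curve is the pair-count-weighted mean
    of the per-track curves.  A requested lag beyond the longest track is
    truncated (with a note in the ensemble metadata).

    Returns ``(ensemble: MSDCurve, per_track: dict[track_id, MSDCurve])``.
    """
    segments = tracks.contiguous_segments()
    if not segments:
        raise EmptyTrackSetError("no track segments to analyse")
    longest = max(len(xy) for _, _, xy in segments)
    n_lags = min(max_lag_frames, longest - 1)
    truncated = n_lags < max_lag_frames

    sums: dict = {}
    counts: dict = {}
    for tid, _, xy in segments:
        s = sums.setdefault(tid, np.zeros(n_lags))
        c = counts.setdefault(tid, np.zeros(n_lags, dtype=int))
        m = len(xy)
        for n in range(1, min(m - 1, n_lags) + 1):
            d = xy[n:] - xy[:-n]
            s[n - 1] += (d ** 2).sum()
            c[n - 1] += m - n

    per_track = {}
    for tid in sums:
        mask = counts[tid] > 0
        if not mask.any():
            continue
        lags = (np.flatnonzero(mask) + 1) * tracks.dt
        per_track[tid] = MSDCurve(lag=lags, msd=sums[tid][mask] / counts[tid][mask],
                                  n_pairs=counts[tid][mask], scope="track")
    tot_s = np.sum(list(sums.values()), axis=0)
    tot_c = np.sum(list(counts.values()), axis=0)
    mask = tot_c > 0
    ensemble = MSDCurve(
        lag=(np.flatnonzero(mask) + 1) * tracks.dt,
        msd=tot_s[mask] / tot_c[mask],
        n_pairs=tot_c[mask],
        scope="ensemble",
        meta={"truncated": truncated, "n_tracks": len(per_track)})
    return ensemble, per_track


# ---------------------------------------------------------------------------
# model fits
# ---------------------------------------------------------------------------

@dataclass
class BrownianFitResult:
    """Free-diffusion fit MSD = 4·D·t + b."""

    D: float                      # µm²/s
    offset: float                 # µm²
    D_stderr: float
    n_lags: int
    negative_D: bool

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({
            "parameter": ["D_app (um^2/s)", "offset (um^2)"],
            "estimate": [self.D, self.offset],
            "stderr": [self.D_stderr, np.nan],
        })


class BrownianMSDModel:
    """Weighted linear fit of an MSD curve to free diffusion.

    Weighted least squares of msd = 4·D·t + b over the first
    ``n_fit_lags`` lags (default 4: the short-lag regime minimizes
    confinement bias), weighted by displacement-pair counts.  A negative
    fitted D is reported with a flag, never clamped.
    """

    def __init__(self, curve: MSDCurve, n_fit_lags: int = 4):
        if len(curve.lag) < n_fit_lags:
            raise ValueError(
                f"curve has {len(curve.lag)} lags; need {n_fit_lags}")
        self.curve = curve
        self.n_fit_lags = n_fit_lags

    def fit(self) -> BrownianFitResult:
        k = self.n_fit_lags
        t = self.curve.lag[:k]
        y = self.curve.msd[:k]
        w = self.curve.n_pairs[:k].astype(float)
        X = sm.add_constant(4.0 * t)
        res = sm.WLS(y, X, weights=w).fit()
        slope_se = float(res.bse[1]) if k > 2 else np.nan
        return BrownianFitResult(D=float(res.params[1]),
                                 offset=float(res.params[0]),
                                 D_stderr=slope_se, n_lags=k,
                                 negative_D=bool(res.params[1] < 0))


def fit_brownian(curve: MSDCurve, n_fit_lags: int = 4) -> BrownianFitResult:
    return BrownianMSDModel(curve, n_fit_lags=n_fit_lags).fit()


def _corral_msd(t, L, D):
    return (L ** 2 / 3.0) * (1.0 - np.exp(-12.0 * D * t / L ** 2))


@dataclass
class ConfinedFitResult:
    """Square-corral confinement fit with a Brownian/confined classifier.

    ``curvature_ratio`` = MSD(t_max) / (4·D_short·t_max) with D_short from
    the short-lag Brownian fit: ≈1 for free diffusion, < 1 when the curve
    saturates.  Classification is "confined" below the threshold stored in
    ``meta``.
    """

    L: float | None               # µm
    D: float | None               # µm²/s
    r_squared: float | None
    curvature_ratio: float
    converged: bool
    classification: str
    meta: dict = field(default_factory=dict)

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({
            "parameter": ["corral side L (um)", "D (um^2/s)", "R^2",
                          "curvature ratio", "classification"],
            "value": [self.L, self.D, self.r_squared,
                      self.curvature_ratio, self.classification],
        })


class ConfinedMSDModel:
    """Nonlinear least-squares fit of an MSD curve to corral confinement.

    MSD(t) = (L²/3)(1 − exp(−12·D·t/L²)) + 4·σ_loc², with σ_loc supplied
    (default 0).  Non-convergence is flagged and parameters left absent.
    """

    def __init__(self, curve: MSDCurve, sigma_loc: float = 0.0,
                 brownian_threshold: float = 0.75):
        if len(curve.lag) < 6:
            raise ValueError("confined fit needs at least 6 lags")
        self.curve = curve
        self.sigma_loc = sigma_loc
        self.brownian_threshold = brownian_threshold

    def fit(self) -> ConfinedFitResult:
        t, y = self.curve.lag, self.curve.msd - 4.0 * self.sigma_loc ** 2
        short = fit_brownian(self.curve, n_fit_lags=min(4, len(t)))
        denom = 4.0 * short.D * t[-1]
        curvature = float(self.curve.msd[-1] / denom) if denom > 0 else np.inf
        label = "confined" if curvature < self.brownian_threshold else "brownian"
        L0 = max(np.sqrt(max(3.0 * y.max(), 1e-12)), 1e-3)
        D0 = max(short.D, 1e-6)
        try:
            popt, _ = curve_fit(_corral_msd, t, y, p0=(L0, D0),
                                bounds=([1e-6, 0.0], [np.inf, np.inf]),
                                maxfev=10000)
        except RuntimeError:
            return ConfinedFitResult(
                L=None, D=None, r_squared=None, curvature_ratio=curvature,
                converged=False, classification=label,
                meta={"model": "square_corral",
                      "brownian_threshold": self.brownian_threshold})
        resid = y - _corral_msd(t, *popt)
        ss_tot = ((y - y.mean()) ** 2).sum()
        r2 = 1.0 - float((resid ** 2).sum() / ss_tot) if ss_tot > 0 else 1.0
        return ConfinedFitResult(
            L=float(popt[0]), D=float(popt[1]), r_squared=r2,
            curvature_ratio=curvature, converged=True, classification=label,
            meta={"model": "square_corral",
                  "brownian_threshold": self.brownian_threshold})


def fit_confined(curve: MSDCurve, sigma_loc: float = 0.0) -> ConfinedFitResult:
    return ConfinedMSDModel(curve, sigma_loc=sigma_loc).fit()
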