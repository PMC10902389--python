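"""Single-particle track container.

All trajectory-level code in this package works in micrometres and seconds.
A :class:`TrackSet` is a thin, validated wrapper around a tidy table with one
row per localization, plus the acquisition metadata every diffusion analysis
needs: the frame interval ``dt`` and the camera pixel size.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: canonical column order for track tables (``state`` is optional)
TRACK_COLUMNS = ["track_id", "frame", "x_um", "y_um"]


@dataclass
class TrackSet:
    """A collection of 2D localization trajectories.

    Parameters
    ----------
    data : pandas.DataFrame
        Columns ``track_id, frame, x_um, y_um`` and optionally ``state``
        (integer ground-truth diffusive state, retained by the simulator for
        recovery tests).  Frames are 0-based integers; within a track they
        must strictly increase.  Gaps (missing frames) encode blinking.
    dt : float
        Frame interval in seconds.
    pixel_size : float
        Camera calibration, micrometres per pixel.  Default 0.16.
    """

    data: pd.DataFrame
    dt: float
    pixel_size: float = 0.16
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        missing = [c for c in TRACK_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"track table missing columns {missing}")
        xy = self.data[["x_um", "y_um"]].to_numpy(float)
        if xy.size and not np.all(np.isfinite(xy)):
            raise ValueError("track coordinates must be finite")
        frames = self.data["frame"].to_numpy()
        if frames.size and (frames != frames.astype(int)).any():
            raise ValueError("frame indices must be integers")
        if frames.size and frames.min() < 0:
            raise ValueError("frame indices must be >= 0")
        # strict monotonicity within each track
        order = self.data.sort_values(["track_id", "frame"]).index
        self.data = self.data.loc[order].reset_index(drop=True)
        d = self.data.groupby("track_id")["frame"].diff().dropna()
        if (d <= 0).any():
            raise ValueError("frame indices must strictly increase within a track")

    # -- basic accessors -------------------------------------------------
    @property
    def n_tracks(self) -> int:
        return self.data["track_id"].nunique()

    @property
    def has_state(self) -> bool:
        return "state" in self.data.columns

    def track_ids(self) -> np.ndarray:
        return self.data["track_id"].unique()

    def iter_tracks(self):
        """Yield ``(track_id, frame)`` sub-tables sorted by frame."""
        yield from self.data.groupby("track_id", sort=True)

    def __len__(self) -> int:
        return len(self.data)

    # -- derived structures ----------------------------------------------
    def contiguous_segments(self, min_length: int = 2):
        """Split every track at blink gaps into gap-free runs.

        Returns a list of ``(track_id, frames, xy)`` with ``xy`` an (n, 2)
        array of positions from consecutive frames only.  Displacements
        taken inside a segment therefore never span a gap.
        """
        out = []
        for tid, tr in self.iter_tracks():
            frames = tr["frame"].to_numpy(int)
            xy = tr[["x_um", "y_um"]].to_numpy(float)
            breaks = np.flatnonzero(np.diff(frames) != 1)
            start = 0
            for b in list(breaks) + [len(frames) - 1]:
                stop = b + 1
                if stop - start >= min_length:
                    out.append((tid, frames[start:stop], xy[start:stop]))
                start = stop
        return out

    def displacement_segments(self):
        """Per-segment displacement arrays (n_i, 2) in micrometres.

        The observation sequences consumed by the displacement HMM; blink
        gaps break a track into independent sequences.
        """
        return [xy[1:] - xy[:-1] for _, _, xy in self.contiguous_segments()]
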