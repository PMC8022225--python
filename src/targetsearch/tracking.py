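"""Linking localizations into tracks.

Positions in consecutive frames are linked when they fall within a fixed
search window (0.48 µm, i.e. 5 pixels at 96 nm).  When several
localizations compete for several track ends, the one-to-one assignment
minimizing the sum of step distances is solved exactly per frame pair
(optimal bipartite matching).  A memory of 1 frame lets a track resume
after a single missed frame (fluorophore blinking or a missed
localization); the resumed step uses the same search window and no
position is interpolated for the missing frame.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

__all__ = ["link"]

MAX_DISP_DEFAULT = 0.48  # µm, 5 pixels of 96 nm

_BIG = 1e9  # cost of a forbidden pairing; >> any achievable distance sum


def link(
    locs: pd.DataFrame,
    max_disp: float = MAX_DISP_DEFAULT,
    memory: int = 1,
) -> pd.DataFrame:
    """Link a localization table into tracks.

    Parameters
    ----------
    locs : DataFrame
        Columns ``frame, x_um, y_um`` and optionally ``cell_id``.  When a
        ``cell_id`` column is present, linking is performed independently
        per cell (molecules do not cross cell boundaries).
    max_disp : float
        Search window per link, in µm; also used unscaled for steps that
        resume a track across a memory gap.
    memory : int
        Number of consecutive missed frames a track may survive.

    Returns
    -------
    DataFrame with columns ``track_id, frame, x_um, y_um[, cell_id]``,
    sorted by (track_id, frame).  Localizations with no link start new
    tracks; every localization belongs to exactly one track.
    """
    if max_disp <= 0:
        raise ValueError("max_disp must be positive")
    if memory < 0:
        raise ValueError("memory must be >= 0")
    if locs.empty:
        return pd.DataFrame(columns=["track_id", "frame", "x_um", "y_um"])

    if "cell_id" in locs.columns:
        pieces = []
        offset = 0
        for cid, grp in locs.groupby("cell_id", sort=True):
            linked = _link_one(grp, max_disp, memory)
            linked["track_id"] += offset
            linked["cell_id"] = cid
            offset = int(linked["track_id"].max()) + 1 if len(linked) else offset
            pieces.append(linked)
        out = pd.concat(pieces, ignore_index=True)
    else:
        out = _link_one(locs, max_disp, memory)
    return out.sort_values(["track_id", "frame"], kind="stable").reset_index(drop=True)


def _link_one(locs: pd.DataFrame, max_disp: float, memory: int) -> pd.DataFrame:
    # deterministic processing order: by frame, then lexicographically
    df = locs.sort_values(["frame", "x_um", "y_um"], kind="stable")
    frames = df["frame"].to_numpy()
    xy = df[["x_um", "y_um"]].to_numpy(dtype=float)

    track_of = np.full(len(df), -1, dtype=int)
    next_track = 0
    # active tracks: (track_id, last_frame, last_xy)
    active_id: list[int] = []
    active_frame: list[int] = []
    active_xy: list[np.ndarray] = []

    row_index = np.arange(len(df))
    for f in np.unique(frames):
        in_frame = row_index[frames == f]
        pts = xy[in_frame]
        # retire tracks that fell out of the memory window
        keep = [i for i, lf in enumerate(active_frame) if lf >= f - 1 - memory]
        active_id = [active_id[i] for i in keep]
        active_frame = [active_frame[i] for i in keep]
        active_xy = [active_xy[i] for i in keep]

        assigned_rows = np.zeros(len(in_frame), dtype=bool)
        if active_id and len(in_frame):
            prev = np.asarray(active_xy)
            dist = np.linalg.norm(prev[:, None, :] - pts[None, :, :], axis=2)
            cost = np.where(dist <= max_disp, dist, _BIG)
            rows, cols = linear_sum_assignment(cost)
            for r, c in zip(rows, cols):
                if cost[r, c] < _BIG / 2:
                    track_of[in_frame[c]] = active_id[r]
                    active_frame[r] = int(f)
                    active_xy[r] = pts[c]
                    assigned_rows[c] = True
        for c in np.flatnonzero(~assigned_rows):
            track_of[in_frame[c]] = next_track
            active_id.append(next_track)
            active_frame.append(int(f))
            active_xy.append(pts[c])
            next_track += 1

    out = df.copy()
    out["track_id"] = track_of
    cols = ["track_id", "frame", "x_um", "y_um"]
    return out[cols].reset_index(drop=True)
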