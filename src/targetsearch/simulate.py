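"""Monte Carlo simulation of confined Brownian motion with motion blur.

Molecules diffuse inside 3D cell volumes built from stacked cylindrical
segments.  Each camera frame is split into ``n_subframes`` sub-frames
(default 100) with Gaussian-distributed displacements per sub-frame; the
observed position of a frame is the mean of its sub-frame (x, y)
positions — reproducing motion blur from continuous illumination — plus
Gaussian localization error.  Tracks start at a random activation frame
and end after an exponentially distributed photobleaching time.

Optionally molecules interconvert between a freely diffusing and a
DNA-bound state with exponential dwell times; each sub-frame displacement
uses the state occupied at the sub-frame start.

Confinement is reflective (specular) at the cell boundary, applied
separately to the axial coordinate (folded into [0, L]) and the radial
coordinate (folded at the local boundary radius).  Sub-frame steps are
short relative to the cell radius, so this per-coordinate reflection is
an accurate hard-wall rule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import CellGeometry
from .models import AcquisitionModel, MotionModel

__all__ = ["GroundTruth", "simulate_tracks", "simulate_dstar_values"]


@dataclass
class GroundTruth:
    """Simulator bookkeeping: per-molecule true positions and states.

    ``frame_xyz`` holds the blur-averaged true 3D position per observed
    frame (NaN beyond a molecule's bleach frame); ``bound_frac`` the
    fraction of sub-frames spent DNA-bound within each frame.  When the
    simulation is run with ``keep_subframes=True`` the raw sub-frame
    positions and state labels are retained as well.
    """

    cell_index: np.ndarray          # (n,) geometry index per molecule
    activation_frame: np.ndarray    # (n,) first observed movie frame
    n_frames: np.ndarray            # (n,) observed frames before bleaching
    frame_xyz: np.ndarray           # (n, max_frames, 3)
    bound_frac: np.ndarray | None   # (n, max_frames) or None
    subframe_xyz: np.ndarray | None = None    # (n, max_frames * n_sub, 3)
    subframe_bound: np.ndarray | None = None  # (n, max_frames * n_sub)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        n, max_f, _ = self.frame_xyz.shape
        for i in range(n):
            for k in range(int(self.n_frames[i])):
                rows.append(
                    {
                        "molecule": i,
                        "cell_id": int(self.cell_index[i]),
                        "frame": int(self.activation_frame[i]) + k,
                        "x_um": self.frame_xyz[i, k, 0],
                        "y_um": self.frame_xyz[i, k, 1],
                        "z_um": self.frame_xyz[i, k, 2],
                        "state": (
                            "n/a"
                            if self.bound_frac is None
                            else ("bound" if self.bound_frac[i, k] >= 0.5 else "free")
                        ),
                    }
                )
        return pd.DataFrame(rows)


def _stack_geometries(geoms: list[CellGeometry]):
    """Concatenate segment tables so one searchsorted serves all cells.

    Each cell's axial range [0, L_c] is shifted by a distinct offset, so
    the concatenated segment-end array stays globally sorted and a single
    lookup returns the local boundary radius for every molecule at once.
    """
    lengths = np.array([g.length for g in geoms])
    spacing = lengths.max() + 10.0
    offsets = spacing * np.arange(len(geoms))
    ends = np.concatenate(
        [g.axial_end - g.axial_start[0] + off for g, off in zip(geoms, offsets)]
    )
    radii = np.concatenate([g.radius for g in geoms])
    return lengths, offsets, ends, radii


def _diffuse(
    pos: np.ndarray,
    bound: np.ndarray | None,
    cell_idx: np.ndarray,
    geoms: list[CellGeometry],
    motion: MotionModel,
    acq: AcquisitionModel,
    n_frames: int,
    rng: np.random.Generator,
    keep_subframes: bool = False,
):
    """Propagate molecules for ``n_frames`` frames; return blur-averaged positions.

    ``pos`` is (n, 3) in each cell's local coordinates (axial in [0, L]);
    modified in place.  Returns (frame_xyz, bound_frac, sub_xyz, sub_bound).
    """
    n = pos.shape[0]
    n_sub = acq.n_subframes
    dt = acq.subframe_interval
    lengths, offsets, ends_g, radii_g = _stack_geometries(geoms)
    L = lengths[cell_idx]
    off = offsets[cell_idx]

    sig_free = np.sqrt(2.0 * motion.d_free * dt)
    sig_bound = np.sqrt(2.0 * motion.d_bound * dt)

    switching = motion.switching_enabled and bound is not None
    if switching:
        a = 1.0 / motion.mean_t_bound                       # bound -> free rate
        if motion.mean_t_free == 0.0:
            p_bf = np.zeros(1)
            p_fb = np.ones(1)
        else:
            b = 1.0 / motion.mean_t_free                    # free -> bound rate
            decay = 1.0 - np.exp(-(a + b) * dt)
            p_bf = np.array([a / (a + b) * decay])          # P(free at t+dt | bound)
            p_fb = np.array([b / (a + b) * decay])

    frame_xyz = np.empty((n, n_frames, 3))
    bound_frac = np.empty((n, n_frames)) if switching else None
    sub_xyz = np.empty((n, n_frames * n_sub, 3)) if keep_subframes else None
    sub_bound = np.empty((n, n_frames * n_sub), dtype=bool) if keep_subframes else None

    two_L = 2.0 * L
    for f in range(n_frames):
        acc = np.zeros((n, 3))
        bacc = np.zeros(n) if switching else None
        for s in range(n_sub):
            if switching:
                sig = np.where(bound, sig_bound, sig_free)
                pos += rng.standard_normal((n, 3)) * sig[:, None]
                bacc += bound
            else:
                pos += rng.standard_normal((n, 3)) * sig_free
            # axial specular reflection into [0, L]
            m = np.mod(pos[:, 0], two_L)
            pos[:, 0] = np.minimum(m, two_L - m)
            # radial reflection at the local boundary radius
            idx = np.clip(np.searchsorted(ends_g, pos[:, 0] + off, side="left"),
                          0, radii_g.size - 1)
            R = radii_g[idx]
            r = np.hypot(pos[:, 1], pos[:, 2])
            over = r > R
            if np.any(over):
                ro, Ro = r[over], R[over]
                mr = np.mod(ro, 2.0 * Ro)
                rf = np.minimum(mr, 2.0 * Ro - mr)
                scale = rf / ro
                pos[over, 1] *= scale
                pos[over, 2] *= scale
            if switching:
                u = rng.uniform(size=n)
                bound = np.where(bound, u >= p_bf[0], u < p_fb[0])
            if keep_subframes:
                sub_xyz[:, f * n_sub + s, :] = pos
                if switching:
                    sub_bound[:, f * n_sub + s] = bound
            acc += pos
        frame_xyz[:, f, :] = acc / n_sub
        if switching:
            bound_frac[:, f] = bacc / n_sub
    return frame_xyz, bound_frac, sub_xyz, sub_bound


def _init_molecules(geoms, cell_idx, motion, rng):
    n = cell_idx.size
    pos = np.empty((n, 3))
    for c, g in enumerate(geoms):
        sel = np.flatnonzero(cell_idx == c)
        if sel.size:
            p = g.sample_uniform(sel.size, rng)
            p[:, 0] -= g.axial_start[0]  # local coordinates start at 0
            pos[sel] = p
    bound = None
    if motion.switching_enabled:
        bound = rng.uniform(size=n) < motion.phi  # stationary initial state
    return pos, bound


def simulate_tracks(
    motion: MotionModel,
    acq: AcquisitionModel,
    geom: CellGeometry | list[CellGeometry],
    n_molecules: int,
    seed: int | np.random.Generator = 0,
    keep_subframes: bool = False,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate sparse photoactivated tracks; return localizations + truth.

    Each molecule is activated at a uniformly random movie frame and
    observed for an exponential number of frames (mean ``bleach_mean``).
    The returned localization table has one row per molecule per observed
    frame with columns ``frame, x_um, y_um, cell_id, track_id``; x is the
    axial and y a transverse cell coordinate, with independent Gaussian
    localization error of ``sigma_loc`` added per axis.
    """
    if n_molecules < 1:
        raise ValueError("n_molecules must be >= 1")
    if isinstance(seed, np.random.Generator):
        rng = seed
    elif isinstance(seed, (int, np.integer)):
        rng = np.random.default_rng(seed)
    else:
        raise TypeError("seed must be an int or a numpy Generator")
    geoms = [geom] if isinstance(geom, CellGeometry) else list(geom)

    cell_idx = rng.integers(len(geoms), size=n_molecules)
    activation = rng.integers(acq.movie_frames, size=n_molecules)
    lifetime = rng.exponential(acq.bleach_mean, size=n_molecules)
    n_frames = np.ceil(lifetime / acq.frame_interval).astype(int)
    n_frames = np.maximum(n_frames, 1)
    n_frames = np.minimum(n_frames, acq.movie_frames - activation)  # movie end
    max_frames = int(n_frames.max())

    pos, bound = _init_molecules(geoms, cell_idx, motion, rng)
    frame_xyz, bound_frac, sub_xyz, sub_bound = _diffuse(
        pos, bound, cell_idx, geoms, motion, acq, max_frames, rng,
        keep_subframes=keep_subframes,
    )

    obs = frame_xyz[:, :, :2] + rng.normal(0.0, acq.sigma_loc, size=(n_molecules, max_frames, 2))

    frames_rel = np.arange(max_frames)
    valid = frames_rel[None, :] < n_frames[:, None]
    mol, rel = np.nonzero(valid)
    locs = pd.DataFrame(
        {
            "frame": activation[mol] + rel,
            "x_um": obs[mol, rel, 0],
            "y_um": obs[mol, rel, 1],
            "cell_id": cell_idx[mol],
            "track_id": mol,
        }
    ).sort_values(["frame", "x_um", "y_um"], kind="stable").reset_index(drop=True)

    # mask truth beyond each molecule's bleach frame
    masked = frame_xyz.copy()
    masked[~valid] = np.nan
    truth = GroundTruth(
        cell_index=cell_idx,
        activation_frame=activation,
        n_frames=n_frames,
        frame_xyz=masked,
        bound_frac=bound_frac,
        subframe_xyz=sub_xyz,
        subframe_bound=sub_bound,
    )
    return locs, truth


def simulate_dstar_values(
    motion: MotionModel,
    acq: AcquisitionModel,
    geoms: CellGeometry | list[CellGeometry],
    n_tracks: int,
    n_steps: int = 4,
    seed: int | np.random.Generator = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Apparent diffusion coefficients of ``n_tracks`` simulated tracks.

    Fast path for simulation-matching inference: only tracks long enough
    to yield a D* (``n_steps + 1`` localizations) contribute, and track
    displacement statistics are independent of the photobleaching time,
    so molecules are simulated for exactly ``n_steps + 1`` frames.
    Returns ``(dstar_values, cell_ids)``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    geoms = [geoms] if isinstance(geoms, CellGeometry) else list(geoms)
    cell_idx = rng.integers(len(geoms), size=n_tracks)
    pos, bound = _init_molecules(geoms, cell_idx, motion, rng)
    frame_xyz, _, _, _ = _diffuse(
        pos, bound, cell_idx, geoms, motion, acq, n_steps + 1, rng
    )
    obs = frame_xyz[:, :, :2] + rng.normal(
        0.0, acq.sigma_loc, size=(n_tracks, n_steps + 1, 2)
    )
    steps = np.diff(obs, axis=1)
    dstar = np.sum(steps**2, axis=(1, 2)) / (4.0 * n_steps * acq.frame_interval)
    return dstar, cell_idx
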