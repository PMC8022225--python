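"""Synthetic fluorescence movies and spot localization.

``render_movie`` turns ground-truth emitter positions into a synthetic
camera movie: each emitter is a 2D Gaussian point-spread function
integrated over the pixel grid, on a constant background, with Poisson
shot noise (EM gain and readout noise are not modelled — shot-noise-
limited images are sufficient to exercise the detection and fitting
logic).  ``detect_candidates`` finds spots by band-pass filtering
(difference of Gaussians) and thresholding; ``localize`` refines each
candidate with a nonlinear least-squares elliptical Gaussian fit whose
free parameters are x, y, x-width, y-width, rotation angle, intensity
and background.

Pixel convention: the centre of pixel (row i, col j) is at
((j + 0.5)·pixel_size, (i + 0.5)·pixel_size) in µm, x along columns.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.optimize import least_squares
from scipy.special import erf

from .models import AcquisitionModel

__all__ = ["FrameStack", "GaussianFitResult", "render_movie", "detect_candidates", "localize"]

log = logging.getLogger(__name__)


@dataclass
class FrameStack:
    """Multi-frame grayscale raster with its pixel size (µm)."""

    frames: np.ndarray  # (n_frames, n_rows, n_cols), photons
    pixel_size: float

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (frame, row, col) array")
        if np.any(self.frames < 0):
            raise ValueError("intensities must be non-negative")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    def save_tiff(self, path):
        import tifffile

        tifffile.imwrite(path, self.frames.astype(np.float32), photometric="minisblack")

    @classmethod
    def load_tiff(cls, path, pixel_size: float) -> "FrameStack":
        import tifffile

        return cls(np.asarray(tifffile.imread(path), dtype=float), pixel_size)


@dataclass
class GaussianFitResult:
    """Elliptical Gaussian fit of one spot (lengths in µm, photons)."""

    x: float
    y: float
    width_x: float
    width_y: float
    rotation_angle: float
    intensity: float
    background: float
    isotropic: bool = False  # widths indistinguishable: angle unidentifiable


def _integrated_gaussian(shape, x_px, y_px, sigma_px, photons):
    """Gaussian PSF integrated over pixels via erf differences."""
    rows, cols = shape
    xe = np.arange(cols + 1, dtype=float)
    ye = np.arange(rows + 1, dtype=float)
    s = sigma_px * np.sqrt(2.0)
    fx = 0.5 * (erf((xe[1:] - x_px) / s) - erf((xe[:-1] - x_px) / s))
    fy = 0.5 * (erf((ye[1:] - y_px) / s) - erf((ye[:-1] - y_px) / s))
    return photons * np.outer(fy, fx)


def render_movie(
    locs: pd.DataFrame,
    psf_sigma: float,
    photons_per_frame: float,
    background: float,
    acq: AcquisitionModel,
    shape: tuple[int, int] = (64, 64),
    n_frames: int | None = None,
    noise: bool = True,
    seed: int = 0,
) -> FrameStack:
    """Render a localization table into a synthetic movie.

    ``locs`` needs columns ``frame, x_um, y_um`` (positions in µm in the
    raster coordinate system).  Emitters outside the raster are clipped
    with a warning.  With ``noise=False`` the expected (Poisson-mean)
    image is returned.
    """
    if psf_sigma <= 0:
        raise ValueError("psf_sigma must be positive")
    if photons_per_frame < 0 or background < 0:
        raise ValueError("photon counts must be non-negative")
    rng = np.random.default_rng(seed)
    px = acq.pixel_size
    if n_frames is None:
        n_frames = int(locs["frame"].max()) + 1 if len(locs) else 1
    movie = np.full((n_frames, *shape), float(background))
    sigma_px = psf_sigma / px
    n_clipped = 0
    rows = (
        locs[["frame", "x_um", "y_um"]].itertuples(index=False) if len(locs) else ()
    )
    for frame, x_um, y_um in rows:
        f = int(frame)
        if not 0 <= f < n_frames:
            continue
        x_px, y_px = x_um / px, y_um / px
        if not (0 <= x_px < shape[1] and 0 <= y_px < shape[0]):
            n_clipped += 1
            continue
        movie[f] += _integrated_gaussian(shape, x_px, y_px, sigma_px, photons_per_frame)
    if n_clipped:
        log.warning("%d emitters outside the raster were clipped", n_clipped)
    if noise:
        movie = rng.poisson(movie).astype(float)
    return FrameStack(movie, px)


def detect_candidates(
    stack: FrameStack,
    bandpass_low: float = 1.0,
    bandpass_high: float = 3.0,
    threshold: float = 5.0,
) -> list[np.ndarray]:
    """Band-pass spot detection: difference of Gaussians + threshold.

    Returns, per frame, an (n, 2) array of candidate (row, col) pixel
    positions — one per connected suprathreshold region (its maximum).
    """
    if bandpass_low >= bandpass_high:
        raise ValueError("bandpass_low must be smaller than bandpass_high")
    if stack.n_frames == 0:
        raise ValueError("empty stack")
    out = []
    for frame in stack.frames:
        dog = ndimage.gaussian_filter(frame, bandpass_low) - ndimage.gaussian_filter(
            frame, bandpass_high
        )
        mask = dog > threshold
        labels, n_lab = ndimage.label(mask)
        if n_lab == 0:
            out.append(np.empty((0, 2), dtype=int))
            continue
        peaks = ndimage.maximum_position(dog, labels, index=range(1, n_lab + 1))
        out.append(np.array(peaks, dtype=int))
    return out


def _elliptical_gaussian(params, yy, xx):
    x0, y0, sx, sy, theta, amp, bg = params
    ct, st = np.cos(theta), np.sin(theta)
    xr = (xx - x0) * ct + (yy - y0) * st
    yr = -(xx - x0) * st + (yy - y0) * ct
    return bg + amp * np.exp(-0.5 * ((xr / sx) ** 2 + (yr / sy) ** 2))


def localize(
    stack: FrameStack,
    candidates: list[np.ndarray],
    window: int = 7,
) -> tuple[pd.DataFrame, list[GaussianFitResult]]:
    """Elliptical Gaussian fits around candidate pixels.

    Returns a localization table (``frame, x_um, y_um``) plus the full
    fit descriptors.  Non-converged fits are dropped and logged.
    """
    if window < 5 or window % 2 == 0:
        raise ValueError("window must be odd and >= 5")
    half = window // 2
    px = stack.pixel_size
    rows_out, fits = [], []
    n_failed = 0
    for f, cand in enumerate(candidates):
        img = stack.frames[f]
        for r, c in np.atleast_2d(cand):
            r0, r1 = max(0, r - half), min(img.shape[0], r + half + 1)
            c0, c1 = max(0, c - half), min(img.shape[1], c + half + 1)
            sub = img[r0:r1, c0:c1]
            yy, xx = np.mgrid[r0:r1, c0:c1]
            bg0 = float(sub.min())
            amp0 = float(sub.max() - bg0)
            if amp0 <= 0:
                n_failed += 1
                continue
            p0 = [float(c), float(r), 1.2, 1.2, 0.0, amp0, bg0]
            try:
                res = least_squares(
                    lambda p: (_elliptical_gaussian(p, yy, xx) - sub).ravel(),
                    p0,
                    bounds=(
                        [c0 - 1, r0 - 1, 0.3, 0.3, -np.pi, 0.0, 0.0],
                        [c1, r1, window, window, np.pi, np.inf, np.inf],
                    ),
                    max_nfev=200,
                )
            except Exception:
                n_failed += 1
                continue
            if not res.success:
                n_failed += 1
                continue
            x0, y0, sx, sy, theta, amp, bg = res.x
            iso = abs(sx - sy) < 0.05 * max(sx, sy)
            fits.append(
                GaussianFitResult(
                    x=(x0 + 0.5) * px,
                    y=(y0 + 0.5) * px,
                    width_x=sx * px,
                    width_y=sy * px,
                    rotation_angle=float(theta),
                    intensity=float(2 * np.pi * amp * sx * sy),
                    background=float(bg),
                    isotropic=bool(iso),
                )
            )
            rows_out.append({"frame": f, "x_um": (x0 + 0.5) * px, "y_um": (y0 + 0.5) * px})
    if n_failed:
        log.info("%d candidate fits dropped (no convergence)", n_failed)
    return pd.DataFrame(rows_out, columns=["frame", "x_um", "y_um"]), fits
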