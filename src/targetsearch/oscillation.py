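"""Kymograph analysis of pole-to-pole protein oscillations.

The Min system oscillates from pole to pole; in filamentous cells it
forms a standing wave.  A kymograph stacks per-frame one-dimensional
fluorescence profiles along the long cell axis; per-frame normalization
to total fluorescence removes photobleaching.  The oscillation period is
obtained by fitting the integrated intensity of a cell half with
F(t) = a·cos(ωt) + b·sin(ωt), and the wavelength from the spacing of
minima of the time-averaged profile.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, signal
from scipy.optimize import minimize_scalar

__all__ = [
    "Kymograph",
    "OscillationResult",
    "build_kymograph",
    "half_cell_signals",
    "fit_period",
    "wavelength_from_profile",
    "NoOscillationError",
]


class NoOscillationError(ValueError):
    """Raised when no significant oscillation is detected."""


@dataclass
class Kymograph:
    """Space-time intensity map f(x, t).

    ``intensity`` has one row per frame; ``x`` are axial positions (µm)
    over the cell length L and ``times`` the frame times (s).
    """

    intensity: np.ndarray  # (n_frames, n_positions)
    x: np.ndarray          # µm
    times: np.ndarray      # s
    normalized: bool = True

    @property
    def length(self) -> float:
        return float(self.x[-1] - self.x[0])

    def time_average(self) -> np.ndarray:
        """Time-averaged profile F_t(x)."""
        return self.intensity.mean(axis=0)


@dataclass
class OscillationResult:
    """Fitted oscillation: period T (s), ω = 2π/T, and quadrature amplitudes."""

    period: float
    omega: float
    a: float
    b: float

    @property
    def amplitude(self) -> float:
        return float(np.hypot(self.a, self.b))


def build_kymograph(profiles, times=None, length: float | None = None,
                    normalize: bool = True) -> Kymograph:
    """Stack per-frame 1D intensity profiles into a kymograph.

    ``profiles`` is (n_frames, n_positions); all frames must have equal
    length and there must be at least 4 of them.  With ``normalize=True``
    every frame is divided by its total intensity, which removes any
    time-dependent global factor such as photobleaching.
    """
    arr = np.asarray(profiles, dtype=float)
    if arr.ndim != 2:
        raise ValueError("profiles must be a 2D (frame, position) array of equal-length rows")
    if arr.shape[0] < 4:
        raise ValueError("need at least 4 frames")
    if normalize:
        totals = arr.sum(axis=1, keepdims=True)
        if np.any(totals <= 0):
            raise ValueError("cannot normalize frames with non-positive total intensity")
        arr = arr / totals
    n_t, n_x = arr.shape
    times = np.arange(n_t, dtype=float) if times is None else np.asarray(times, float)
    if times.size != n_t:
        raise ValueError("times must match the number of frames")
    L = float(length) if length is not None else float(n_x)
    x = np.linspace(0.0, L, n_x)
    return Kymograph(arr, x, times, normalized=normalize)


def half_cell_signals(k: Kymograph) -> tuple[np.ndarray, np.ndarray]:
    """Integrated intensity of the two cell halves per frame.

    F_left(t) = ∫_0^{L/2} f(x,t) dx and F_right(t) = ∫_{L/2}^L f(x,t) dx,
    by trapezoidal quadrature with the midpoint shared (so that
    F_left + F_right equals the integral over the whole cell).
    """
    mid = k.x[0] + k.length / 2.0
    xl = np.append(k.x[k.x < mid], mid)
    xr = np.insert(k.x[k.x > mid], 0, mid)
    f_mid = np.array([np.interp(mid, k.x, row) for row in k.intensity])
    left = np.array(
        [np.trapezoid(np.append(row[k.x < mid], fm), xl)
         for row, fm in zip(k.intensity, f_mid)]
    )
    right = np.array(
        [np.trapezoid(np.insert(row[k.x > mid], 0, fm), xr)
         for row, fm in zip(k.intensity, f_mid)]
    )
    return left, right


def _quadrature_fit(times, trace, omega):
    """Solve a, b of a·cos(ωt) + b·sin(ωt) by linear least squares."""
    design = np.column_stack([np.cos(omega * times), np.sin(omega * times)])
    coef, res, _, _ = np.linalg.lstsq(design, trace, rcond=None)
    pred = design @ coef
    return coef, float(np.sum((trace - pred) ** 2))


def fit_period(
    times,
    trace,
    period_range: tuple[float, float] = (4.0, 200.0),
    min_r2: float = 0.2,
) -> OscillationResult:
    """Fit F(t) = a·cos(ωt) + b·sin(ωt) to a (mean-subtracted) half-cell trace.

    ω is found by a coarse scan over the period range followed by local
    bounded refinement; a and b are solved linearly at each ω.  Raises
    :class:`NoOscillationError` when the best fit explains less than
    ``min_r2`` of the trace variance (amplitude below noise).
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(trace, dtype=float)
    if t.size != y.size or t.size < 8:
        raise ValueError("need >= 8 samples spanning >= 2 putative periods")
    y = y - y.mean()
    total_ss = float(np.sum(y**2))
    if total_ss == 0:
        raise NoOscillationError("constant trace: no oscillation detected")
    span = t[-1] - t[0]
    p_lo, p_hi = period_range
    p_hi = min(p_hi, span / 2.0)  # demand at least 2 full periods of data
    if p_hi <= p_lo:
        raise ValueError("time span too short for the requested period range")

    periods = np.linspace(p_lo, p_hi, 400)
    omegas = 2.0 * np.pi / periods
    rss = np.array([_quadrature_fit(t, y, w)[1] for w in omegas])
    k = int(np.argmin(rss))
    w_lo = omegas[min(k + 1, omegas.size - 1)]
    w_hi = omegas[max(k - 1, 0)]
    if w_lo < w_hi:
        res = minimize_scalar(
            lambda w: _quadrature_fit(t, y, w)[1], bounds=(w_lo, w_hi), method="bounded"
        )
        omega = float(res.x)
    else:
        omega = float(omegas[k])
    (a, b), best_rss = _quadrature_fit(t, y, omega)
    r2 = 1.0 - best_rss / total_ss
    if r2 < min_r2:
        raise NoOscillationError(f"no significant oscillation (R² = {r2:.2f})")
    return OscillationResult(period=2.0 * np.pi / omega, omega=omega, a=float(a), b=float(b))


def wavelength_from_profile(
    k: Kymograph,
    filamentous: bool = True,
    smooth_um: float = 0.2,
) -> float:
    """Oscillation wavelength from the time-averaged profile.

    λ = (1/n) Σ (x_min,i+1 − x_min,i): the mean spacing of consecutive
    minima of F_t(x) (filamentous standing-wave mode); with
    ``filamentous=False`` the spacing of maxima is used instead.  The
    profile is lightly smoothed before extremum detection.  Invariant to
    uniform intensity scaling.
    """
    profile = k.time_average()
    dx = k.x[1] - k.x[0]
    if smooth_um > 0:
        profile = ndimage.gaussian_filter1d(profile, smooth_um / dx, mode="nearest")
    target = -profile if filamentous else profile
    peaks, _ = signal.find_peaks(target)
    if peaks.size < 2:
        raise ValueError(
            "insufficient extrema: need at least 2 "
            + ("minima" if filamentous else "peaks")
            + " in the time-averaged profile"
        )
    return float(np.mean(np.diff(k.x[peaks])))
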