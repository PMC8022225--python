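"""Physical ground-truth and acquisition parameter containers.

``MotionModel`` describes the molecule: its free diffusion coefficient,
the apparent coefficient while bound to chromosomal DNA (slow constrained
DNA motion, 0.04 µm²/s by default), and — when two-state interconversion
is enabled — the mean exponential dwell times in each state.  The bound
time fraction Φ = t_bound / (t_bound + t_free) is the stationary fraction
of time spent DNA-bound.

``AcquisitionModel`` describes the camera and photophysics: frame
interval (15.48 ms by default; 5.48 ms for the fast acquisition mode),
sub-frames per frame for motion blur, localization error σ_loc = 35 nm,
exponential photobleaching lifetime 85 ms, and 96 nm pixels.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

__all__ = ["MotionModel", "AcquisitionModel"]


@dataclass(frozen=True)
class MotionModel:
    """Ground-truth motion parameters (µm²/s, s)."""

    d_free: float
    d_bound: float = 0.04
    switching_enabled: bool = False
    mean_t_bound: float | None = None
    mean_t_free: float | None = None

    def __post_init__(self):
        if self.d_free < 0 or self.d_bound < 0:
            raise ValueError("diffusion coefficients must be non-negative")
        if self.switching_enabled:
            if self.d_free < self.d_bound:
                raise ValueError("d_free must be >= d_bound when switching")
            if self.mean_t_bound is None or self.mean_t_free is None:
                raise ValueError("switching requires both mean dwell times")
            if self.mean_t_bound <= 0 or self.mean_t_free < 0:
                raise ValueError("dwell means must be positive")

    @property
    def phi(self) -> float:
        """Stationary bound-time fraction t_b / (t_b + t_f)."""
        if not self.switching_enabled:
            return 0.0
        return self.mean_t_bound / (self.mean_t_bound + self.mean_t_free)

    @classmethod
    def from_phi(
        cls,
        d_free: float,
        phi: float,
        d_bound: float = 0.04,
        mean_t_bound: float = 0.001,
    ) -> "MotionModel":
        """Build a switching model from Φ and the mean bound dwell time.

        Only the ratio of dwell times is identifiable from apparent
        diffusion data; t_bound anchors the (sub-frame) exchange timescale.
        """
        if not 0.0 <= phi <= 1.0:
            raise ValueError("phi must lie in [0, 1]")
        if phi >= 1.0:
            # never free: infinite bound dwell is the clean limit
            return cls(d_free=d_free, d_bound=d_bound, switching_enabled=True,
                       mean_t_bound=mean_t_bound, mean_t_free=0.0)
        mean_t_free = mean_t_bound * (1.0 - phi) / max(phi, 1e-12)
        return cls(d_free=d_free, d_bound=d_bound, switching_enabled=True,
                   mean_t_bound=mean_t_bound, mean_t_free=mean_t_free)


@dataclass(frozen=True)
class AcquisitionModel:
    """Camera and photophysics parameters (s, µm)."""

    frame_interval: float = 0.01548
    n_subframes: int = 100
    sigma_loc: float = 0.035
    bleach_mean: float = 0.085
    movie_frames: int = 10_000
    pixel_size: float = 0.096

    def __post_init__(self):
        if min(self.frame_interval, self.bleach_mean, self.pixel_size) <= 0:
            raise ValueError("time and length scales must be positive")
        if self.sigma_loc < 0:
            raise ValueError("sigma_loc must be non-negative")
        if self.n_subframes < 1 or self.movie_frames < 1:
            raise ValueError("counts must be >= 1")

    @property
    def subframe_interval(self) -> float:
        return self.frame_interval / self.n_subframes

    def with_(self, **kwargs) -> "AcquisitionModel":
        return replace(self, **kwargs)
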