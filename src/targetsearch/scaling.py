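"""Mass scaling of free diffusion in chromosome-free cells.

In cells devoid of chromosomal DNA the diffusion coefficient of
DNA-binding proteins shows a steep inverse dependence on molecular
weight, D_free = c·Mᵅ, much steeper than the Stokes–Einstein prediction
(α = −1/3) — the crowded cytoplasm sieves by size even without the DNA
mesh.  The exponent is obtained by ordinary least squares of log10(D) on
log10(M); the fitted law extrapolates D_free for proteins that were not
measured in chromosome-free cells.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ScalingFit", "fit_power_law", "predict_dfree", "STOKES_EINSTEIN_ALPHA"]

STOKES_EINSTEIN_ALPHA = -1.0 / 3.0


@dataclass
class ScalingFit:
    """Power law D = c·Mᵅ fitted in log-log space.

    ``alpha`` is the exponent (OLS slope), ``intercept`` the log10-space
    intercept; ``c`` re-expresses the fit in the D = (c·M)ᵅ
    parameterization (c = 10^(intercept/alpha)).
    """

    alpha: float
    intercept: float
    masses: np.ndarray
    d_values: np.ndarray

    @property
    def c(self) -> float:
        return float(10.0 ** (self.intercept / self.alpha))

    @property
    def residuals(self) -> np.ndarray:
        return np.log10(self.d_values) - (self.alpha * np.log10(self.masses) + self.intercept)

    def predict(self, mass_kda) -> np.ndarray | float:
        m = np.asarray(mass_kda, dtype=float)
        if np.any(m <= 0):
            raise ValueError("mass must be positive")
        out = 10.0 ** (self.alpha * np.log10(m) + self.intercept)
        return float(out) if out.ndim == 0 else out


def fit_power_law(pairs) -> ScalingFit:
    """Fit D = c·Mᵅ to (mass_kDa, D_µm²/s) pairs by log-log OLS."""
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 2:
        raise ValueError("need at least two (mass, D) pairs")
    if np.any(arr <= 0):
        raise ValueError("masses and diffusion coefficients must be positive")
    if np.unique(arr[:, 0]).size < 2:
        raise ValueError("need at least two distinct masses")
    logm, logd = np.log10(arr[:, 0]), np.log10(arr[:, 1])
    alpha, intercept = np.polyfit(logm, logd, 1)
    return ScalingFit(float(alpha), float(intercept), arr[:, 0], arr[:, 1])


def predict_dfree(mass_kda: float, fit: ScalingFit) -> float:
    """Evaluate the fitted power law at ``mass_kda`` (value on the line)."""
    return float(fit.predict(mass_kda))
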