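"""Height-normalized Gaussian, Lorentzian, and Voigt line shapes.

All three are parameterized by peak height (amplitude = value at the
center), not by area, so a profile can be initialized directly from a
detected peak's intensity.  Areas follow from the parameters if needed:
A*sigma*sqrt(2*pi) for a Gaussian, A*pi*gamma for a Lorentzian.

* Gaussian:    A * exp(-(x-c)^2 / (2 sigma^2))
* Lorentzian:  A * gamma^2 / ((x-c)^2 + gamma^2)   (half height at c +/- gamma)
* Voigt:       convolution of the two, evaluated with the scaled complex
               error function (Faddeeva w) and rescaled so its value at
               the center equals A.  It reduces to the Gaussian as
               gamma -> 0 and to the Lorentzian as sigma -> 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import wofz

__all__ = ["ProfileParams", "profile_eval", "model_sum", "FAMILIES"]

FAMILIES = ("gaussian", "lorentzian", "voigt")

# below these widths the Voigt switches to its exact limiting form to
# avoid cancellation in wofz
_VOIGT_SIGMA_FLOOR = 1e-10
_VOIGT_GAMMA_FLOOR = 1e-14


@dataclass(frozen=True)
class ProfileParams:
    """Parameters of one line-shape component.

    ``sigma`` is the Gaussian standard deviation (unused for a pure
    Lorentzian), ``gamma`` the Lorentzian half-width at half-maximum
    (unused for a pure Gaussian); both in x units.
    """

    family: str
    center: float
    amplitude: float
    sigma: float | None = None
    gamma: float | None = None

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(
                f"unknown family {self.family!r}: expected one of {FAMILIES}"
            )
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if self.family in ("gaussian", "voigt"):
            if self.sigma is None or self.sigma <= 0:
                raise ValueError(f"{self.family} needs sigma > 0")
        if self.family in ("lorentzian", "voigt"):
            if self.gamma is None or self.gamma <= 0:
                raise ValueError(f"{self.family} needs gamma > 0")

    @property
    def fwhm(self) -> float:
        """Full width at half maximum implied by the parameters."""
        if self.family == "gaussian":
            return 2.0 * np.sqrt(2.0 * np.log(2.0)) * self.sigma
        if self.family == "lorentzian":
            return 2.0 * self.gamma
        # Olivero-Longbothum approximation, accurate to ~0.02%
        fg = 2.0 * np.sqrt(2.0 * np.log(2.0)) * self.sigma
        fl = 2.0 * self.gamma
        return 0.5346 * fl + np.sqrt(0.2166 * fl * fl + fg * fg)


def _voigt_shape(dx: np.ndarray, sigma: float, gamma: float) -> np.ndarray:
    """Voigt profile normalized to 1 at dx = 0."""
    if sigma <= _VOIGT_SIGMA_FLOOR:
        return gamma * gamma / (dx * dx + gamma * gamma)
    if gamma <= _VOIGT_GAMMA_FLOOR:
        return np.exp(-dx * dx / (2.0 * sigma * sigma))
    denom = sigma * np.sqrt(2.0)
    z = (dx + 1j * gamma) / denom
    peak = wofz(1j * gamma / denom).real
    return wofz(z).real / peak


def profile_eval(p: ProfileParams, x: np.ndarray) -> np.ndarray:
    """Evaluate one component on ``x``; the value at the center is the
    amplitude."""
    x = np.asarray(x, dtype=float)
    dx = x - p.center
    if p.family == "gaussian":
        return p.amplitude * np.exp(-dx * dx / (2.0 * p.sigma * p.sigma))
    if p.family == "lorentzian":
        g2 = p.gamma * p.gamma
        return p.amplitude * g2 / (dx * dx + g2)
    return p.amplitude * _voigt_shape(dx, p.sigma, p.gamma)


def model_sum(components, x: np.ndarray) -> np.ndarray:
    """Elementwise sum of all components evaluated on ``x``."""
    x = np.asarray(x, dtype=float)
    total = np.zeros_like(x)
    for comp in components:
        total += profile_eval(comp, x)
    return total
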