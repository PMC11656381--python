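"""Decompose a detrended signal into a sum of line-shape components.

Each detected peak seeds one Gaussian, Lorentzian, or Voigt component;
all component parameters (center, height, width(s)) are then optimized
jointly by robust nonlinear least squares so that the component sum
reproduces the signal.  The objective is

    S = sum_i rho(r_i^2),   r = model(x) - s_hat(x)

with rho one of the robust losses ``linear`` (plain sum of squares),
``soft_l1``, ``huber``, or ``arctan``.  The robust losses down-weight
large residuals, which keeps a few badly modeled points (residual
baseline, cosmic spikes) from distorting every component.

Centers are softly bounded to the detection window around each peak to
prevent components from swapping places during optimization; pass
``free_centers=True`` to lift the bounds.  Optimization is deterministic
(no random restarts): the same inputs give the same decomposition.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .peaks import PeakSet
from .profiles import FAMILIES, ProfileParams, model_sum
from .spectrum import Spectrum

__all__ = ["Decomposition", "LOSSES", "cost", "fit"]

LOSSES = ("linear", "soft_l1", "huber", "arctan")

_WIDTH_FLOOR_STEPS = 2.0    # width init lower clip, in grid steps
_WIDTH_CAP_FRACTION = 0.1   # width init upper clip, fraction of x-span


@dataclass
class Decomposition:
    """Fitted component list plus the final objective value."""

    components: list[ProfileParams]
    family: str
    loss: str
    cost: float
    n_iter: int
    reconstruction: np.ndarray
    success: bool = True
    message: str = ""

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "loss": self.loss,
            "cost": self.cost,
            "n_iter": self.n_iter,
            "components": [
                {
                    "family": c.family,
                    "center": c.center,
                    "amplitude": c.amplitude,
                    "sigma": c.sigma,
                    "gamma": c.gamma,
                }
                for c in self.components
            ],
        }

    def save_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_dict(cls, d: dict) -> "Decomposition":
        comps = [
            ProfileParams(
                family=c["family"], center=c["center"],
                amplitude=c["amplitude"], sigma=c.get("sigma"),
                gamma=c.get("gamma"),
            )
            for c in d["components"]
        ]
        return cls(
            components=comps, family=d["family"], loss=d["loss"],
            cost=d.get("cost", np.nan), n_iter=d.get("n_iter", 0),
            reconstruction=np.empty(0),
        )


def _rho(u: np.ndarray, loss: str) -> np.ndarray:
    """Robust loss applied to squared residuals (scale fixed at 1)."""
    if loss == "linear":
        return u
    if loss == "soft_l1":
        return 2.0 * (np.sqrt(1.0 + u) - 1.0)
    if loss == "huber":
        return np.where(u <= 1.0, u, 2.0 * np.sqrt(u) - 1.0)
    if loss == "arctan":
        return np.arctan(u)
    raise ValueError(f"unknown loss {loss!r}: expected one of {LOSSES}")


def cost(components, s_hat: np.ndarray, x: np.ndarray, loss: str) -> float:
    """Objective value S for a given component list."""
    r = model_sum(components, x) - np.asarray(s_hat, dtype=float)
    return float(np.sum(_rho(r * r, loss)))


def _n_params(family: str) -> int:
    return 4 if family == "voigt" else 3


def _pack(components) -> np.ndarray:
    theta = []
    for c in components:
        theta.extend([c.center, c.amplitude])
        if c.family in ("gaussian", "voigt"):
            theta.append(c.sigma)
        if c.family in ("lorentzian", "voigt"):
            theta.append(c.gamma)
    return np.array(theta)

def _unpack(theta: np.ndarray, family: str) -> list[ProfileParams]:
    k = _n_params(family)
    comps = []
    for j in range(0, theta.size, k):
        c, a = theta[j], theta[j + 1]
        if family == "gaussian":
            comps.append(ProfileParams(family, c, max(a, 0.0),
                                       sigma=theta[j + 2]))
        elif family == "lorentzian":
            comps.append(ProfileParams(family, c, max(a, 0.0),
                                       gamma=theta[j + 2]))
        else:
            comps.append(ProfileParams(family, c, max(a, 0.0),
                                       sigma=theta[j + 2],
                                       gamma=theta[j + 3]))
    return comps


def _estimate_fwhm(s_hat: Spectrum, index: int) -> float:
    """Width of the half-maximum crossing around a detected peak.

    Scans outward from the peak until the intensity drops below half the
    peak value or starts rising again (an overlapping neighbor); the
    sum of the two arm lengths approximates the FWHM.
    """
    y = s_hat.y
    half = 0.5 * y[index]
    n = y.size
    left = index
    while left > 0 and y[left - 1] >= half and y[left - 1] <= y[left]:
        left -= 1
    right = index
    while right < n - 1 and y[right + 1] >= half and y[right + 1] <= y[right]:
        right += 1
    return float(s_hat.x[right] - s_hat.x[left])


def _initial_components(s_hat: Spectrum, peaks: PeakSet,
                        family: str) -> list[ProfileParams]:
    """Seed one component per peak.

    Centers and heights come from the detection; the width scale is the
    measured half-maximum width around each peak, clipped between 2 grid
    steps and 10% of the x-span.
    """
    h = s_hat.grid_step()
    span = s_hat.span
    comps = []
    for p in peaks:
        w = _estimate_fwhm(s_hat, p.index)
        w = float(np.clip(w, _WIDTH_FLOOR_STEPS * h,
                          _WIDTH_CAP_FRACTION * span))
        amp = max(p.amplitude, 0.0)
        if family == "gaussian":
            comps.append(ProfileParams(family, p.x, amp,
                                       sigma=w / 2.3548))
        elif family == "lorentzian":
            comps.append(ProfileParams(family, p.x, amp, gamma=w / 2.0))
        else:
            comps.append(ProfileParams(family, p.x, amp,
                                       sigma=w / (2.0 * 2.3548),
                                       gamma=w / 4.0))
    return comps


def fit(
    s_hat: Spectrum,
    peaks: PeakSet,
    family: str = "gaussian",
    loss: str = "linear",
    max_iter: int = 100,
    warm_start: Decomposition | None = None,
    free_centers: bool = False,
) -> Decomposition:
    """Fit the component sum to the detrended signal.

    ``max_iter`` bounds the optimizer's function evaluations, so a call
    may stop before convergence; pass the returned object back through
    ``warm_start`` to continue from where it left off (the cost sequence
    across chained calls is non-increasing).
    """
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}: expected {FAMILIES}")
    if loss not in LOSSES:
        raise ValueError(f"unknown loss {loss!r}: expected {LOSSES}")
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")
    if len(peaks) < 1:
        raise ValueError("decomposition needs at least one peak")

    if warm_start is not None:
        init = warm_start.components
        if len(init) != len(peaks):
            raise ValueError(
                "warm_start component count does not match the peak set"
            )
    else:
        init = _initial_components(s_hat, peaks, family)

    x, y = s_hat.x, s_hat.y
    h = s_hat.grid_step()
    theta0 = _pack(init)
    k = _n_params(family)

    lo = np.full(theta0.size, -np.inf)
    hi = np.full(theta0.size, np.inf)
    halfwin = max(peaks.window_size, 1) * h
    width_floor = 1e-6 * h
    for j in range(len(init)):
        base = j * k
        if not free_centers:
            lo[base] = theta0[base] - halfwin
            hi[base] = theta0[base] + halfwin
        lo[base + 1] = 0.0                      # amplitude >= 0
        for w_off in range(2, k):
            lo[base + w_off] = width_floor      # widths > 0
    theta0 = np.clip(theta0, lo, hi)

    def residuals(theta: np.ndarray) -> np.ndarray:
        return model_sum(_unpack(theta, family), x) - y

    result = least_squares(
        residuals,
        theta0,
        bounds=(lo, hi),
        loss=loss,
        f_scale=1.0,
        max_nfev=max_iter,
        method="trf",
    )
    if not np.isfinite(result.cost):
        raise FloatingPointError(
            f"optimizer produced non-finite cost; last parameters: "
            f"{result.x.tolist()}"
        )
    comps = _unpack(result.x, family)
    recon = model_sum(comps, x)
    return Decomposition(
        components=comps,
        family=family,
        loss=loss,
        cost=cost(comps, y, x, loss),
        n_iter=int(result.nfev),
        reconstruction=recon,
        success=bool(result.success),
        message=str(result.message),
    )
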