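"""Baseline estimation and detrending: linear, airPLS, and arPLS.

A baseline is a slowly varying additive bias ``z`` under the signal
``s``; subtracting it aligns the spectrum's featureless regions with the
x-axis so that peak heights and areas become meaningful.  The two
penalized-least-squares (PLS, Whittaker-smoother) variants estimate z by
minimizing

    sum_i w_i (s_i - z_i)^2  +  lam * ||D z||^2

where D is the second-order difference matrix and W = diag(w) holds
per-point weights.  They differ only in how the weights are re-estimated
between iterations:

* airPLS zeroes the weight wherever the signal sits above the current
  baseline (protecting peaks) and grows the remaining weights
  exponentially with the iteration count, so the baseline is pulled down
  into the troughs.
* arPLS computes the mean mu and standard deviation sigma of the
  negative residuals and passes each residual through a logistic
  function centered at 2*sigma - mu, which saturates at weight 1 for
  points at or above the baseline.  The detrended signal comes out
  primarily positive, which matches the physical expectation for
  emission/absorption spectra.

The linear method simply draws the chord from the first to the last
sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import spsolve

from .spectrum import Spectrum

__all__ = [
    "BaselineResult",
    "difference_matrix",
    "linear_baseline",
    "pls_solve",
    "airpls",
    "arpls",
    "detrend",
]

# exp() saturates rather than overflows
_EXP_CLIP = 500.0


@dataclass
class BaselineResult:
    """Estimated baseline plus solver diagnostics."""

    z: np.ndarray
    method: str
    lam: float = 0.0
    ratio: float = 0.0
    n_iter: int = 0
    converged: bool = True
    weights: np.ndarray = field(default_factory=lambda: np.empty(0))
    diagnostics: dict = field(default_factory=dict)


def difference_matrix(n: int) -> sp.csc_matrix:
    """Second-order difference operator D of shape (n-2, n).

    Row i carries the stencil (1, -2, 1) at columns (i, i+1, i+2), so
    D @ v is the discrete second difference of v; constants and linear
    ramps lie in its null space.
    """
    if n < 3:
        raise ValueError(f"difference matrix needs n >= 3, got {n}")
    return sp.diags(
        [np.ones(n - 2), -2.0 * np.ones(n - 2), np.ones(n - 2)],
        offsets=[0, 1, 2],
        shape=(n - 2, n),
        format="csc",
    )


def linear_baseline(s: Spectrum) -> BaselineResult:
    """Straight line through the first and last sample."""
    x, y = s.x, s.y
    slope = (y[-1] - y[0]) / (x[-1] - x[0])
    z = y[0] + slope * (x - x[0])
    return BaselineResult(z=z, method="linear")


def pls_solve(s: np.ndarray, weights: np.ndarray, lam: float) -> np.ndarray:
    """Solve the penalized weighted least-squares system for the baseline.

    Returns the minimizer of ``sum w_i (s_i - z_i)^2 + lam ||D z||^2``,
    i.e. the solution of ``(W + lam D'D) z = W s`` with W = diag(weights),
    via a sparse pentadiagonal solve.
    """
    s = np.asarray(s, dtype=float)
    w = np.asarray(weights, dtype=float)
    n = s.size
    if n < 3:
        raise ValueError("pls_solve needs at least 3 samples")
    if lam <= 0:
        raise ValueError(f"lam must be positive, got {lam}")
    if np.any(w < 0):
        raise ValueError("weights must be non-negative")
    # Split off the weighted affine fit a(x): D annihilates it exactly, so
    # z = a + A^{-1} W (s - a) is algebraically identical but keeps the
    # solve's right-hand side at residual scale.  Without the split the
    # affine component is carried through a system whose condition number
    # grows with lam, and the lam -> inf limit (the least-squares line)
    # drowns in rounding error.
    t = np.arange(n) - (n - 1) / 2.0
    sw = np.sqrt(w)
    X = np.column_stack([sw, sw * t])
    coef, *_ = np.linalg.lstsq(X, sw * s, rcond=None)
    a = coef[0] + coef[1] * t
    if not np.all(np.isfinite(a)):
        a = np.zeros(n)

    D = difference_matrix(n)
    A = sp.diags(w) + lam * (D.T @ D)
    z = a + spsolve(A.tocsc(), w * (s - a))
    if not np.all(np.isfinite(z)):
        raise FloatingPointError("singular penalized least-squares system")
    return z


def airpls(
    s: np.ndarray,
    lam: float = 200.0,
    ratio: float = 1e-6,
    max_iter: int = 50,
) -> BaselineResult:
    """Adaptive iteratively reweighted PLS baseline.

    Weights are zero where the signal is at or above the current
    baseline and grow exponentially with the iteration count ``t`` where
    it dips below:  w_i = exp(t * |d_i| / ||d||_1)  with d the negative
    part of s - z.  Iteration stops when ||d||_1 < ratio * ||s||_1.
    """
    s = np.asarray(s, dtype=float)
    n = s.size
    if not 0 < ratio < 1:
        raise ValueError(f"ratio must be in (0, 1), got {ratio}")
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")
    w = np.ones(n)
    z = np.zeros(n)
    abs_s = np.abs(s).sum()
    converged = False
    history: list[float] = []
    t = 0
    for t in range(1, max_iter + 1):
        z = pls_solve(s, w, lam)
        d = s - z
        neg = d < 0
        dssn = np.abs(d[neg]).sum()
        history.append(float(dssn))
        if not np.all(np.isfinite(z)):
            raise FloatingPointError(f"non-finite baseline at iteration {t}")
        if dssn <= ratio * abs_s or dssn == 0.0:
            converged = True
            break
        w = np.zeros(n)
        w[neg] = np.exp(np.clip(t * np.abs(d[neg]) / dssn, None, _EXP_CLIP))
        # anchor the endpoints so the exponential reweighting cannot let
        # the baseline drift free at the edges
        w[0] = np.exp(np.clip(t * np.abs(d[neg]).max() / dssn, None, _EXP_CLIP))
        w[-1] = w[0]
    return BaselineResult(
        z=z,
        method="airpls",
        lam=lam,
        ratio=ratio,
        n_iter=t,
        converged=converged,
        weights=w,
        diagnostics={"neg_residual_l1": history},
    )


def arpls(
    s: np.ndarray,
    lam: float = 200.0,
    ratio: float = 1e-6,
    max_iter: int = 50,
) -> BaselineResult:
    """Asymmetrically reweighted PLS baseline.

    Each iteration computes d = s - z, takes the mean ``mu`` and standard
    deviation ``sigma`` of the negative part of d, and sets logistic
    weights

        w_i = 1 / (1 + exp(2 (d_i - (2 sigma - mu)) / sigma))

    which tend to 1 for points at or above the baseline.  Iteration
    stops when the relative change of the weight vector drops below
    ``ratio``.  If no residual is negative (or sigma is zero) the current
    baseline is accepted as a degenerate success.
    """
    s = np.asarray(s, dtype=float)
    n = s.size
    if not 0 < ratio < 1:
        raise ValueError(f"ratio must be in (0, 1), got {ratio}")
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")
    w = np.ones(n)
    z = np.zeros(n)
    converged = False
    history: list[tuple[float, float]] = []
    t = 0
    for t in range(1, max_iter + 1):
        z = pls_solve(s, w, lam)
        d = s - z
        dn = d[d < 0]
        if dn.size == 0:
            converged = True
            break
        mu = float(dn.mean())
        sigma = float(dn.std())
        history.append((mu, sigma))
        # sigma at floating-point noise level means the baseline already
        # interpolates the signal: degenerate success
        if sigma <= 1e-12 * max(np.abs(s).max(), np.finfo(float).tiny):
            converged = True
            break
        arg = np.clip(2.0 * (d - (2.0 * sigma - mu)) / sigma,
                      -_EXP_CLIP, _EXP_CLIP)
        w_new = 1.0 / (1.0 + np.exp(arg))
        if not np.all(np.isfinite(w_new)):
            raise FloatingPointError(f"non-finite weights at iteration {t}")
        if np.linalg.norm(w - w_new) / np.linalg.norm(w) < ratio:
            w = w_new
            converged = True
            break
        w = w_new
    return BaselineResult(
        z=z,
        method="arpls",
        lam=lam,
        ratio=ratio,
        n_iter=t,
        converged=converged,
        weights=w,
        diagnostics={"mu_sigma": history},
    )


def detrend(
    s: Spectrum,
    method: str = "arpls",
    lam: float = 200.0,
    ratio: float = 1e-6,
    max_iter: int = 50,
) -> tuple[Spectrum, BaselineResult]:
    """Estimate and subtract a baseline; returns (corrected, result).

    ``method`` is one of ``linear``, ``airpls``, ``arpls``, or ``none``
    (identity with a zero baseline).
    """
    if method == "none":
        res = BaselineResult(z=np.zeros(len(s)), method="none")
    elif method == "linear":
        res = linear_baseline(s)
    elif method == "airpls":
        res = airpls(s.y, lam=lam, ratio=ratio, max_iter=max_iter)
    elif method == "arpls":
        res = arpls(s.y, lam=lam, ratio=ratio, max_iter=max_iter)
    else:
        raise ValueError(
            f"unknown baseline method {method!r}: "
            "expected linear, airpls, arpls, or none"
        )
    return s.with_y(s.y - res.z), res
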