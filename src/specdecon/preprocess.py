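"""Uniform-grid interpolation and moving-average denoising.

The pipeline order is fixed: interpolate onto a uniform grid first, then
denoise, then correct the baseline, then detect peaks, then decompose.
Interpolation is linear on purpose — spline overshoot would manufacture
spurious curvature extrema that the second-derivative peak detector
downstream would pick up as candidates.
"""

from __future__ import annotations

import numpy as np

from .spectrum import Spectrum

__all__ = ["interpolate_uniform", "denoise"]


def interpolate_uniform(s: Spectrum, n_points: int) -> Spectrum:
    """Resample onto a uniform grid of ``n_points`` from min(x) to max(x).

    Intensities are linearly interpolated; both endpoints are preserved
    exactly.
    """
    if n_points < 2:
        raise ValueError(f"n_points must be >= 2, got {n_points}")
    grid = np.linspace(s.x[0], s.x[-1], int(n_points))
    y = np.interp(grid, s.x, s.y)
    return Spectrum(grid, y, s.x_label, s.y_label)


def denoise(s: Spectrum, window: int, repeats: int = 1) -> Spectrum:
    """Centered boxcar (moving-average) smoothing.

    Each sample is replaced by the mean of the samples inside a window of
    nominal size ``window`` centered on it; windows are truncated at the
    array edges, so edge samples average over fewer points.  Even windows
    take the extra sample on the left.  ``repeats`` applies the filter
    that many times in sequence.  ``window <= 1`` is the identity.
    """
    n = len(s)
    if window < 1:
        raise ValueError(f"window must be >= 1, got {window}")
    if window > n:
        raise ValueError(f"window ({window}) exceeds spectrum length ({n})")
    if repeats < 1:
        raise ValueError(f"repeats must be >= 1, got {repeats}")

    left = window // 2          # even windows: extra sample on the left
    right = window - 1 - left
    y = s.y
    for _ in range(repeats):
        csum = np.concatenate(([0.0], np.cumsum(y)))
        idx = np.arange(n)
        lo = np.maximum(idx - left, 0)
        hi = np.minimum(idx + right, n - 1)
        y = (csum[hi + 1] - csum[lo]) / (hi - lo + 1)
    return s.with_y(y)
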