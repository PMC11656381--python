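"""Peak detection by window propagation over second-derivative candidates.

Candidate peaks are the points where the *negative* second derivative of
the signal has a strict local maximum with positive curvature.  Working
on curvature rather than on the signal itself lets the detector see
shoulders: a small component riding on the flank of a larger one never
forms a local maximum in y, but it does bend the signal, and that bend
shows up as a curvature extremum.

A fixed-size window is then slid along the grid one sample at a time.
Within each placement the candidate with the largest intensity wins, and
it is kept only if the intensity range inside the window (max - min)
reaches ``threshold`` and the intensity at the peak itself reaches
``min_amplitude``.  Smaller windows and lower thresholds admit more
candidates (and more false positives); larger windows and higher
thresholds are stricter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .spectrum import Spectrum

__all__ = [
    "PeakCandidate",
    "PeakSet",
    "second_derivative",
    "candidate_indices",
    "detect_peaks",
]


@dataclass(frozen=True)
class PeakCandidate:
    """One detected peak: grid index, position, intensity, curvature."""

    index: int
    x: float
    amplitude: float
    curvature: float


@dataclass(frozen=True)
class PeakSet:
    """Detected peaks sorted by position, plus the detector settings."""

    peaks: tuple[PeakCandidate, ...]
    window_size: int = 0
    threshold: float = 0.0
    min_amplitude: float = 0.0

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self):
        return iter(self.peaks)

    @property
    def positions(self) -> np.ndarray:
        return np.array([p.x for p in self.peaks])

    @property
    def amplitudes(self) -> np.ndarray:
        return np.array([p.amplitude for p in self.peaks])

    @property
    def indices(self) -> np.ndarray:
        return np.array([p.index for p in self.peaks], dtype=int)


def _require_uniform(s: Spectrum) -> float:
    if not s.is_uniform(rtol=1e-6):
        raise ValueError(
            "peak detection requires a uniform grid; run "
            "interpolate_uniform first"
        )
    return s.grid_step()


def second_derivative(s: Spectrum) -> np.ndarray:
    """Central second differences (y[i-1] - 2 y[i] + y[i+1]) / h^2.

    Requires a uniform grid with at least 3 points; the endpoint values
    are copied from the nearest interior point.
    """
    h = _require_uniform(s)
    y = s.y
    if y.size < 3:
        raise ValueError("second derivative needs at least 3 samples")
    d2 = np.empty_like(y)
    d2[1:-1] = (y[:-2] - 2.0 * y[1:-1] + y[2:]) / (h * h)
    d2[0] = d2[1]
    d2[-1] = d2[-2]
    return d2


def candidate_indices(s: Spectrum) -> np.ndarray:
    """Indices where -y'' has a local maximum with y'' < 0.

    Local maxima are strict except for plateaus: a run of equal values
    flanked by strictly smaller neighbors counts as one candidate at its
    midpoint (a symmetric peak sampled so its apex falls exactly between
    two grid points produces such a two-sample plateau).
    """
    neg_d2 = -second_derivative(s)
    idx, _ = find_peaks(neg_d2)
    # curvature must clear the rounding noise of the finite-difference
    # stencil (eps-level cancellation of y/h^2), or flat and affine
    # stretches sprout spurious candidates
    h = s.grid_step()
    floor = 1e-9 * np.max(np.abs(s.y)) / (h * h)
    return idx[neg_d2[idx] > floor]


def detect_peaks(
    s: Spectrum,
    window_size: int,
    threshold: float = 0.0,
    min_amplitude: float = 0.0,
) -> PeakSet:
    """Window-propagation peak detection.

    Slides a window of ``window_size`` samples along the grid with step
    one (truncated at the edges).  In each placement, the curvature
    candidate with the largest intensity is selected; it is accepted if
    the in-window intensity range (max - min) is at least ``threshold``
    and its own intensity is at least ``min_amplitude``.  Accepted
    indices are deduplicated across placements.
    """
    n = len(s)
    if window_size < 3:
        raise ValueError(f"window_size must be >= 3, got {window_size}")
    if window_size > n:
        raise ValueError(
            f"window_size ({window_size}) exceeds spectrum length ({n})"
        )
    if threshold < 0 or min_amplitude < 0:
        raise ValueError("threshold and min_amplitude must be >= 0")

    y = s.y
    cands = candidate_indices(s)
    accepted: set[int] = set()
    if cands.size:
        half_lo = window_size // 2
        half_hi = window_size - 1 - half_lo
        for start in range(-half_lo, n - window_size + 1 + half_hi):
            lo = max(start, 0)
            hi = min(start + window_size, n)  # edge windows truncated
            inside = cands[(cands >= lo) & (cands < hi)]
            if inside.size == 0:
                continue
            # ties in intensity break toward the smaller index
            best = inside[np.argmax(y[inside])]
            if (y[lo:hi].max() - y[lo:hi].min()) < threshold:
                continue
            if y[best] < min_amplitude:
                continue
            accepted.add(int(best))

    d2 = second_derivative(s)
    peaks = tuple(
        PeakCandidate(index=i, x=float(s.x[i]), amplitude=float(y[i]),
                      curvature=float(-d2[i]))
        for i in sorted(accepted)
    )
    return PeakSet(peaks=peaks, window_size=window_size,
                   threshold=threshold, min_amplitude=min_amplitude)
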