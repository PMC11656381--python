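"""Synthetic spectra with known ground truth.

Every generated spectrum is a sum of line-shape components plus an
optional drifting baseline plus optional white Gaussian noise, and comes
back together with the :class:`GroundTruth` that produced it, so tests
can assert recovery of the true peak count, centers, heights, and
widths.  Generation is deterministic: the PRNG is numpy's PCG64 seeded
from the ``seed`` field, and the same truth object always yields a
bit-identical spectrum.

Four named suites cover the regimes a spectroscopist meets in practice:

* ``fig1_multisine`` — peaks on an exaggerated multi-sine drift, the
  stress case for baseline correction;
* ``fig2_test``      — peaks of mixed height, including a small peak
  flanked by taller neighbors, for exercising window/threshold choices
  in peak detection;
* ``narrow_xrd``     — many sharp, well-separated lines (diffraction-
  like, widths under 1% of the x-span);
* ``broad_uvvis``    — few strongly overlapping broad bands on a slow
  drift (absorption-like).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .profiles import ProfileParams, model_sum
from .spectrum import Spectrum

__all__ = ["GroundTruth", "make_spectrum", "make_suite", "SUITES",
           "SUITE_SETTINGS"]

SUITES = ("fig1_multisine", "fig2_test", "narrow_xrd", "broad_uvvis")

#: Recommended analysis settings per suite: the baseline treatment each
#: family tolerates and a detection window on the order of the FWHM in
#: samples.  Broad overlapping bands get no detrending (a penalized
#: baseline stiff enough to spare them cannot follow the drift either),
#: narrow lines need none, and the drifting multi-sine family needs a
#: very stiff arPLS fit (lam grows like the fourth power of the feature
#: width in samples).
SUITE_SETTINGS: dict[str, dict] = {
    "fig1_multisine": dict(baseline="arpls", lam=1e7, window_size=45,
                           threshold=0.05, min_amplitude=0.1),
    "fig2_test": dict(baseline="none", lam=200.0, window_size=45,
                      threshold=0.05, min_amplitude=0.05),
    "narrow_xrd": dict(baseline="none", lam=200.0, window_size=25,
                       threshold=0.05, min_amplitude=0.05),
    "broad_uvvis": dict(baseline="none", lam=200.0, window_size=501,
                        threshold=0.05, min_amplitude=0.3),
}


@dataclass(frozen=True)
class GroundTruth:
    """Recipe for one synthetic spectrum.

    ``baseline`` is ``none``, ``affine`` (params: intercept, slope), or
    ``multisine`` (params: flat list of amplitude/period/phase triples;
    periods should stay above ~25% of the x-span so the drift is slow
    compared to the peaks).
    """

    components: tuple[ProfileParams, ...]
    baseline: str = "none"
    baseline_params: tuple[float, ...] = ()
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.baseline not in ("none", "affine", "multisine"):
            raise ValueError(f"unknown baseline kind {self.baseline!r}")
        if self.baseline == "affine" and len(self.baseline_params) != 2:
            raise ValueError("affine baseline needs (intercept, slope)")
        if self.baseline == "multisine" and (
            len(self.baseline_params) == 0 or len(self.baseline_params) % 3
        ):
            raise ValueError(
                "multisine baseline needs amplitude/period/phase triples"
            )
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")

    def baseline_eval(self, x: np.ndarray) -> np.ndarray:
        if self.baseline == "none":
            return np.zeros_like(x)
        if self.baseline == "affine":
            b0, b1 = self.baseline_params
            return b0 + b1 * (x - x[0])
        z = np.zeros_like(x)
        p = self.baseline_params
        for amp, period, phase in zip(p[0::3], p[1::3], p[2::3]):
            z += amp * np.sin(2.0 * np.pi * (x - x[0]) / period + phase)
        return z

    def clean_signal(self, x: np.ndarray) -> np.ndarray:
        """Component sum without baseline or noise."""
        return model_sum(self.components, x)


def make_spectrum(
    gt: GroundTruth,
    x_min: float,
    x_max: float,
    n_points: int,
) -> tuple[Spectrum, GroundTruth]:
    """Realize a ground-truth recipe on a uniform grid."""
    if n_points < 16:
        raise ValueError(f"n_points must be >= 16, got {n_points}")
    if not x_min < x_max:
        raise ValueError("x_min must be < x_max")
    x = np.linspace(x_min, x_max, int(n_points))
    y = gt.clean_signal(x) + gt.baseline_eval(x)
    if gt.noise_sigma > 0:
        rng = np.random.Generator(np.random.PCG64(gt.seed))
        y = y + rng.normal(0.0, gt.noise_sigma, size=x.size)
    return Spectrum(x, y), gt


def _gaussians(specs) -> tuple[ProfileParams, ...]:
    return tuple(
        ProfileParams("gaussian", c, a, sigma=s) for c, a, s in specs
    )


def make_suite(
    name: str,
    noise_sigma: float | None = None,
    seed: int = 0,
) -> list[tuple[Spectrum, GroundTruth]]:
    """Build a named fixture suite; see the module docstring.

    ``noise_sigma`` overrides each member's default noise level (use 0.0
    for the noiseless variants the recovery tests rely on); ``seed``
    offsets every member's PRNG seed.
    """
    if name == "fig1_multisine":
        members = [
            GroundTruth(
                components=_gaussians(
                    [(200.0, 1.0, 5.0), (420.0, 0.7, 6.0),
                     (650.0, 0.9, 5.0), (830.0, 0.5, 5.0)]
                ),
                baseline="multisine",
                # slow drift comparable in size to the peaks: extreme case
                baseline_params=(0.8, 900.0, 0.3, 0.5, 400.0, 1.1,
                                 0.3, 260.0, 2.0),
                noise_sigma=0.0,
            ),
        ]
        domain = (0.0, 1000.0, 4000)
    elif name == "fig2_test":
        members = [
            GroundTruth(
                components=_gaussians(
                    [(150.0, 1.0, 6.0), (185.0, 0.25, 5.0),
                     (220.0, 0.9, 6.0), (400.0, 0.6, 7.0),
                     (600.0, 1.0, 6.0), (790.0, 0.45, 6.0)]
                ),
                noise_sigma=0.002,
            ),
        ]
        domain = (0.0, 1000.0, 4000)
    elif name == "narrow_xrd":
        members = [
            GroundTruth(
                components=_gaussians(
                    [(120.0, 1.0, 1.5), (260.0, 0.8, 1.2),
                     (430.0, 0.6, 1.5), (610.0, 0.9, 1.3),
                     (840.0, 0.7, 1.4)]
                ),
                noise_sigma=0.0,
            ),
            GroundTruth(
                components=_gaussians(
                    [(180.0, 0.9, 1.0), (500.0, 1.0, 1.5),
                     (520.0, 0.5, 1.2), (770.0, 0.8, 1.3)]
                ),
                baseline="affine",
                baseline_params=(0.05, 1e-4),
                noise_sigma=0.0,
            ),
        ]
        domain = (0.0, 1000.0, 8000)
    elif name == "broad_uvvis":
        # drift stays slow (periods >= half the span) and small next to
        # the bands, mirroring how little detrending broad absorption
        # spectra tolerate before the bands themselves get absorbed
        members = [
            GroundTruth(
                components=_gaussians(
                    [(350.0, 0.9, 55.0), (460.0, 1.0, 60.0),
                     (600.0, 0.7, 70.0)]
                ),
                baseline="multisine",
                baseline_params=(0.12, 1100.0, 0.7, 0.08, 500.0, 1.9),
                noise_sigma=0.002,
            ),
            GroundTruth(
                components=_gaussians(
                    [(420.0, 1.0, 50.0), (540.0, 0.8, 65.0)]
                ),
                baseline="multisine",
                baseline_params=(0.1, 1200.0, 0.2, 0.08, 600.0, 1.0),
                noise_sigma=0.002,
            ),
        ]
        domain = (200.0, 1000.0, 4000)
    else:
        raise ValueError(f"unknown suite {name!r}: expected one of {SUITES}")

    x_min, x_max, n = domain
    out = []
    for i, gt in enumerate(members):
        gt = replace(gt, seed=seed + i)
        if noise_sigma is not None:
            gt = replace(gt, noise_sigma=noise_sigma)
        out.append(make_spectrum(gt, x_min, x_max, n))
    return out
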