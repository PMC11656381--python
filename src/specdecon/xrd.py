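"""Miller-index assignment for tetragonal powder-diffraction patterns.

Bragg's law, n*lambda = 2 d sin(theta), converts an observed diffraction
angle 2-theta into an interplanar spacing d.  For a tetragonal lattice
(a = b != c) the spacing of the (h, k, l) plane family is

    1 / d^2 = (h^2 + k^2) / a^2 + l^2 / c^2

so, given the lattice constants, each observed reflection can be
labelled with the integer triple whose predicted angle lies closest to
the observation.  The assignment here is purely geometric: no
structure-factor extinction rules are applied.

Angles are degrees of 2-theta at the interface, radians internally;
lengths are in angstroms.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np

__all__ = [
    "MillerAssignment",
    "bragg_d",
    "bragg_two_theta",
    "tetragonal_d",
    "assign_miller",
]


@dataclass(frozen=True)
class MillerAssignment:
    """One indexed reflection: observed angle, spacing, (h,k,l), residual."""

    two_theta: float
    d: float
    hkl: tuple[int, int, int]
    residual: float
    wavelength: float
    order: int = 1


def bragg_d(two_theta: float, wavelength: float, order: int = 1) -> float:
    """Interplanar spacing d = n*lambda / (2 sin(theta)), angles in
    degrees of 2-theta, lengths in angstroms."""
    if not 0.0 < two_theta <= 180.0:
        raise ValueError(
            f"2-theta must lie in (0, 180] degrees, got {two_theta}"
        )
    if wavelength <= 0:
        raise ValueError(f"wavelength must be positive, got {wavelength}")
    if order < 1:
        raise ValueError(f"diffraction order must be >= 1, got {order}")
    theta = np.radians(two_theta / 2.0)
    return order * wavelength / (2.0 * np.sin(theta))


def bragg_two_theta(d: float, wavelength: float, order: int = 1) -> float:
    """Inverse of :func:`bragg_d`: predicted 2-theta (degrees) for a
    spacing d, or ValueError when the reflection is geometrically
    impossible (n*lambda > 2d)."""
    if d <= 0:
        raise ValueError(f"d-spacing must be positive, got {d}")
    sin_theta = order * wavelength / (2.0 * d)
    if sin_theta >= 1.0:
        raise ValueError(
            f"no diffraction angle exists for d={d} at wavelength "
            f"{wavelength} (sin theta = {sin_theta:.3f} >= 1)"
        )
    return float(2.0 * np.degrees(np.arcsin(sin_theta)))


def tetragonal_d(hkl: tuple[int, int, int], a: float, c: float) -> float:
    """Tetragonal interplanar spacing 1/sqrt((h^2+k^2)/a^2 + l^2/c^2)."""
    h, k, l = hkl
    if (h, k, l) == (0, 0, 0):
        raise ValueError("(0, 0, 0) is not a lattice plane")
    if a <= 0 or c <= 0:
        raise ValueError("lattice constants must be positive")
    return 1.0 / np.sqrt((h * h + k * k) / (a * a) + (l * l) / (c * c))


def _canonical_triples(hkl_max: int):
    """All index triples with 0 <= k <= h <= hkl_max, 0 <= l <= hkl_max,
    excluding (0,0,0).  Restricting to h >= k removes the h<->k
    degeneracy up front; triples come out in lexicographic order so the
    first best match is the canonical one."""
    for h, k, l in product(range(hkl_max + 1), repeat=3):
        if (h, k, l) == (0, 0, 0) or k > h:
            continue
        yield (h, k, l)


def assign_miller(
    two_theta_list,
    wavelength: float,
    a: float,
    c: float,
    hkl_max: int = 6,
    order: int = 1,
) -> list[MillerAssignment]:
    """Label each observed 2-theta with the best-matching (h, k, l).

    All triples with indices up to ``hkl_max`` are enumerated; for each
    observation the triple minimizing |2theta_pred - 2theta_obs| is
    returned.  Ties (including the exact h<->k degeneracy) resolve to
    the lexicographically smallest triple with h >= k.
    """
    if hkl_max < 1:
        raise ValueError(f"hkl_max must be >= 1, got {hkl_max}")

    table = []
    for hkl in _canonical_triples(hkl_max):
        d = tetragonal_d(hkl, a, c)
        try:
            tt = bragg_two_theta(d, wavelength, order)
        except ValueError:
            continue  # reflection outside the accessible angular range
        table.append((hkl, d, tt))
    if not table:
        raise ValueError(
            "no reflection with indices up to "
            f"{hkl_max} is accessible at wavelength {wavelength}"
        )

    out = []
    for tt_obs in two_theta_list:
        if not 0.0 < tt_obs <= 180.0:
            raise ValueError(
                f"observed 2-theta {tt_obs} outside (0, 180] degrees"
            )
        best = min(table, key=lambda row: (abs(row[2] - tt_obs), row[0]))
        hkl, d, tt_pred = best
        out.append(
            MillerAssignment(
                two_theta=float(tt_obs),
                d=float(d),
                hkl=hkl,
                residual=float(abs(tt_pred - tt_obs)),
                wavelength=float(wavelength),
                order=order,
            )
        )
    return out
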