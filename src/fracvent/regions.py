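"""Eigenvalue regions for fractional-order stability and D-stability.

A commensurate fractional system D^alpha x = A x is asymptotically stable
iff every eigenvalue of A satisfies |arg(lambda)| > alpha*pi/2 — the
Matignon sector F(alpha).  For performance shaping, eigenvalues are
additionally confined to the LMI region

    S(r, theta) = {z : |z| < r} ∩ {z : Re(z) sin(theta) + |Im(z)| cos(theta) < 0},

the open origin-centred disk of radius r intersected with the left-half-
plane cone of half-angle theta about the negative real axis.  For
alpha in (1, 2), S(r, theta) is contained in F(alpha) whenever
theta <= pi - alpha*pi/2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import numpy.typing as npt

__all__ = [
    "SectorDiskRegion",
    "is_in_stability_region",
    "max_sector_angle",
    "region_membership",
]


@dataclass(frozen=True)
class SectorDiskRegion:
    """The region S(r, theta): disk of radius ``radius`` ∩ cone of half-angle ``theta``."""

    radius: float
    theta: float  # radians, in (0, pi/2]

    def __post_init__(self) -> None:
        if not self.radius > 0:
            raise ValueError(f"radius must be > 0, got {self.radius}")
        if not 0.0 < self.theta <= np.pi / 2:
            raise ValueError(f"theta must lie in (0, pi/2], got {self.theta}")

    @classmethod
    def from_degrees(cls, radius: float, theta_deg: float) -> "SectorDiskRegion":
        return cls(radius=radius, theta=np.deg2rad(theta_deg))

    @property
    def theta_degrees(self) -> float:
        return float(np.rad2deg(self.theta))

    def membership_margins(self, eigenvalues: npt.ArrayLike) -> tuple[np.ndarray, np.ndarray]:
        """(disk, sector) margins per eigenvalue; both negative inside S."""
        lam = np.atleast_1d(np.asarray(eigenvalues, dtype=complex))
        disk = np.abs(lam) - self.radius
        sector = lam.real * np.sin(self.theta) + np.abs(lam.imag) * np.cos(self.theta)
        return disk, sector


def is_in_stability_region(
    eigenvalues: npt.ArrayLike, alpha: float, tol: float = 0.0
) -> bool:
    """Matignon test: all |arg(lambda)| > alpha*pi/2 + tol (arg in (-pi, pi]).

    lambda = 0 has arg 0 and is always rejected.
    """
    if not 0.0 < alpha < 2.0:
        raise ValueError(f"alpha must lie in (0, 2), got {alpha}")
    if tol < 0:
        raise ValueError(f"tol must be >= 0, got {tol}")
    lam = np.atleast_1d(np.asarray(eigenvalues, dtype=complex))
    return bool(np.all(np.abs(np.angle(lam)) > alpha * np.pi / 2 + tol))


def max_sector_angle(alpha: float) -> float:
    """Supremum of admissible theta (radians) with S(r, theta) ⊂ F(alpha).

    pi/2 for alpha <= 1; pi - alpha*pi/2 for alpha in (1, 2).
    """
    if not 0.0 < alpha < 2.0:
        raise ValueError(f"alpha must lie in (0, 2), got {alpha}")
    if alpha <= 1.0:
        return np.pi / 2
    return np.pi - alpha * np.pi / 2


def region_membership(
    eigenvalues: npt.ArrayLike, region: SectorDiskRegion, tol: float = 0.0
) -> np.ndarray:
    """Boolean per eigenvalue: strictly inside S(r, theta) with margin ``tol``.

    This direct geometric test is the analytic oracle for the LMI
    characterization of the same region.
    """
    if tol < 0:
        raise ValueError(f"tol must be >= 0, got {tol}")
    disk, sector = region.membership_margins(eigenvalues)
    return (disk < -tol) & (sector < -tol)
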