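"""Closed-form geometry of excess cell-surface area.

When a spread cell rounds up at constant volume its plasma membrane suddenly
exceeds, severalfold, the area of the smooth sphere enclosing that volume.
This module collects the small closed-form pieces used throughout the package:
sphere/area conversions, the excess-surface ratio, the analytic limit on how
much excess equal spherical protrusions (BLiPs) can store, and the normalized
bending energy of a discrete closed contour,

    E = (L/N) * sum_i kappa_i**2,

with ``kappa_i`` the polyline curvature at bead ``i`` (turning angle divided
by the mean adjacent segment length), ``L`` the perimeter and ``N`` the bead
count.  All lengths are in micrometres unless stated otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Contour2D",
    "ExcessSpec",
    "sphere_radius_from_area",
    "excess_ratio",
    "equal_blip_excess",
    "contour_edges",
    "turning_angle_curvature",
    "normalized_bending_energy",
    "polygon_area",
]


@dataclass
class Contour2D:
    """A closed planar contour given by ordered vertices (last connects to first).

    Parameters
    ----------
    vertices : (N, 2) array_like
        Ordered vertex coordinates in micrometres.
    allow_self_intersection : bool
        Set when the contour is intentionally self-overlapping (e.g. a
        pentagram test case); geometric validity checks still require at
        least 3 pairwise-distinct consecutive vertices.
    """

    vertices: np.ndarray
    allow_self_intersection: bool = False
    closed: bool = field(default=True, init=False)

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2:
            raise ValueError("vertices must be an (N, 2) array")
        if v.shape[0] < 3:
            raise ValueError("a closed contour needs at least 3 vertices")
        seg = np.roll(v, -1, axis=0) - v
        if np.any(np.hypot(seg[:, 0], seg[:, 1]) == 0.0):
            raise ValueError("consecutive vertices must be distinct")
        self.vertices = v

    def __len__(self) -> int:
        return self.vertices.shape[0]

    @property
    def perimeter(self) -> float:
        seg = np.roll(self.vertices, -1, axis=0) - self.vertices
        return float(np.hypot(seg[:, 0], seg[:, 1]).sum())

    @property
    def area(self) -> float:
        """Signed shoelace area (positive for counter-clockwise orientation)."""
        return polygon_area(self.vertices)


@dataclass
class ExcessSpec:
    """Spread-versus-rounded bookkeeping for one cell.

    ``excess_ratio`` is the spread surface area divided by the area of the
    smooth sphere of the rounded radius; it is >= 1 for any real cell.
    """

    spread_area: float | None = None
    rounded_radius: float | None = None
    excess: float | None = None

    def __post_init__(self) -> None:
        if self.excess is None:
            if self.spread_area is None or self.rounded_radius is None:
                raise ValueError("give excess, or spread_area and rounded_radius")
            self.excess = excess_ratio(self.spread_area, self.rounded_radius)
        if self.excess < 1.0:
            raise ValueError("excess ratio must be >= 1")


def sphere_radius_from_area(S: float) -> float:
    """Radius of the sphere with surface area ``S``: R = sqrt(S / 4 pi)."""
    if S <= 0:
        raise ValueError("surface area must be positive")
    return float(np.sqrt(S / (4.0 * np.pi)))


def excess_ratio(spread_area: float, rounded_radius: float) -> float:
    """Spread area over the smooth-sphere area ``4 pi R^2`` of the rounded cell."""
    if spread_area <= 0 or rounded_radius <= 0:
        raise ValueError("spread_area and rounded_radius must be positive")
    return float(spread_area / (4.0 * np.pi * rounded_radius**2))


def equal_blip_excess(coverage_fraction: float) -> float:
    """Excess-surface ratio for a sphere coated with equal spherical BLiPs.

    Model: the base sphere stays intact; each BLiP of radius ``r`` contributes
    its full area ``4 pi r^2`` over a flat footprint disk ``pi r^2``, so a
    footprint coverage fraction ``f`` of the base sphere yields a total area
    of ``(1 + 4 f) * 4 pi R^2``.  The supremum over all packings — vanishing
    BLiP radius and complete disk coverage, f -> 1 — is exactly 5: no rounded
    cell covered with equal spherical BLiPs can store more than five times
    the smooth-sphere area.  (Observed excesses of up to ~14 therefore demand
    heterogeneous BLiP sizes or non-spherical storage.)
    """
    f = float(coverage_fraction)
    if not 0.0 <= f <= 1.0:
        raise ValueError("coverage_fraction must lie in [0, 1]")
    return 1.0 + 4.0 * f


def polygon_area(vertices: np.ndarray) -> float:
    """Signed shoelace area of a closed polygon."""
    v = np.asarray(vertices, dtype=float)
    x, y = v[:, 0], v[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    return float(0.5 * np.sum(x * yn - xn * y))


def contour_edges(vertices: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Edge vectors ``e_i = v_{i+1} - v_i`` (cyclic) and their lengths."""
    v = np.asarray(vertices, dtype=float)
    e = np.roll(v, -1, axis=0) - v
    return e, np.hypot(e[:, 0], e[:, 1])


def turning_angle_curvature(vertices: np.ndarray) -> np.ndarray:
    """Unsigned polyline curvature at each vertex of a closed contour.

    kappa_i = theta_i / ((l_{i-1} + l_i)/2) with theta_i the turning angle
    between the incoming and outgoing edge.  This estimator converges to the
    continuum curvature as the polyline is refined and is shared by every
    module that evaluates bending energy, so that discrete energies are
    comparable across models.
    """
    e, lengths = contour_edges(vertices)
    if np.any(lengths == 0.0):
        raise ValueError("degenerate contour: zero-length segment")
    prev_e = np.roll(e, 1, axis=0)
    prev_l = np.roll(lengths, 1)
    cross = prev_e[:, 0] * e[:, 1] - prev_e[:, 1] * e[:, 0]
    dot = np.einsum("ij,ij->i", prev_e, e)
    theta = np.arctan2(cross, dot)
    return np.abs(theta) / (0.5 * (prev_l + lengths))


def normalized_bending_energy(contour: Contour2D | np.ndarray) -> float:
    """Normalized total bending energy of a closed contour.

    E = (L/N) * sum_i kappa_i**2 — the discrete form of the contour integral
    of squared curvature.  For a circle of radius R this tends to 2 pi / R;
    it is invariant under rigid motions and scales as 1/s under dilation by s.
    """
    vertices = contour.vertices if isinstance(contour, Contour2D) else np.asarray(contour, float)
    _, lengths = contour_edges(vertices)
    kappa = turning_angle_curvature(vertices)
    L = lengths.sum()
    N = vertices.shape[0]
    return float(L / N * np.sum(kappa**2))
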