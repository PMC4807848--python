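"""Target morphologies and initial states for phase-field runs.

Targets are built as equilibrium tanh profiles of a signed distance function
(positive outside the cell, so phi1 = 1 in the exterior medium).  2D targets
come from closed contours (circles, Fourier-lobed circles, digitized cell
peripheries); 3D targets from level-set grids such as the seed-and-growth
packed-cell export.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

from ..surface_math import Contour2D
from .core import Grid, PhaseState, equilibrium_profile

__all__ = [
    "fourier_lobed_contour",
    "signed_distance_to_contour",
    "target_from_contour",
    "target_from_level_set",
    "three_phase_from_distance",
    "circle_state",
    "sphere_state",
    "slab_state",
]


def fourier_lobed_contour(n_lobes: int, base_radius: float, amplitude: float,
                          n_vertices: int = 2048,
                          center: tuple[float, float] = (0.0, 0.0)) -> Contour2D:
    """Circle with one superimposed Fourier mode: r(t) = R (1 + a cos(n t)).

    The benchmark morphology with ``n_lobes`` identical, equally spaced
    protrusions.  The curve is simple (non-self-intersecting) for the
    amplitudes used here (a ~ 0.15); self-intersection is checked by the
    positivity of r.
    """
    if n_lobes < 0:
        raise ValueError("n_lobes must be non-negative")
    if amplitude >= 1.0:
        raise ValueError("amplitude must keep r(t) positive")
    t = np.linspace(0.0, 2.0 * np.pi, n_vertices, endpoint=False)
    r = base_radius * (1.0 + amplitude * np.cos(n_lobes * t))
    v = np.column_stack([center[0] + r * np.cos(t), center[1] + r * np.sin(t)])
    return Contour2D(v)


def signed_distance_to_contour(grid: Grid, contour: Contour2D,
                               oversample: int = 4) -> np.ndarray:
    """Signed distance from every grid point to a star-shaped closed contour.

    Distance is measured to a densely resampled polyline (KD-tree nearest
    neighbour); the sign is positive outside, decided by comparing the
    radius about the contour centroid (valid for star-shaped targets).
    """
    if grid.dim != 2:
        raise ValueError("contour targets are 2D")
    v = contour.vertices
    # densify the polyline so the chord error is << h
    reps = []
    for k in range(oversample):
        reps.append(v + (np.roll(v, -1, axis=0) - v) * (k / oversample))
    dense = np.concatenate(reps, axis=0)
    X, Y = grid.coords()
    pts = np.column_stack([X.ravel(), Y.ravel()])
    d, _ = cKDTree(dense).query(pts, workers=-1)
    c = v.mean(axis=0)
    r_pts = np.hypot(pts[:, 0] - c[0], pts[:, 1] - c[1])
    theta = np.arctan2(pts[:, 1] - c[1], pts[:, 0] - c[0])
    vr = np.hypot(v[:, 0] - c[0], v[:, 1] - c[1])
    vth = np.arctan2(v[:, 1] - c[1], v[:, 0] - c[0])
    order = np.argsort(vth)
    r_target = np.interp(theta, vth[order], vr[order], period=2.0 * np.pi)
    sign = np.where(r_pts >= r_target, 1.0, -1.0)
    return (sign * d).reshape(grid.shape)


def target_from_contour(grid: Grid, contour: Contour2D, eps: float
                        ) -> np.ndarray:
    """phi1 target: equilibrium profile of the signed distance to a contour."""
    if contour.vertices.shape[0] < 3:
        raise ValueError("degenerate contour")
    return equilibrium_profile(signed_distance_to_contour(grid, contour), eps)


def target_from_level_set(grid: Grid, sdf: np.ndarray, eps: float) -> np.ndarray:
    """phi1 target from a signed-distance grid (negative inside the cell)."""
    if sdf.shape != grid.shape:
        raise ValueError("level-set shape does not match grid")
    return equilibrium_profile(sdf, eps)


def three_phase_from_distance(grid: Grid, sdf: np.ndarray, eps: float,
                              cortex_width: float) -> PhaseState:
    """Build (phi1, phi2) from a signed distance: cortex band inside the surface.

    phi1 rises across d = 0 (surface), phi3 rises inward across
    d = -cortex_width; the cortex phi2 = 1 - phi1 - phi3 occupies the band.
    ``cortex_width`` should exceed ~6 eps so the two interfaces do not
    interpenetrate (three-phase coexistence stays penalized)."""
    phi1 = equilibrium_profile(sdf, eps)
    phi3 = equilibrium_profile(-(sdf + cortex_width), eps)
    return PhaseState(grid, phi1, 1.0 - phi1 - phi3)


def _radial_distance(grid: Grid, center, radius: float) -> np.ndarray:
    mesh = grid.coords()
    r = np.sqrt(sum((x - c) ** 2 for x, c in zip(mesh, center)))
    return r - radius


def circle_state(grid: Grid, radius: float, eps: float, cortex_width: float,
                 center=None) -> PhaseState:
    """Rounded-cell initial data in 2D: circular surface + cortex annulus."""
    if center is None:
        center = (0.5 * grid.box_size,) * 2
    return three_phase_from_distance(grid, _radial_distance(grid, center, radius),
                                     eps, cortex_width)


def sphere_state(grid: Grid, radius: float, eps: float, cortex_width: float,
                 center=None) -> PhaseState:
    """Rounded-cell initial data in 3D: spherical surface + cortex shell."""
    if center is None:
        center = (0.5 * grid.box_size,) * 3
    return three_phase_from_distance(grid, _radial_distance(grid, center, radius),
                                     eps, cortex_width)


def slab_state(grid: Grid, eps: float, lo: float = 0.3, hi: float = 0.7
               ) -> PhaseState:
    """Flat two-interface slab of phase 2 between lo and hi along axis 0.

    Calibration fixture: each flat interface has geometric area equal to the
    box cross-section."""
    x = grid.coords()[0]
    L = grid.box_size
    d = np.maximum(lo * L - x, x - hi * L)   # positive outside the slab
    phi1 = equilibrium_profile(d, eps)
    return PhaseState(grid, phi1, 1.0 - phi1)
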