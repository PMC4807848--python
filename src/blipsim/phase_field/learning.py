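"""Learning the spontaneous-curvature field C1 from a target morphology.

The spontaneous curvature of the cell surface is a proxy for the
heterogeneous membrane-cortex attachment ("fishnet") and is not known a
priori.  Given a target morphology (a digitized cell periphery in 2D, or a
packed-cell level set in 3D) the model learns C1 by:

1. initializing C1 with the target surface's mean curvature, extended
   constantly along normals off the interface (nearest-surface-point value);
2. alternating conserved relaxation of the phase fields with a proportional
   correction C1 <- C1 + eta (phi1 - phi1_target), restricted to the
   interfacial band: where the target cell extends beyond the current
   surface (phi1 too large relative to the target) the preferred curvature
   is raised, nucleating an outward bulge there, and lowered where the
   current cell overshoots — a local-feature rule (a positive spontaneous-
   curvature spike grows a bump; a negative one a notch).

The loop stops when the surface mismatch (mean 0.5-contour distance in 2D,
band-normalized L1 mismatch otherwise) drops below tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from ..surface_math import Contour2D, turning_angle_curvature
from .analysis import contour_distance, extract_contour
from .core import FieldParams, Grid, PhaseState
from .dynamics import relax

__all__ = [
    "curvature_field_from_contour",
    "curvature_field_from_level_set",
    "LearnResult",
    "learn_spontaneous_curvature",
]


def curvature_field_from_contour(grid: Grid, contour: Contour2D) -> np.ndarray:
    """Signed curvature of a closed contour, extended along normals.

    Every grid point receives the curvature of its nearest contour vertex —
    exactly the constant-along-normals extension.  Sign convention: positive
    where the contour is locally convex (outward normal diverging), matching
    H = div(grad phi1 / |grad phi1|) with phi1 = 1 outside.
    """
    v = contour.vertices
    # ensure counter-clockwise orientation for the sign convention
    from ..surface_math import polygon_area

    if polygon_area(v) < 0:
        v = v[::-1]
    kappa = turning_angle_curvature(v)
    e = np.roll(v, -1, axis=0) - v
    prev_e = np.roll(e, 1, axis=0)
    cross = prev_e[:, 0] * e[:, 1] - prev_e[:, 1] * e[:, 0]
    signed = np.where(cross >= 0, kappa, -kappa)
    X, Y = grid.coords()
    pts = np.column_stack([X.ravel(), Y.ravel()])
    _, idx = cKDTree(v).query(pts, workers=-1)
    return signed[idx].reshape(grid.shape)


def curvature_field_from_level_set(grid: Grid, sdf: np.ndarray, eps: float
                                   ) -> np.ndarray:
    """Mean-curvature sum H = lap(d) on the band |d| < 2 eps, extended off it."""
    H = grid.laplacian(sdf)
    band = np.abs(sdf) < 2.0 * eps
    if not band.any():
        raise ValueError("no interfacial band found in the level set")
    coords = np.column_stack([c.ravel() for c in grid.coords()])
    band_flat = band.ravel()
    tree = cKDTree(coords[band_flat])
    _, idx = tree.query(coords[~band_flat], workers=-1)
    out = H.copy().ravel()
    out[~band_flat] = H.ravel()[band_flat][idx]
    return out.reshape(grid.shape)


@dataclass
class LearnResult:
    state: PhaseState
    C1: np.ndarray
    mismatch: float
    mismatch_trace: np.ndarray
    n_outer: int
    converged: bool


def learn_spontaneous_curvature(target_phi1: np.ndarray, state: PhaseState,
                                params: FieldParams, n_outer: int = 40,
                                n_inner: int = 200, dt: float = 1e-6,
                                eta: float | None = None,
                                tol: float | None = None,
                                C1_init: np.ndarray | None = None,
                                C1_max: float | None = None,
                                evolve_director: bool = False,
                                verbose: bool = False) -> LearnResult:
    """Alternate relaxation and proportional C1 correction until phi1 matches.

    ``tol`` is the target mean contour distance in 2D (default: 2 grid
    spacings) or band-L1 mismatch in 3D (default 0.05).  ``eta`` defaults to
    2/eps, which converts an O(1) phase mismatch into an O(1/eps) curvature
    correction.  C1 is clamped to |C1| <= C1_max (default 1/eps): sharper
    curvatures are unresolvable on the grid and destabilize the bending
    force.  Returns the best iterate if the mismatch stagnates.
    """
    g = state.grid
    if eta is None:
        eta = 2.0 / params.eps
    if tol is None:
        tol = 2.0 * g.h if g.dim == 2 else 0.05
    if C1_max is None:
        C1_max = 1.0 / params.eps
    st = state.copy()
    if C1_init is not None:
        st.C1 = C1_init.copy()
    st.C1 = np.clip(st.C1, -C1_max, C1_max)

    target_contour = None
    if g.dim == 2:
        target_contour = extract_contour(target_phi1, g)

    def mismatch_of(s: PhaseState) -> float:
        if target_contour is not None:
            try:
                return contour_distance(extract_contour(s), target_contour)
            except ValueError:
                return np.inf
        band = target_phi1 * (1.0 - target_phi1) > 0.02
        return float(np.abs(s.phi1 - target_phi1)[band].mean())

    best = st.copy()
    best_mis = mismatch_of(st)
    trace = [best_mis]
    converged = best_mis < tol
    k = 0
    bad_streak = 0
    for k in range(1, n_outer + 1):
        if converged:
            break
        res = relax(st, params, dt, n_inner, evolve_director=evolve_director)
        st = res.state
        mis = mismatch_of(st)
        trace.append(mis)
        if verbose:
            print(f"outer {k}: mismatch {mis:.4g}")
        if mis < best_mis:
            best = st.copy()
            best_mis = mis
            bad_streak = 0
        elif mis > 1.05 * best_mis:
            # progressive worsening = controller overshoot: soften the gain
            # (flat stretches are normal during slow lobe nucleation and do
            # not reduce the gain)
            bad_streak += 1
            if bad_streak >= 3:
                eta *= 0.5
                bad_streak = 0
        if mis < tol:
            converged = True
            break
        band = ((target_phi1 * (1.0 - target_phi1) > 0.02)
                | (st.phi1 * (1.0 - st.phi1) > 0.02))
        st.C1 = np.clip(st.C1 + eta * (st.phi1 - target_phi1) * band,
                        -C1_max, C1_max)
    final = st if converged else best
    return LearnResult(final, final.C1, mismatch_of(final),
                       np.asarray(trace), k, converged)
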