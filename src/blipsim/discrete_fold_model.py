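"""2D two-layer bead-spring model of cell-surface folding.

The cell surface (outer closed chain of N beads, inextensible by a stiff
spring penalty, with curvature-squared bending energy) is coupled to the
contractile actomyosin cortex (inner closed chain of M beads with
zero-rest-length springs and a target enclosed area) at M discrete contact
points.  Minimizing the total Hamiltonian

    H = H_out + H_inn + H_contact + H_cross + H_self

from a coincident-circle initial condition makes the cortex contract while
the surface, forced to keep its prescribed perimeter L = ER * P_target,
buckles into exactly M folds — the 2D cartoon of bleb-like protrusions.
The excess surface ratio ER is the outer perimeter over the contracted
cortex perimeter.

Self-crossing of the surface is a hard constraint (c7 -> infinity): any bead
whose proposed move would create a proper crossing of outer segments is kept
fixed for that iteration.  Minimization is a FIRE-type damped descent with
per-step energy rejection, so the energy is non-increasing along accepted
steps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from .surface_math import (
    Contour2D,
    normalized_bending_energy,
    polygon_area,
    turning_angle_curvature,
)

__all__ = [
    "ModelParams",
    "TwoLayerState",
    "MinimizeResult",
    "init_two_layer",
    "outer_energy",
    "inner_energy",
    "contact_energy",
    "cross_penalty",
    "total_energy",
    "winding_number",
    "segments_cross",
    "any_self_crossing",
    "minimize",
    "fold_template",
    "steady_state",
    "rescale_to_target_area",
    "fold_metrics",
    "count_radial_lobes",
]


@dataclass
class ModelParams:
    """Bead counts, excess ratio, target area and energy weights.

    ``ER`` is the prescribed outer perimeter divided by the perimeter of the
    circle of target area ``A_target`` (the fully contracted cortex).  The
    weights follow c2 >> c1 so the stretching term vanishes at steady state;
    c7 is conceptually infinite and enforced as a hard move-rejection rule.
    """

    N: int = 400
    M: int = 40
    ER: float = 4.0
    A_target: float = np.pi
    c1: float = 1.0
    c2: float = 1e8
    c3: float = 1.0
    c4: float = 1e7
    c5: float = 1e8
    c6: float = 1e8

    def __post_init__(self) -> None:
        if self.M >= self.N:
            raise ValueError("need M < N")
        if self.M < 0 or self.N < 3:
            raise ValueError("invalid bead counts")
        if self.ER < 1.0:
            raise ValueError("excess ratio must be >= 1")
        if self.A_target <= 0:
            raise ValueError("target area must be positive")
        if min(self.c1, self.c2, self.c3, self.c4, self.c5, self.c6) < 0:
            raise ValueError("energy weights must be non-negative")

    @property
    def target_inner_perimeter(self) -> float:
        """Perimeter of the circle of area A_target."""
        return 2.0 * np.sqrt(np.pi * self.A_target)

    @property
    def outer_perimeter(self) -> float:
        """Prescribed outer perimeter L = ER * target inner perimeter."""
        return self.ER * self.target_inner_perimeter


@dataclass
class TwoLayerState:
    """Bead positions of both layers plus the contact pairing.

    ``contacts[k]`` is the outer-bead index tied to inner bead ``k``; the
    pairing is a bijection onto the inner beads.  Chains are cyclic (bead 0
    follows bead N-1).
    """

    outer: np.ndarray                     # (N, 2)
    inner: np.ndarray                     # (M, 2)
    contacts: np.ndarray                  # (M,) int

    def __post_init__(self) -> None:
        self.outer = np.asarray(self.outer, float)
        self.inner = np.asarray(self.inner, float).reshape(-1, 2)
        self.contacts = np.asarray(self.contacts, int).ravel()
        if self.contacts.size != self.inner.shape[0]:
            raise ValueError("one contact per inner bead required")
        if self.contacts.size and len(np.unique(self.contacts)) != self.contacts.size:
            raise ValueError("contact pairing must be a bijection")

    def copy(self) -> "TwoLayerState":
        return TwoLayerState(self.outer.copy(), self.inner.copy(), self.contacts.copy())


def init_two_layer(params: ModelParams, seed: int = 0) -> TwoLayerState:
    """Both layers coincident on the circle of perimeter L = ER * P_target.

    The M contact points are equally spaced around the contour (consecutive
    contact indices differ by floor(N/M) or ceil(N/M)) and are nudged inward
    by 1e-6 * L/N to break the rotational symmetry deterministically, so the
    M folds nucleate at the contacts under any seed.
    """
    del seed  # initialization is deterministic; kept for interface stability
    N, M = params.N, params.M
    L = params.outer_perimeter
    R0 = L / (2.0 * np.pi)
    ang = 2.0 * np.pi * np.arange(N) / N
    outer = R0 * np.column_stack([np.cos(ang), np.sin(ang)])
    if M == 0:
        return TwoLayerState(outer, np.empty((0, 2)), np.empty(0, dtype=int))
    contacts = np.floor(np.arange(M) * N / M).astype(int)
    inner = outer[contacts].copy()
    nudge = 1e-6 * L / N
    radial = outer[contacts] / np.linalg.norm(outer[contacts], axis=1)[:, None]
    outer[contacts] -= nudge * radial
    inner -= nudge * radial
    return TwoLayerState(outer, inner, contacts)


# ---------------------------------------------------------------------------
# energy terms and analytic gradients
# ---------------------------------------------------------------------------

def _edges(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    e = np.roll(x, -1, axis=0) - x
    return e, np.hypot(e[:, 0], e[:, 1])


def _perp(e: np.ndarray) -> np.ndarray:
    return np.column_stack([e[:, 1], -e[:, 0]])


def outer_energy(state: TwoLayerState, params: ModelParams) -> float:
    """H_out = c1 sum kappa_i^2 + c2 sum (l_i - L/N)^2."""
    e, l = _edges(state.outer)
    kappa = turning_angle_curvature(state.outer)
    a = params.outer_perimeter / params.N
    return float(params.c1 * np.sum(kappa**2) + params.c2 * np.sum((l - a) ** 2))


def inner_energy(state: TwoLayerState, params: ModelParams) -> float:
    """H_inn = c3 sum p_j^2 + c4 (A - A_target)^2 (A: shoelace area)."""
    if state.inner.shape[0] == 0:
        return 0.0
    _, p = _edges(state.inner)
    A = polygon_area(state.inner)
    return float(params.c3 * np.sum(p**2) + params.c4 * (A - params.A_target) ** 2)


def contact_energy(state: TwoLayerState, params: ModelParams) -> float:
    """H_contact = c5 sum ||t_i - tau_i||^2 over contact pairs."""
    if state.contacts.size == 0:
        return 0.0
    d = state.outer[state.contacts] - state.inner
    return float(params.c5 * np.sum(d**2))


def _points_in_polygon(points: np.ndarray, poly: np.ndarray) -> np.ndarray:
    """Vectorized winding-number interiority test (winding != 0)."""
    if poly.shape[0] < 3:
        return np.zeros(points.shape[0], dtype=bool)
    a = poly
    b = np.roll(poly, -1, axis=0)
    px = points[:, 0][:, None]
    py = points[:, 1][:, None]
    ay, by = a[:, 1][None, :], b[:, 1][None, :]
    upward = (ay <= py) & (by > py)
    downward = (ay > py) & (by <= py)
    is_left = ((b[:, 0] - a[:, 0])[None, :] * (py - ay)
               - (px - a[:, 0][None, :]) * (by - ay))
    wn = (upward & (is_left > 0)).sum(axis=1) - (downward & (is_left < 0)).sum(axis=1)
    return wn != 0


def _closest_point_on_segments(points: np.ndarray, poly: np.ndarray
                               ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per point: squared distance to the polygon boundary, the foot point,
    the index of the nearest segment and the barycentric parameter on it."""
    a = poly
    e = np.roll(poly, -1, axis=0) - poly
    ee = np.einsum("ij,ij->i", e, e)
    diff = points[:, None, :] - a[None, :, :]          # (P, M, 2)
    t = np.clip(np.einsum("pmj,mj->pm", diff, e) / ee[None, :], 0.0, 1.0)
    foot = a[None, :, :] + t[..., None] * e[None, :, :]
    d2 = np.sum((points[:, None, :] - foot) ** 2, axis=-1)
    k = np.argmin(d2, axis=1)
    rows = np.arange(points.shape[0])
    return d2[rows, k], foot[rows, k], k, t[rows, k]


def cross_penalty(state: TwoLayerState, params: ModelParams) -> float:
    """c6 * sum over outer beads inside the cortex polygon of d^2 to its boundary."""
    if state.inner.shape[0] < 3 or params.c6 == 0.0:
        return 0.0
    inside = _points_in_polygon(state.outer, state.inner)
    if not inside.any():
        return 0.0
    d2, _, _, _ = _closest_point_on_segments(state.outer[inside], state.inner)
    return float(params.c6 * np.sum(d2))


def total_energy(state: TwoLayerState, params: ModelParams) -> float:
    return (outer_energy(state, params) + inner_energy(state, params)
            + contact_energy(state, params) + cross_penalty(state, params))


def _gradients(state: TwoLayerState, params: ModelParams
               ) -> tuple[np.ndarray, np.ndarray]:
    """Analytic gradients of H (without H_self) wrt outer and inner beads."""
    x = state.outer
    N = params.N
    e, l = _edges(x)
    ehat = e / l[:, None]

    # stretching
    a = params.outer_perimeter / N
    g = 2.0 * params.c2 * (l - a)
    grad_out = np.roll(g[:, None] * ehat, 1, axis=0) - g[:, None] * ehat

    # bending: B = sum theta_i^2 / m_i^2
    prev_e = np.roll(e, 1, axis=0)
    prev_l = np.roll(l, 1)
    cross = prev_e[:, 0] * e[:, 1] - prev_e[:, 1] * e[:, 0]
    dot = np.einsum("ij,ij->i", prev_e, e)
    theta = np.arctan2(cross, dot)
    m = 0.5 * (prev_l + l)
    A_c = 2.0 * theta / m**2                    # dB/dtheta_i
    C_c = -(theta**2) / m**3                    # dB/dl for each adjacent edge
    perp = _perp(e)
    G_e = ((np.roll(A_c, -1) - A_c)[:, None] * perp / (l**2)[:, None]
           + (C_c + np.roll(C_c, -1))[:, None] * ehat)
    grad_out += params.c1 * (np.roll(G_e, 1, axis=0) - G_e)

    if state.inner.shape[0] == 0:
        return grad_out, np.zeros((0, 2))

    y = state.inner
    ey, _ = _edges(y)
    # inner springs: d/dy sum |e_j|^2
    grad_in = 2.0 * params.c3 * (np.roll(ey, 1, axis=0) - ey)
    # area term
    A = polygon_area(y)
    dA = 0.5 * np.column_stack([np.roll(y[:, 1], -1) - np.roll(y[:, 1], 1),
                                np.roll(y[:, 0], 1) - np.roll(y[:, 0], -1)])
    grad_in += 2.0 * params.c4 * (A - params.A_target) * dA
    # contacts
    d = x[state.contacts] - y
    grad_out[state.contacts] += 2.0 * params.c5 * d
    grad_in -= 2.0 * params.c5 * d
    # cross penalty; the foot-point parameter distributes the reaction force
    # onto the two endpoints of the nearest cortex segment
    if y.shape[0] >= 3 and params.c6 > 0.0:
        inside = _points_in_polygon(x, y)
        if inside.any():
            _, foot, seg, tpar = _closest_point_on_segments(x[inside], y)
            w = 2.0 * params.c6 * (x[inside] - foot)
            grad_out[inside] += w
            Mv = y.shape[0]
            np.add.at(grad_in, seg, -w * (1.0 - tpar)[:, None])
            np.add.at(grad_in, (seg + 1) % Mv, -w * tpar[:, None])
    return grad_out, grad_in


# ---------------------------------------------------------------------------
# crossing predicates (H_self hard constraint)
# ---------------------------------------------------------------------------

def winding_number(point, polygon) -> int:
    """Signed winding number of ``polygon`` (closed) about ``point``.

    The interiority indicator of the cross penalty is (winding != 0); for a
    self-overlapping contour (e.g. a pentagram) the winding counts the
    overlap multiplicity.
    """
    poly = polygon.vertices if isinstance(polygon, Contour2D) else np.asarray(polygon, float)
    p = np.asarray(point, float)
    a = poly
    b = np.roll(poly, -1, axis=0)
    wn = 0
    for (ax, ay), (bx, by) in zip(a, b):
        if ay <= p[1]:
            if by > p[1] and (bx - ax) * (p[1] - ay) - (p[0] - ax) * (by - ay) > 0:
                wn += 1
        else:
            if by <= p[1] and (bx - ax) * (p[1] - ay) - (p[0] - ax) * (by - ay) < 0:
                wn -= 1
    return wn


def _orient(a, b, c) -> float:
    return (b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0])


def segments_cross(a1, a2, b1, b2) -> bool:
    """True iff open segments (a1,a2) and (b1,b2) properly intersect.

    Shared endpoints (adjacent contour segments) do not count as crossings;
    collinear overlapping segments do.
    """
    a1, a2, b1, b2 = (np.asarray(p, float) for p in (a1, a2, b1, b2))
    d1 = _orient(b1, b2, a1)
    d2 = _orient(b1, b2, a2)
    d3 = _orient(a1, a2, b1)
    d4 = _orient(a1, a2, b2)
    if ((d1 > 0) != (d2 > 0)) and ((d3 > 0) != (d4 > 0)) and d1 != 0 and d2 != 0 \
            and d3 != 0 and d4 != 0:
        return True
    if d1 == d2 == d3 == d4 == 0.0:
        # collinear: overlapping interiors count as crossing
        u = a2 - a1
        t1 = float(u @ (b1 - a1)) / float(u @ u)
        t2 = float(u @ (b2 - a1)) / float(u @ u)
        lo, hi = min(t1, t2), max(t1, t2)
        return hi > 0.0 and lo < 1.0
    return False


def _proper_crossings(x: np.ndarray, pairs: np.ndarray) -> np.ndarray:
    """Rows of ``pairs`` (edge-index pairs, non-adjacent) that properly cross."""
    if pairs.size == 0:
        return np.empty((0, 2), dtype=int)
    nxt = np.roll(np.arange(x.shape[0]), -1)
    a1 = x[pairs[:, 0]]
    a2 = x[nxt[pairs[:, 0]]]
    b1 = x[pairs[:, 1]]
    b2 = x[nxt[pairs[:, 1]]]

    def orient(p, q, r):
        return ((q[:, 0] - p[:, 0]) * (r[:, 1] - p[:, 1])
                - (q[:, 1] - p[:, 1]) * (r[:, 0] - p[:, 0]))

    d1 = orient(b1, b2, a1)
    d2 = orient(b1, b2, a2)
    d3 = orient(a1, a2, b1)
    d4 = orient(a1, a2, b2)
    hit = ((d1 > 0) != (d2 > 0)) & ((d3 > 0) != (d4 > 0)) \
        & (d1 != 0) & (d2 != 0) & (d3 != 0) & (d4 != 0)
    return pairs[hit]


def _all_edge_pairs(N: int) -> np.ndarray:
    i, j = np.triu_indices(N, k=2)
    keep = ~((i == 0) & (j == N - 1))      # cyclic adjacency
    return np.column_stack([i[keep], j[keep]])


def any_self_crossing(vertices: np.ndarray) -> bool:
    """Exhaustive proper-crossing check over all non-adjacent edge pairs."""
    x = np.asarray(vertices, float)
    return _proper_crossings(x, _all_edge_pairs(x.shape[0])).shape[0] > 0


def _candidate_pairs(x: np.ndarray, margin: float) -> np.ndarray:
    """Non-adjacent edge pairs whose bead anchors are within ``margin``."""
    d = np.linalg.norm(x[:, None, :] - x[None, :, :], axis=-1)
    i, j = np.nonzero(np.triu(d < margin, k=2))
    keep = ~((i == 0) & (j == x.shape[0] - 1))
    return np.column_stack([i[keep], j[keep]])


# ---------------------------------------------------------------------------
# minimization
# ---------------------------------------------------------------------------

@dataclass
class MinimizeResult:
    state: TwoLayerState
    energy: float
    converged: bool
    n_iter: int
    residuals: dict = field(default_factory=dict)
    energy_trace: np.ndarray = field(default_factory=lambda: np.array([]))


def constraint_residuals(state: TwoLayerState, params: ModelParams) -> dict:
    """Relative steady-state residuals of the soft constraints.

    Lengths are relative to the rest edge length a = L/N; the area to
    A_target.  All should fall below 1% at convergence.
    """
    a = params.outer_perimeter / params.N
    _, l = _edges(state.outer)
    res = {"stretch": float(np.max(np.abs(l - a)) / a)}
    if state.inner.shape[0] >= 3:
        A = polygon_area(state.inner)
        res["area"] = float(abs(A - params.A_target) / params.A_target)
        d = np.linalg.norm(state.outer[state.contacts] - state.inner, axis=1)
        res["contact"] = float(np.max(d) / a)
        res["cross"] = cross_penalty(state, params)
    res["self_crossing"] = bool(any_self_crossing(state.outer))
    return res


def minimize(state: TwoLayerState, params: ModelParams,
             max_iter: int = 200_000, tol: float = 1e-8,
             window: int = 100, dt0: float | None = None) -> MinimizeResult:
    """Damped descent on the full Hamiltonian from an arbitrary state.

    FIRE-type damped dynamics with (i) per-step rejection of any move that
    raises the total energy — so the energy is non-increasing along accepted
    steps — and (ii) the hard no-self-crossing rule: beads whose proposed
    move would create a proper crossing of outer segments are kept fixed for
    that iteration.  Terminates when the relative energy decrease over
    ``window`` accepted iterations falls below ``tol``, or at ``max_iter``.

    This is the literal constrained descent; for production M-fold steady
    states use `steady_state`, which relaxes the pre-folded template in the
    M-fold symmetric subspace and is orders of magnitude faster.
    """
    st = state.copy()
    a = params.outer_perimeter / params.N
    if dt0 is None:
        dt0 = 2e-3 * a / max(np.sqrt(params.c2), 1.0)
    # stability is guarded by energy rejection and the displacement cap, so
    # the step is allowed to grow aggressively on smooth stretches
    dt, dt_max = dt0, 1e4 * dt0
    alpha, alpha0 = 0.1, 0.1
    f_inc, f_dec, f_alpha, n_min = 1.1, 0.5, 0.99, 5
    n_good = 0
    vx = np.zeros_like(st.outer)
    vy = np.zeros_like(st.inner)

    margin = 6.0 * a
    pairs = _candidate_pairs(st.outer, margin)
    moved_since_rebuild = 0.0

    H = total_energy(st, params)
    trace = [H]
    n_since_drop = 0
    H_window = H

    it = 0
    for it in range(1, max_iter + 1):
        gx, gy = _gradients(st, params)
        Fx, Fy = -gx, -gy
        P = float(np.sum(Fx * vx) + np.sum(Fy * vy))
        if P > 0:
            vnorm = np.sqrt(np.sum(vx**2) + np.sum(vy**2))
            fnorm = np.sqrt(np.sum(Fx**2) + np.sum(Fy**2))
            if fnorm > 0:
                mix = alpha * vnorm / fnorm
                vx = (1 - alpha) * vx + mix * Fx
                vy = (1 - alpha) * vy + mix * Fy
            n_good += 1
            if n_good > n_min:
                dt = min(dt * f_inc, dt_max)
                alpha *= f_alpha
        else:
            vx[:] = 0.0
            vy[:] = 0.0
            dt *= f_dec
            alpha = alpha0
            n_good = 0
        vx += dt * Fx
        vy += dt * Fy

        # cap the largest single-bead displacement at a fraction of a
        dx = dt * vx
        dy_ = dt * vy
        dmax = max(np.max(np.hypot(dx[:, 0], dx[:, 1])) if dx.size else 0.0,
                   np.max(np.hypot(dy_[:, 0], dy_[:, 1])) if dy_.size else 0.0)
        cap = 0.2 * a
        if dmax > cap:
            scale = cap / dmax
            dx *= scale
            dy_ *= scale
            dmax = cap

        new_outer = st.outer + dx
        # hard no-self-crossing rule: freeze offending beads this iteration
        for _ in range(4):
            bad = _proper_crossings(new_outer, pairs)
            if bad.shape[0] == 0:
                break
            nxt = np.roll(np.arange(params.N), -1)
            frozen = np.unique(np.concatenate([bad.ravel(), nxt[bad.ravel()]]))
            new_outer[frozen] = st.outer[frozen]
            vx[frozen] = 0.0

        new_inner = st.inner + dy_
        cand = TwoLayerState(new_outer, new_inner, st.contacts)
        H_new = total_energy(cand, params)
        if H_new <= H:
            st = cand
            H = H_new
            moved_since_rebuild += dmax
            if moved_since_rebuild > 0.4 * margin:
                pairs = _candidate_pairs(st.outer, margin)
                moved_since_rebuild = 0.0
        else:
            vx[:] = 0.0
            vy[:] = 0.0
            dt *= f_dec
            alpha = alpha0
            n_good = 0
        trace.append(H)

        n_since_drop += 1
        if n_since_drop >= window:
            if H_window - H <= tol * max(abs(H_window), 1e-30):
                break
            H_window = H
            n_since_drop = 0

    converged = it < max_iter
    res = constraint_residuals(st, params)
    return MinimizeResult(st, H, converged, it, res, np.asarray(trace))


def _soft_core(x: np.ndarray, sigma: float, crep: float
               ) -> tuple[float, np.ndarray]:
    """Short-range repulsion between outer beads >= 3 apart along the chain.

    Numerical realization of the hard self-avoidance (c7 -> infinity) under
    the quasi-Newton relaxer: crossing two contour walls would force a bead
    pair inside ``sigma``, which costs ``crep (1 - r/sigma)^2``.  The final
    state is additionally verified crossing-free exactly.
    """
    from scipy.spatial import cKDTree

    N = x.shape[0]
    pairs = cKDTree(x).query_pairs(sigma, output_type="ndarray")
    if pairs.size:
        sep = np.abs(pairs[:, 0] - pairs[:, 1])
        sep = np.minimum(sep, N - sep)
        pairs = pairs[sep >= 3]
    if pairs.size == 0:
        return 0.0, np.zeros_like(x)
    d = x[pairs[:, 0]] - x[pairs[:, 1]]
    r = np.hypot(d[:, 0], d[:, 1])
    pen = 1.0 - r / sigma
    g = (-2.0 * crep * pen / (sigma * r))[:, None] * d
    grad = np.zeros_like(x)
    np.add.at(grad, pairs[:, 0], g)
    np.add.at(grad, pairs[:, 1], -g)
    return float(crep * np.sum(pen**2)), grad


def fold_template(params: ModelParams, width_frac: float = 0.7) -> TwoLayerState:
    """Contracted-cortex state with M flask-shaped folds of the right length.

    Mirrors the intermediate stage of the computation: the cortex has already
    shrunk to its target area (a regular M-gon) and the surface excess hangs
    in M identical folds, each a flask — two radial walls capped by a
    semicircle — whose arc length matches the surface length budget L/M.
    Bending energy is not yet minimal; relaxation shapes the flasks.  The
    template is non-self-intersecting by construction.
    """
    N, M = params.N, params.M
    if M < 3:
        raise ValueError("fold template needs M >= 3")
    a = params.outer_perimeter / N
    r_in = np.sqrt(2.0 * params.A_target / (M * np.sin(2.0 * np.pi / M)))
    ang = 2.0 * np.pi * np.arange(M) / M
    inner = r_in * np.column_stack([np.cos(ang), np.sin(ang)])
    contacts = np.floor(np.arange(M) * N / M).astype(int)
    outer = np.zeros((N, 2))
    for k in range(M):
        i0, i1 = contacts[k], contacts[(k + 1) % M]
        nseg = (i1 - i0) % N or N
        P0, P1 = inner[k], inner[(k + 1) % M]
        s = nseg * a                                   # fold arc length
        c = float(np.linalg.norm(P1 - P0))
        w = min(width_frac * c, 1.6 * s / np.pi)
        h = max((s - np.pi * w / 2.0 - (c - w)) / 2.0, 0.0)
        mid = 0.5 * (P0 + P1)
        u = mid / np.linalg.norm(mid)                  # radial direction
        tv = np.array([-u[1], u[0]])
        if float((P1 - P0) @ tv) < 0:
            tv = -tv
        A0, A1 = mid - 0.5 * w * tv, mid + 0.5 * w * tv
        capc = mid + h * u
        # piecewise path P0 -> A0 -> wall -> cap -> wall -> A1 -> P1
        segs: list[tuple] = []
        segs.append(("L", P0, A0, float(np.linalg.norm(A0 - P0))))
        segs.append(("L", A0, A0 + h * u, h))
        th0 = float(np.arctan2(*(A0 + h * u - capc)[::-1]))
        sgn = 1.0
        pm = capc + 0.5 * w * np.array([np.cos(th0 + np.pi / 2),
                                        np.sin(th0 + np.pi / 2)])
        if float((pm - capc) @ u) < 0:
            sgn = -1.0
        segs.append(("A", capc, (0.5 * w, th0, th0 + sgn * np.pi),
                     0.5 * w * np.pi))
        segs.append(("L", A1 + h * u, A1, h))
        segs.append(("L", A1, P1, float(np.linalg.norm(P1 - A1))))
        total = sum(sg[-1] for sg in segs)
        pos = np.arange(nseg) * total / nseg
        pts = []
        for sarc in pos:
            acc = 0.0
            for j, sg in enumerate(segs):
                if sarc <= acc + sg[-1] or j == len(segs) - 1:
                    tl = (sarc - acc) / sg[-1] if sg[-1] > 0 else 0.0
                    if sg[0] == "L":
                        pts.append(sg[1] + tl * (sg[2] - sg[1]))
                    else:
                        rad, a0_, a1_ = sg[2]
                        th = a0_ + tl * (a1_ - a0_)
                        pts.append(sg[1] + rad * np.array([np.cos(th), np.sin(th)]))
                    break
                acc += sg[-1]
        outer[(i0 + np.arange(nseg)) % N] = np.array(pts)
    return TwoLayerState(outer, inner, contacts)


def steady_state(params: ModelParams, maxiter: int = 20_000,
                 sigma_frac: float = 0.5, crep: float | None = None
                 ) -> MinimizeResult:
    """M-fold steady state: relax the fold template in the symmetric subspace.

    The uniform M-fold configuration is an equilibrium of the full
    Hamiltonian but is only marginally stable against fold pairing (fewer,
    larger folds are energetically cheaper — the model's own coarsening
    prediction), so unconstrained descent at large M drifts out of the
    M-fold basin.  Relaxing over a single fold with rotation boundary
    conditions (gradient projection onto the C_M-symmetric subspace)
    excludes the pairing mode while every energy term remains that of the
    full chain.  Requires N divisible by M; M = 0 returns the circle.
    """
    from scipy.optimize import minimize as _spmin

    N, M = params.N, params.M
    if M == 0:
        state = init_two_layer(params)
        res = constraint_residuals(state, params)
        return MinimizeResult(state, total_energy(state, params), True, 0, res)
    if N % M != 0:
        raise ValueError("steady_state requires N divisible by M")
    n = N // M
    a = params.outer_perimeter / N
    sigma = sigma_frac * a
    if crep is None:
        crep = 3e5 * a**2
    st0 = fold_template(params)
    contacts = st0.contacts
    th = 2.0 * np.pi / M
    ks = np.arange(M)
    C, S = np.cos(th * ks), np.sin(th * ks)

    def replicate(z: np.ndarray) -> TwoLayerState:
        xf = z[:2 * n].reshape(n, 2)
        y0 = z[2 * n:]
        X = np.empty((M, n, 2))
        X[:, :, 0] = C[:, None] * xf[None, :, 0] - S[:, None] * xf[None, :, 1]
        X[:, :, 1] = S[:, None] * xf[None, :, 0] + C[:, None] * xf[None, :, 1]
        Y = np.column_stack([C * y0[0] - S * y0[1], S * y0[0] + C * y0[1]])
        return TwoLayerState(X.reshape(N, 2), Y, contacts)

    def project(gx: np.ndarray, gy: np.ndarray) -> np.ndarray:
        G = gx.reshape(M, n, 2)
        gxf = np.empty((n, 2))
        gxf[:, 0] = np.sum(C[:, None] * G[:, :, 0] + S[:, None] * G[:, :, 1], axis=0)
        gxf[:, 1] = np.sum(-S[:, None] * G[:, :, 0] + C[:, None] * G[:, :, 1], axis=0)
        gy0 = np.array([np.sum(C * gy[:, 0] + S * gy[:, 1]),
                        np.sum(-S * gy[:, 0] + C * gy[:, 1])])
        return np.concatenate([gxf.ravel(), gy0])

    trace: list[float] = []

    def fg(z: np.ndarray) -> tuple[float, np.ndarray]:
        s = replicate(z)
        gx, gy = _gradients(s, params)
        Er, gr = _soft_core(s.outer, sigma, crep)
        return total_energy(s, params) + Er, project(gx + gr, gy)

    z0 = np.concatenate([st0.outer[:n].ravel(), st0.inner[0]])
    r = _spmin(fg, z0, jac=True, method="L-BFGS-B",
               callback=lambda z: trace.append(fg(z)[0]),
               options=dict(maxiter=maxiter, ftol=1e-18, gtol=1e-12))
    state = replicate(r.x)
    res = constraint_residuals(state, params)
    return MinimizeResult(state, total_energy(state, params),
                          bool(r.nit < maxiter), int(r.nit), res,
                          np.asarray(trace))


# ---------------------------------------------------------------------------
# analysis
# ---------------------------------------------------------------------------

def rescale_to_target_area(state: TwoLayerState, A_target: float) -> TwoLayerState:
    """Uniformly dilate both layers so the outer contour encloses ``A_target``."""
    A = abs(polygon_area(state.outer))
    if A == 0.0:
        raise ValueError("degenerate outer contour")
    s = np.sqrt(A_target / A)
    return TwoLayerState(state.outer * s, state.inner * s, state.contacts.copy())


def count_radial_lobes(vertices: np.ndarray, smooth_window: int = 3,
                       rel_prominence: float = 0.1) -> int:
    """Strict local maxima of the radial coordinate about the centroid.

    The radial profile is smoothed with a small periodic moving average and
    peaks must be prominent relative to the overall radial spread, so a
    circle counts 0 and grid-scale wiggle is ignored.  Shared by the fold
    counter here and the phase-field lobe counter.
    """
    v = np.asarray(vertices, float)
    c = v.mean(axis=0)
    r = np.hypot(v[:, 0] - c[0], v[:, 1] - c[1])
    if smooth_window > 1:
        kern = np.ones(smooth_window) / smooth_window
        n = r.size
        r = np.convolve(np.concatenate([r[-smooth_window:], r, r[:smooth_window]]),
                        kern, mode="same")[smooth_window:smooth_window + n]
    spread = float(np.ptp(r))
    # absolute floor: radial wiggle below 0.1% of the mean radius is noise
    prominence = max(rel_prominence * spread, 1e-3 * float(np.mean(r)))
    # rotate so the profile starts at its global minimum: peaks never straddle
    k = int(np.argmin(r))
    r = np.roll(r, -k)
    peaks, _ = find_peaks(r, prominence=prominence)
    return int(peaks.size)


def fold_metrics(state: TwoLayerState, params: ModelParams) -> dict:
    """Per-fold perimeter/area and contour-level bending totals.

    A fold is the outer arc between two consecutive contact points closed by
    its chord.  Totals include the normalized bending energy
    E = (L/N) sum kappa^2 of the whole outer contour and the number of
    radial lobes (== M at a clean steady state).
    """
    x = state.outer
    E = normalized_bending_energy(x)
    out = {
        "total_bending_energy": E,
        "outer_area": abs(polygon_area(x)),
        "folds": [],
        "fold_area_total": 0.0,
        "n_lobes": count_radial_lobes(x, smooth_window=max(3, params.N // (20 * max(params.M, 1)))),
    }
    if state.contacts.size == 0:
        return out
    c_sorted = np.sort(state.contacts)
    M = c_sorted.size
    for k in range(M):
        i0 = c_sorted[k]
        i1 = c_sorted[(k + 1) % M]
        idx = np.arange(i0, i1 + 1) if i1 > i0 else np.concatenate(
            [np.arange(i0, params.N), np.arange(0, i1 + 1)])
        arc = x[idx]
        seg = np.diff(arc, axis=0)
        arc_len = float(np.hypot(seg[:, 0], seg[:, 1]).sum())
        chord = float(np.linalg.norm(arc[-1] - arc[0]))
        area = abs(polygon_area(arc))        # arc closed by its chord
        bend = float(np.sum(turning_angle_curvature(x)[idx[1:-1]] ** 2))
        out["folds"].append({"fold_id": k, "perimeter": arc_len + chord,
                             "area": area, "bending": bend})
        out["fold_area_total"] += area
    return out
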