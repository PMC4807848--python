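"""Free-energy functionals of the multi-phase-field model.

Total free energy F = F_S + F_B + F_p + F_anch + F_SA:

* F_S    — interfacial tension of both diffuse interfaces plus a penalty on
           three-phase coexistence.
* F_B    — Helfrich-type bending energy of the cell surface with a spatial
           spontaneous-curvature field C1, in the diffuse Willmore form; on
           a resolved interface it reduces to (gamma1b/2) * int (H - C1)^2 dA.
* F_p    — Frank-Oseen distortion plus Landau-deGennes bulk energy of the
           cortical nematic, gated by phi2^2.
* F_anch — director anchoring at the cell surface, (alpha1/2)(p . grad phi1)^2.
* F_SA   — quadratic penalty (lam_S/2)(S - s0 S*)^2 holding the diffuse
           surface-area estimate at the prescribed excess s0.

The same calibration constants (K_SURF, K_BEND) make the slab area exact and
the sphere bending energy radius-independent; see `core`.
"""

from __future__ import annotations

import numpy as np

from .core import (
    K_BEND,
    K_SURF,
    FieldParams,
    PhaseState,
    double_well,
    double_well_prime,
)

__all__ = [
    "interface_density",
    "surface_energy",
    "surface_area_estimate",
    "coarea_surface_area",
    "bending_operator",
    "bending_energy",
    "nematic_energy",
    "anchoring_energy",
    "area_penalty",
    "total_energy",
    "chemical_potentials",
    "director_force",
]


def interface_density(grid, phi: np.ndarray, eps: float) -> np.ndarray:
    """eps/2 |grad phi|^2 + W(phi)/eps — the diffuse interface density."""
    g = grid.gradient(phi)
    return 0.5 * eps * sum(c**2 for c in g) + double_well(phi) / eps


def surface_area_estimate(state: PhaseState, params: FieldParams) -> float:
    """Geometric area of the cell surface, estimated from phi1.

    K_SURF * int f(phi1): equals the exact area for the equilibrium profile
    (slab to machine precision, sphere to O((eps/R)^2))."""
    return K_SURF * state.grid.integrate(
        interface_density(state.grid, state.phi1, params.eps))


def coarea_surface_area(state: PhaseState, params: FieldParams) -> float:
    """Interface area via the coarea formula: int 6 phi(1-phi) |grad phi|.

    Exactly the geometric area for any monotone profile shape or width
    (int 6 phi(1-phi) dphi = 1), unlike the energy-based estimate which can
    be inflated by off-equilibrium profile widening.  Used as the drive of
    the area penalty when params.area_measure == "coarea"."""
    g = state.grid
    grad = g.gradient(state.phi1)
    gnorm = np.sqrt(sum(c**2 for c in grad))
    return float(g.integrate(6.0 * state.phi1 * (1.0 - state.phi1) * gnorm))


def _area_and_mu(state: PhaseState, params: FieldParams):
    """Selected area estimate and its variational derivative wrt phi1."""
    g = state.grid
    if params.area_measure == "coarea":
        grad = g.gradient(state.phi1)
        gnorm = np.sqrt(sum(c**2 for c in grad) + 1e-12)
        w = 6.0 * state.phi1 * (1.0 - state.phi1)
        S = float(g.integrate(w * gnorm))
        dS = (6.0 * (1.0 - 2.0 * state.phi1) * gnorm
              - g.divergence([w * c / gnorm for c in grad]))
        return S, dS
    S = surface_area_estimate(state, params)
    return S, K_SURF * _surface_mu(g, state.phi1, params.eps)


def surface_energy(state: PhaseState, params: FieldParams) -> float:
    g = state.grid
    e = 0.0
    for gam, phi in ((params.gamma1s, state.phi1), (params.gamma2s, state.phi2),
                     (params.gamma3s, state.phi3)):
        e += K_SURF * gam * g.integrate(interface_density(g, phi, params.eps))
    e += (params.gamma123 / params.eps) * g.integrate(
        state.phi1**2 * state.phi2**2 * state.phi3**2)
    return float(e)


def bending_operator(state: PhaseState, params: FieldParams) -> np.ndarray:
    """Psi = eps lap(phi1) - W'(phi1)/eps - sqrt(2) C1 phi1 (1 - phi1).

    On the equilibrium profile Psi = sqrt(2) phi1(1-phi1) (H - C1), so the
    squared integrand localizes (H - C1)^2 on the interface."""
    eps = params.eps
    lap = state.grid.laplacian(state.phi1)
    return (eps * lap - double_well_prime(state.phi1) / eps
            - np.sqrt(2.0) * state.C1 * state.phi1 * (1.0 - state.phi1))


def bending_energy(state: PhaseState, params: FieldParams) -> float:
    psi = bending_operator(state, params)
    return float(K_BEND * params.gamma1b / params.eps
                 * state.grid.integrate(psi**2))


def nematic_energy(state: PhaseState, params: FieldParams) -> float:
    """int (phi2^2/2) (K |grad p|^2 + h2/2 |p|^4 - h1 |p|^2).

    The phi2^2 gate confines the nematic energy to the cortex; the bulk part
    is minimized by |p| = sqrt(h1/h2) (nematic) for h1 > 0 and by p = 0
    (isotropic) otherwise.  The constant offset is not subtracted, so the
    nematic bulk contribution is negative at equilibrium order."""
    g = state.grid
    grad2 = np.zeros(g.shape)
    for comp in state.p:
        gc = g.gradient(comp)
        grad2 += sum(c**2 for c in gc)
    p2 = sum(c**2 for c in state.p)
    dens = 0.5 * state.phi2**2 * (params.K * grad2
                                  + 0.5 * params.h2 * p2**2 - params.h1 * p2)
    return float(g.integrate(dens))


def anchoring_energy(state: PhaseState, params: FieldParams) -> float:
    g = state.grid
    gphi = g.gradient(state.phi1)
    pdotg = sum(pc * gc for pc, gc in zip(state.p, gphi))
    return float(0.5 * params.alpha1 * g.integrate(pdotg**2))


def area_penalty(state: PhaseState, params: FieldParams) -> float:
    if params.lam_S == 0.0:
        return 0.0
    S = (coarea_surface_area(state, params)
         if params.area_measure == "coarea"
         else surface_area_estimate(state, params))
    return float(0.5 * params.lam_S * (S - params.target_area) ** 2)


def total_energy(state: PhaseState, params: FieldParams) -> float:
    return (surface_energy(state, params) + bending_energy(state, params)
            + nematic_energy(state, params) + anchoring_energy(state, params)
            + area_penalty(state, params))


# ---------------------------------------------------------------------------
# variational derivatives (for the relaxation dynamics)
# ---------------------------------------------------------------------------

def _surface_mu(grid, phi: np.ndarray, eps: float) -> np.ndarray:
    """delta/delta phi of int f(phi): W'(phi)/eps - eps lap(phi)."""
    return double_well_prime(phi) / eps - eps * grid.laplacian(phi)


def chemical_potentials(state: PhaseState, params: FieldParams
                        ) -> tuple[np.ndarray, np.ndarray]:
    """mu1 = dF/dphi1 and mu2 = dF/dphi2 with phi3 = 1 - phi1 - phi2 chained."""
    g = state.grid
    eps = params.eps
    phi1, phi2, phi3 = state.phi1, state.phi2, state.phi3

    mu3 = K_SURF * params.gamma3s * _surface_mu(g, phi3, eps)
    mu1 = K_SURF * params.gamma1s * _surface_mu(g, phi1, eps) - mu3
    mu2 = K_SURF * params.gamma2s * _surface_mu(g, phi2, eps) - mu3

    # triple-phase penalty
    pref = 2.0 * params.gamma123 / eps
    mu1 += pref * (phi1 * phi2**2 * phi3**2 - phi1**2 * phi2**2 * phi3)
    mu2 += pref * (phi1**2 * phi2 * phi3**2 - phi1**2 * phi2**2 * phi3)

    # bending (phi1 only)
    psi = bending_operator(state, params)
    mu1 += (2.0 * K_BEND * params.gamma1b / eps) * (
        eps * g.laplacian(psi)
        - (2.0 - 12.0 * phi1 * (1.0 - phi1)) * psi / eps
        - np.sqrt(2.0) * state.C1 * (1.0 - 2.0 * phi1) * psi)

    # nematic gate (phi2 only)
    if params.h1 != 0.0 or params.K != 0.0:
        grad2 = np.zeros(g.shape)
        for comp in state.p:
            gc = g.gradient(comp)
            grad2 += sum(c**2 for c in gc)
        p2 = sum(c**2 for c in state.p)
        mu2 += phi2 * (params.K * grad2 + 0.5 * params.h2 * p2**2
                       - params.h1 * p2)

    # anchoring (phi1 only)
    if params.alpha1 != 0.0:
        gphi = g.gradient(phi1)
        pdotg = sum(pc * gc for pc, gc in zip(state.p, gphi))
        mu1 -= params.alpha1 * g.divergence([pdotg * pc for pc in state.p])

    # surface-area penalty (phi1 only); drive clamped to sa_drive_max
    if params.lam_S != 0.0:
        S, dS = _area_and_mu(state, params)
        drive = params.lam_S * (S - params.target_area)
        drive = float(np.clip(drive, -params.sa_drive_max, params.sa_drive_max))
        # gate the drive to the interfacial band: an ungated inflation force
        # pumps bulk noise into satellite droplets
        gate = np.clip(4.0 * phi1 * (1.0 - phi1), 0.0, 1.0)
        mu1 += drive * gate * dS
    return mu1, mu2


def director_force(state: PhaseState, params: FieldParams) -> list[np.ndarray]:
    """-dF/dp, the relaxational force on the director components."""
    g = state.grid
    p2 = sum(c**2 for c in state.p)
    gate = state.phi2**2
    bulk = gate * (params.h2 * p2 - params.h1)
    forces = []
    gphi = g.gradient(state.phi1) if params.alpha1 != 0.0 else None
    pdotg = (sum(pc * gc for pc, gc in zip(state.p, gphi))
             if gphi is not None else None)
    for i, comp in enumerate(state.p):
        f = -bulk * comp
        gc = g.gradient(comp)
        f += params.K * g.divergence([gate * c for c in gc])
        if gphi is not None:
            f -= params.alpha1 * pdotg * gphi[i]
        forces.append(f)
    return forces
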