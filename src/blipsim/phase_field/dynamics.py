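"""Relaxation dynamics: conserved Cahn-Hilliard flow + director relaxation.

The stationary morphologies of the model are reached by gradient flows of
the total free energy: conserved (Cahn-Hilliard) transport for the phase
fractions, which preserves every component volume exactly (the k = 0 Fourier
mode is untouched), and non-conserved relaxation for the nematic director.

Stepping is semi-implicit Fourier-spectral with linear stabilization: the
stiff linear symbol Lambda(k) = S0 + a2 k^2 + a4 k^4 (surface + bending
scales) is subtracted/added so that

    phi^{n+1} = [phi^n - dt M k^2 (mu^n - Lambda phi^n)] / (1 + dt M k^2 Lambda)

is first-order consistent for any Lambda and stable for the stiff terms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import K_BEND, K_SURF, FieldParams, PhaseState
from .energies import chemical_potentials, director_force, total_energy

__all__ = ["RelaxResult", "relax", "relax_director"]


@dataclass
class RelaxResult:
    state: PhaseState
    n_steps: int
    energy_trace: np.ndarray
    volume_drift: tuple[float, float, float]
    aborted: bool = False
    message: str = ""


def _stabilizer(grid, params: FieldParams) -> np.ndarray:
    gmax = max(params.gamma1s, params.gamma2s, params.gamma3s)
    S0 = 2.0 * K_SURF * gmax / params.eps + 2.0 * params.gamma123 / params.eps
    a2 = K_SURF * (params.gamma1s + params.gamma2s + 2.0 * params.gamma3s) * params.eps
    if params.lam_S > 0.0 and np.isfinite(params.sa_drive_max):
        S0 += 2.0 * K_SURF * params.sa_drive_max / params.eps
        a2 += K_SURF * params.sa_drive_max * params.eps
    a4 = 2.0 * K_BEND * params.gamma1b * params.eps
    # safety factor: for modes with dt M k^2 Lambda >> 1 the update is a
    # fixed-point iteration with step 1/Lambda, so Lambda must dominate the
    # true Jacobian regardless of dt
    return 4.0 * (S0 + a2 * grid.k2 + a4 * grid.k2**2)


def relax(state: PhaseState, params: FieldParams, dt: float, n_steps: int,
          evolve_director: bool = False,
          director_substeps: int = 1,
          energy_check_every: int = 0,
          energy_tol: float = 1e-6,
          record_every: int = 0) -> RelaxResult:
    """Evolve phi1, phi2 by stabilized Cahn-Hilliard flow (optionally p too).

    ``energy_check_every > 0`` monitors the total energy and aborts on blow-up
    (relative increase beyond ``energy_tol`` or non-finite fields), returning
    the last healthy state.  ``record_every`` controls the energy trace
    density (0 records only start/end).
    """
    g = state.grid
    lam = _stabilizer(g, params)
    M = params.mobility
    st = state.copy()
    v0 = st.volumes()

    trace = [total_energy(st, params)]
    prev_energy = trace[0]
    aborted, message = False, ""

    for step in range(1, n_steps + 1):
        mu1, mu2 = chemical_potentials(st, params)
        ph1 = g.fft(st.phi1)
        ph2 = g.fft(st.phi2)
        denom = 1.0 + dt * M * g.k2 * lam
        ph1 = (ph1 - dt * M * g.k2 * (g.fft(mu1) - lam * ph1)) / denom
        ph2 = (ph2 - dt * M * g.k2 * (g.fft(mu2) - lam * ph2)) / denom
        st.phi1 = g.ifft(ph1)
        st.phi2 = g.ifft(ph2)

        if evolve_director:
            _director_steps(st, params, dt, director_substeps)

        if record_every and step % record_every == 0:
            trace.append(total_energy(st, params))
        if energy_check_every and step % energy_check_every == 0:
            e = trace[-1] if record_every and step % record_every == 0 \
                else total_energy(st, params)
            if not np.isfinite(e) or not np.all(np.isfinite(st.phi1)):
                aborted, message = True, f"non-finite fields at step {step}"
                break
            if e > prev_energy + energy_tol * (abs(prev_energy) + 1e-30):
                aborted, message = True, (
                    f"energy increased at step {step}: {prev_energy} -> {e}")
                break
            prev_energy = e

    trace.append(total_energy(st, params))
    v1 = st.volumes()
    drift = tuple(abs(b - a) / (abs(a) + 1e-30) for a, b in zip(v0, v1))
    return RelaxResult(st, step if n_steps else 0, np.asarray(trace), drift,
                       aborted, message)


def _director_steps(st: PhaseState, params: FieldParams, dt: float,
                    substeps: int) -> None:
    """Explicit relaxation of p, restricted to the cortex (phi2 > 0.01).

    The step is automatically subdivided to respect the explicit stability
    bound of the stiffest local terms (Frank diffusion at the grid Nyquist
    wavenumber, the Landau-deGennes bulk slope and the anchoring force)."""
    g = st.grid
    mask = st.phi2 > 0.01
    total = dt * params.director_mobility
    pmax2 = max(float(max(np.max(c**2) for c in st.p)), 1.0)
    k2max = float(np.max(g.k2)) * (2.0 if g.dim == 2 else 3.0) / 2.0
    stiff = (abs(params.h1) + 3.0 * params.h2 * pmax2
             + params.K * k2max + abs(params.alpha1) / params.eps**2 * 0.1)
    h_stable = 0.5 / stiff
    n_sub = max(substeps, int(np.ceil(total / h_stable)))
    h = total / n_sub
    for _ in range(n_sub):
        forces = director_force(st, params)
        for comp, f in zip(st.p, forces):
            comp[mask] += h * f[mask]


def relax_director(state: PhaseState, params: FieldParams, dt: float,
                   n_steps: int) -> PhaseState:
    """Relax only the director at frozen phase fields."""
    st = state.copy()
    for _ in range(n_steps):
        _director_steps(st, params, dt, 1)
    return st
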