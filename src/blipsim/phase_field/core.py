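"""Grids, parameters and state for the multi-phase-field cell model.

Three volume fractions partition the computational box: phi1 (exterior
aqueous medium), phi2 (nematic actomyosin cortex) and phi3 (interior
cytosol), with phi1 + phi2 + phi3 = 1 pointwise.  The cell surface is the
level set phi1 = 0.5 (where phi3 = 0) and the cortex-cytosol interface is
phi2 = phi3 = 0.5.  The cortex carries a nematic director field p whose
magnitude |p| in [0, 1] is the scalar order parameter of cortical F-actin.

All fields live on a periodic uniform grid; spectral (FFT) differentiation
is used throughout.  Units are dimensionless box units; the physical scale
(a rounded cell of ~8 um radius spanning half the box) enters only when
interpreting outputs.

Diffuse-interface conventions (fixed package-wide):

* double well        W(phi) = phi^2 (1 - phi)^2
* interface density  f(phi) = eps/2 |grad phi|^2 + W(phi)/eps
* equilibrium profile across a flat interface
                     phi(d) = (1 + tanh(d / (sqrt(2) eps))) / 2
* calibration        K_SURF = 3 sqrt(2)  makes  K_SURF * integral(f) the
  geometric interface area exactly;  K_BEND = 3/sqrt(2)  makes the bending
  functional reduce to (gamma_b/2) * integral (H - C1)^2 dA on resolved
  interfaces (H = sum of principal curvatures).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["K_SURF", "K_BEND", "Grid", "FieldParams", "PhaseState",
           "double_well", "double_well_prime", "equilibrium_profile"]

K_SURF = 3.0 * np.sqrt(2.0)
K_BEND = 3.0 / np.sqrt(2.0)


def double_well(phi: np.ndarray) -> np.ndarray:
    return phi**2 * (1.0 - phi) ** 2


def double_well_prime(phi: np.ndarray) -> np.ndarray:
    return 2.0 * phi * (1.0 - phi) * (1.0 - 2.0 * phi)


def equilibrium_profile(d: np.ndarray, eps: float) -> np.ndarray:
    """Equilibrium tanh profile of signed distance (phi = 1 at d -> +inf)."""
    return 0.5 * (1.0 + np.tanh(d / (np.sqrt(2.0) * eps)))


class Grid:
    """Periodic uniform grid with cached spectral operators (2D or 3D)."""

    def __init__(self, shape: tuple[int, ...], box_size: float = 1.0):
        if len(shape) not in (2, 3):
            raise ValueError("grid must be 2D or 3D")
        self.shape = tuple(shape)
        self.dim = len(shape)
        self.box_size = float(box_size)
        self.h = self.box_size / shape[0]
        if any(abs(self.box_size / s - self.h) > 1e-12 for s in shape):
            raise ValueError("grid must be isotropic (cubic cells)")
        ks = [2.0 * np.pi * np.fft.fftfreq(n, d=self.h) for n in shape[:-1]]
        ks.append(2.0 * np.pi * np.fft.rfftfreq(shape[-1], d=self.h))
        mesh = np.meshgrid(*ks, indexing="ij")
        self.kvec = mesh
        self.k2 = sum(k**2 for k in mesh)
        self.cell_volume = self.h ** self.dim

    # -- transforms -------------------------------------------------------
    def fft(self, f: np.ndarray) -> np.ndarray:
        return np.fft.rfftn(f)

    def ifft(self, fh: np.ndarray) -> np.ndarray:
        return np.fft.irfftn(fh, s=self.shape, axes=range(self.dim))

    # -- differential operators ------------------------------------------
    def laplacian(self, f: np.ndarray) -> np.ndarray:
        return self.ifft(-self.k2 * self.fft(f))

    def gradient(self, f: np.ndarray) -> list[np.ndarray]:
        fh = self.fft(f)
        return [self.ifft(1j * k * fh) for k in self.kvec]

    def divergence(self, v: list[np.ndarray]) -> np.ndarray:
        out = np.zeros(self.shape)
        for k, comp in zip(self.kvec, v):
            out += self.ifft(1j * k * self.fft(comp))
        return out

    def integrate(self, f: np.ndarray) -> float:
        return float(np.sum(f) * self.cell_volume)

    def coords(self) -> list[np.ndarray]:
        axes = [np.arange(n) * self.h for n in self.shape]
        return np.meshgrid(*axes, indexing="ij")


@dataclass
class FieldParams:
    """Constitutive coefficients of the phase-field free energy.

    gamma1s/gamma2s set the cell-surface tension, gamma2s/gamma3s the
    cortex-cytosol tension; gamma123 penalizes three-phase coexistence.
    gamma1b is the surface bending rigidity; eps the interface thickness
    parameter (the tanh profile spans ~4*eps).  K is the one-constant Frank
    elasticity, h1/h2 the Landau-deGennes bulk coefficients whose ratio is
    the Flory order parameter (equilibrium |p| = sqrt(h1/h2) for h1 > 0,
    isotropic p = 0 for h1 <= 0).  alpha1 > 0 anchors the director
    tangentially to the surface, alpha1 < 0 normally.  lam_S weights the
    quadratic penalty holding the diffuse surface area at s0 * S_star.
    """

    eps: float = 0.02
    gamma1s: float = 1.0
    gamma2s: float = 1.0
    gamma3s: float = 1.0
    gamma123: float = 1.0
    gamma1b: float = 1e-4
    K: float = 1e-3
    h1: float = 1.0
    h2: float = 1.0
    alpha1: float = 0.0
    lam_S: float = 0.0
    sa_drive_max: float = np.inf
    s0: float = 1.0
    S_star: float = 0.0
    mobility: float = 1.0
    director_mobility: float = 1.0
    area_measure: str = "energy"   # "energy" (Eq-14-style f-integral) or
                                   # "coarea" (width-gauge-invariant)

    def __post_init__(self) -> None:
        if self.eps <= 0:
            raise ValueError("eps must be positive")
        if self.h2 <= 0:
            raise ValueError("h2 must be positive")

    @property
    def equilibrium_order(self) -> float:
        """Bulk-cortex equilibrium scalar order parameter |p|."""
        return float(np.sqrt(self.h1 / self.h2)) if self.h1 > 0 else 0.0

    @property
    def target_area(self) -> float:
        return self.s0 * self.S_star


@dataclass
class PhaseState:
    """Phase fractions, director and spontaneous-curvature fields on a grid.

    phi3 is derived (1 - phi1 - phi2), so the partition-of-unity constraint
    holds exactly by construction.  The director p is stored component-wise
    and is meaningful only where phi2 is appreciable.
    """

    grid: Grid
    phi1: np.ndarray
    phi2: np.ndarray
    p: list[np.ndarray] = field(default_factory=list)
    C1: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.phi1.shape != self.grid.shape or self.phi2.shape != self.grid.shape:
            raise ValueError("field shape does not match grid")
        if not self.p:
            self.p = [np.zeros(self.grid.shape) for _ in range(self.grid.dim)]
        if self.C1 is None:
            self.C1 = np.zeros(self.grid.shape)

    @property
    def phi3(self) -> np.ndarray:
        return 1.0 - self.phi1 - self.phi2

    def order_parameter(self) -> np.ndarray:
        """|p| at every grid point."""
        return np.sqrt(sum(c**2 for c in self.p))

    def volumes(self) -> tuple[float, float, float]:
        g = self.grid
        return (g.integrate(self.phi1), g.integrate(self.phi2),
                g.integrate(self.phi3))

    def copy(self) -> "PhaseState":
        return PhaseState(self.grid, self.phi1.copy(), self.phi2.copy(),
                          [c.copy() for c in self.p], self.C1.copy())
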