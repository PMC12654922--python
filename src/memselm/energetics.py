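"""Energy and entropy functionals of the coupled system and their gradients.

The system state is ``Y = [X, q, thetaP, thetaI, thetaC]``: a particle
position, a dimensionless concentration distribution on the mesh, and the
protein/interface/membrane temperatures.  The total energy is

    E = Psi(X) + C_P thetaP + sum_m Phi(x_m; X) c0 q_m dV
        + sum_m C_C thetaC_m dV + C_I thetaI

and the entropy

    S = C_P ln thetaP + C_I ln thetaI
        + sum_m [ -c0 q_m ln q_m + C_C ln thetaC_m ] dV.

Gradients are reported in the *field-value* convention: the q and thetaC
blocks are the continuum functional-derivative values sampled per cell (no
cell-volume factor), e.g. d S / d thetaC(x_m) = C_C / thetaC_m.

The particle position is kept unwrapped (so mean-square displacements are
meaningful); every field coupling applies the minimum-image convention.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from .grid import (
    Grid,
    KernelSpec,
    kernel_field,
    minimum_image,
    spread_kernel_gradient,
)
from .params import PhysicalParams

__all__ = [
    "SystemState",
    "StateGradient",
    "Potential",
    "ZeroPotential",
    "HarmonicWell",
    "KernelCoupling",
    "WellLattice",
    "total_energy",
    "total_entropy",
    "entropy_gradient",
    "energy_gradient",
    "protein_force",
    "Q_FLOOR",
]

#: Positivity floor used inside logarithms of q (mass itself is never clamped).
Q_FLOOR = 1.0e-12


@dataclass
class SystemState:
    """Full state advanced by the integrator.

    Arrays broadcast over leading batch axes: ``X`` is (..., 2), ``thetaP``
    and ``thetaI`` are (...,), fields are (..., ny, nx).  ``q`` may be None
    for studies without a concentration field.
    """

    X: np.ndarray
    q: Optional[np.ndarray]
    thetaP: np.ndarray
    thetaI: np.ndarray
    thetaC: np.ndarray

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.thetaP = np.asarray(self.thetaP, dtype=float)
        self.thetaI = np.asarray(self.thetaI, dtype=float)
        self.thetaC = np.asarray(self.thetaC, dtype=float)
        if self.q is not None:
            self.q = np.asarray(self.q, dtype=float)

    def copy(self) -> "SystemState":
        return SystemState(
            X=self.X.copy(),
            q=None if self.q is None else self.q.copy(),
            thetaP=self.thetaP.copy(),
            thetaI=self.thetaI.copy(),
            thetaC=self.thetaC.copy(),
        )

    @property
    def batch_shape(self) -> tuple[int, ...]:
        return self.X.shape[:-1]

    def positivity_ok(self, q_tol: float = 1.0e-12) -> bool:
        """Temperatures strictly positive; q nonnegative up to ``q_tol``.

        The conserved (divergence-form) multiplicative concentration noise
        lets near-empty cells overdraw by at most roughly one step's noise at
        the self-limiting scale (the integrator passes that scale in as the
        tolerance); such excursions are accepted rather than clamped, so the
        total mass stays exact.  Anything larger rejects the step.
        """
        ok = (
            bool(np.all(self.thetaP > 0))
            and bool(np.all(self.thetaI > 0))
            and bool(np.all(self.thetaC > 0))
        )
        if ok and self.q is not None:
            ok = bool(np.min(self.q) >= -q_tol)
        return ok


@dataclass
class StateGradient:
    """Component-wise gradient over [X, q, thetaP, thetaI, thetaC]."""

    X: np.ndarray
    q: Optional[np.ndarray]
    thetaP: np.ndarray
    thetaI: np.ndarray
    thetaC: np.ndarray


class Potential:
    """Pluggable potential: particle energy Psi plus chemical potential Phi."""

    has_phi: bool = False

    def psi(self, X: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def grad_psi(self, X: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def phi(self, X: np.ndarray, grid: Grid) -> np.ndarray:
        """Phi(x_m; X) sampled on cells, shape (..., ny, nx)."""
        raise NotImplementedError

    def grad_X_phi(self, X: np.ndarray, grid: Grid):
        """d Phi(x_m; X) / d X, both components, each (..., ny, nx)."""
        raise NotImplementedError


class ZeroPotential(Potential):
    def psi(self, X):
        return np.zeros(np.shape(X)[:-1])

    def grad_psi(self, X):
        return np.zeros_like(np.asarray(X, dtype=float))


class HarmonicWell(Potential):
    """Psi(X) = (k/2) |X - a|^2 (non-periodic; confining wells only)."""

    def __init__(self, k: float, center=(0.0, 0.0)):
        self.k = float(k)
        self.center = np.asarray(center, dtype=float)

    def psi(self, X):
        d = np.asarray(X, dtype=float) - self.center
        return 0.5 * self.k * np.sum(d * d, axis=-1)

    def grad_psi(self, X):
        return self.k * (np.asarray(X, dtype=float) - self.center)


class KernelCoupling(Potential):
    """Concentration-coupled interaction Phi(x; X) = sign * eta(x - X).

    With ``attractive=True`` (the default) the sign is -1, so the interaction
    energy decreases with particle/concentration overlap and the resulting
    force pulls the protein toward regions of high concentration — the mutual
    attraction of the positioning study.  The kernel amplitude k1 sets the
    coupling strength.
    """

    has_phi = True

    def __init__(self, kernel: KernelSpec, attractive: bool = True):
        self.kernel = kernel
        self.sign = -1.0 if attractive else 1.0

    def psi(self, X):
        return np.zeros(np.shape(X)[:-1])

    def grad_psi(self, X):
        return np.zeros_like(np.asarray(X, dtype=float))

    def phi(self, X, grid):
        return self.sign * kernel_field(self.kernel, X, grid)

    def grad_X_phi(self, X, grid):
        # d/dX eta(x - X) = -grad_x eta evaluated at s = x - X
        gx, gy = spread_kernel_gradient(X, self.kernel, grid)
        return -self.sign * gx, -self.sign * gy

    def phi_and_gradX(self, X, grid):
        """(Phi, dPhi/dX_1, dPhi/dX_2) sharing one kernel evaluation."""
        from .grid import kernel_field_and_gradient

        w, gx, gy = kernel_field_and_gradient(self.kernel, X, grid)
        return self.sign * w, -self.sign * gx, -self.sign * gy


class WellLattice(Potential):
    """Gaussian energy wells Psi(X) = sum_i -c2 exp(-|X - X_i|^2 / 2 sigma0^2).

    Centers are replicated periodically through the minimum-image convention
    on a domain of size (Lx, Ly).
    """

    def __init__(self, c2: float, sigma0: float, centers: np.ndarray, Lx: float, Ly: float):
        self.c2 = float(c2)
        self.sigma0 = float(sigma0)
        self.centers = np.asarray(centers, dtype=float).reshape(-1, 2)
        self.Lx = float(Lx)
        self.Ly = float(Ly)

    @staticmethod
    def staggered(c2: float, sigma0: float, grid: Grid, spacing: float | None = None) -> "WellLattice":
        """Staggered (hexagonal-offset) lattice filling the periodic domain.

        Rows of wells are offset by half the spacing; the spacing defaults to
        a third of the domain width so neighboring wells (width sigma0) do
        not overlap.
        """
        if spacing is None:
            spacing = grid.Lx / 3.0
        nrow = max(1, int(round(grid.Ly / spacing)))
        ncol = max(1, int(round(grid.Lx / spacing)))
        sy = grid.Ly / nrow
        sx = grid.Lx / ncol
        centers = []
        for j in range(nrow):
            # even rows shifted by half a spacing: odd rows carry centers at
            # (i + 1/2) sx, so e.g. (5 Lx/6, Ly/2) is an exact lattice site
            off = 0.5 * sx if j % 2 == 0 else 0.0
            for i in range(ncol):
                centers.append(((i + 0.5) * sx + off, (j + 0.5) * sy))
        return WellLattice(c2, sigma0, np.array(centers), grid.Lx, grid.Ly)

    def _disp(self, X):
        X = np.asarray(X, dtype=float)
        d = X[..., None, :] - self.centers  # (..., n_wells, 2)
        d = np.stack(
            [minimum_image(d[..., 0], self.Lx), minimum_image(d[..., 1], self.Ly)],
            axis=-1,
        )
        return d

    def psi(self, X):
        d = self._disp(X)
        r2 = np.sum(d * d, axis=-1)
        return np.sum(-self.c2 * np.exp(-r2 / (2.0 * self.sigma0**2)), axis=-1)

    def grad_psi(self, X):
        d = self._disp(X)
        r2 = np.sum(d * d, axis=-1)
        w = self.c2 / self.sigma0**2 * np.exp(-r2 / (2.0 * self.sigma0**2))
        return np.sum(w[..., None] * d, axis=-2)


def _q_log(q: np.ndarray) -> np.ndarray:
    return np.log(np.maximum(q, Q_FLOOR))


def total_energy(Y: SystemState, p: PhysicalParams, pot: Potential, grid: Grid) -> np.ndarray:
    dV = grid.cell_volume
    E = pot.psi(Y.X) + p.C_P * Y.thetaP + p.C_I * Y.thetaI
    E = E + p.C_C * np.sum(Y.thetaC, axis=(-2, -1)) * dV
    if Y.q is not None and pot.has_phi:
        E = E + p.c0 * np.sum(pot.phi(Y.X, grid) * Y.q, axis=(-2, -1)) * dV
    return E


def total_entropy(Y: SystemState, p: PhysicalParams, grid: Grid) -> np.ndarray:
    if not (np.all(Y.thetaP > 0) and np.all(Y.thetaI > 0) and np.all(Y.thetaC > 0)):
        raise ValueError("entropy requires strictly positive temperatures")
    dV = grid.cell_volume
    S = p.C_P * np.log(Y.thetaP) + p.C_I * np.log(Y.thetaI)
    S = S + p.C_C * np.sum(np.log(Y.thetaC), axis=(-2, -1)) * dV
    if Y.q is not None:
        # 0 * ln 0 := 0; the floor only guards the logarithm.
        S = S - p.c0 * np.sum(Y.q * _q_log(Y.q), axis=(-2, -1)) * dV
    return S


def entropy_gradient(Y: SystemState, p: PhysicalParams) -> StateGradient:
    gq = None
    if Y.q is not None:
        gq = -p.c0 * (1.0 + _q_log(Y.q))
    return StateGradient(
        X=np.zeros_like(Y.X),
        q=gq,
        thetaP=p.C_P / Y.thetaP,
        thetaI=p.C_I / Y.thetaI,
        thetaC=p.C_C / Y.thetaC,
    )


def energy_gradient(Y: SystemState, p: PhysicalParams, pot: Potential, grid: Grid) -> StateGradient:
    dV = grid.cell_volume
    gX = pot.grad_psi(Y.X)
    gq = None
    if Y.q is not None and pot.has_phi:
        gq = p.c0 * pot.phi(Y.X, grid)
        dphix, dphiy = pot.grad_X_phi(Y.X, grid)
        gX = gX + np.stack(
            [
                p.c0 * np.sum(dphix * Y.q, axis=(-2, -1)) * dV,
                p.c0 * np.sum(dphiy * Y.q, axis=(-2, -1)) * dV,
            ],
            axis=-1,
        )
    elif Y.q is not None:
        gq = np.zeros_like(Y.q)
    return StateGradient(
        X=gX,
        q=gq,
        thetaP=np.broadcast_to(p.C_P, Y.thetaP.shape).copy(),
        thetaI=np.broadcast_to(p.C_I, Y.thetaI.shape).copy(),
        thetaC=np.full_like(Y.thetaC, p.C_C),
    )


def protein_force(Y: SystemState, p: PhysicalParams, pot: Potential, grid: Grid) -> np.ndarray:
    """F_X = -dE/dX: potential force plus the concentration-coupled force."""
    return -energy_gradient(Y, p, pot, grid).X
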