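"""Seeded constructors for test states: blobs, sinusoids, random smooth fields.

Everything here is generated programmatically and reproducibly; identical
seeds give identical fixtures.
"""

from __future__ import annotations

import numpy as np

from .dynamics import Model, substream
from .energetics import KernelCoupling, SystemState, ZeroPotential
from .grid import Grid, KernelSpec
from .params import PhysicalParams
from .scenarios import gaussian_blob, heating_profile, sinusoid_profile

__all__ = [
    "band_limited_field",
    "gaussian_blob",
    "sinusoid_profile",
    "heating_profile",
    "tiny_model",
    "tiny_state",
]


def band_limited_field(grid: Grid, seed: int, *, mean: float = 1.0, amp: float = 0.2, kmax: int = 2) -> np.ndarray:
    """Random smooth positive periodic field: mean + low-mode Fourier noise.

    The relative modulation is bounded by ``amp`` so the field stays positive
    whenever mean*(1-amp) > 0.
    """
    rng = substream(seed)
    f = np.zeros(grid.shape)
    gx, gy = grid.meshgrid()
    for kx in range(-kmax, kmax + 1):
        for ky in range(-kmax, kmax + 1):
            if kx == 0 and ky == 0:
                continue
            phase = 2.0 * np.pi * (kx * gx / grid.Lx + ky * gy / grid.Ly)
            f += rng.normal() * np.cos(phase) + rng.normal() * np.sin(phase)
    f = f / max(np.max(np.abs(f)), 1e-12)
    return mean * (1.0 + amp * f)


def tiny_model(*, with_q: bool = True, with_bath: bool = True, kB: float = 1.0e-3) -> Model:
    """A 4x4 moderate-rate model for dense-oracle tests.

    All rates are O(1) so one integrator step at small dt is dominated by the
    fluctuations rather than the drift, which is what the increment-covariance
    protocol needs.
    """
    grid = Grid(4, 4, 0.25)
    p = PhysicalParams(
        kB=kB,
        c0=1.0,
        kappa_bar=0.5,
        gamma_p=2.0,
        kappa_PI=0.8,
        kappa_CI=0.6,
        kappa_CC=0.7,
        kappa_0=0.5 if with_bath else 0.0,
        C_P=1.1,
        C_C=1.3,
        C_I=0.9,
        theta0=3.0,
    )
    kern = KernelSpec(kind="gaussian", k1=0.8, sigma0=0.12)
    return Model(
        grid=grid,
        params=p,
        potential=KernelCoupling(kern) if with_q else ZeroPotential(),
        coupling=KernelSpec(kind="gaussian", k1=1.0, sigma0=0.12),
        include_q=with_q,
        theta_bath=p.theta0 if with_bath else None,
    )


def tiny_state(model: Model, seed: int = 7) -> SystemState:
    """Smooth, strictly positive 4x4 state with every block active."""
    grid = model.grid
    p = model.params
    q = band_limited_field(grid, seed + 1, mean=1.0, amp=0.3) if model.include_q else None
    return SystemState(
        X=np.array([0.4 * grid.Lx, 0.6 * grid.Ly]),
        q=q,
        thetaP=np.array(1.1 * p.theta0),
        thetaI=np.array(0.9 * p.theta0),
        thetaC=band_limited_field(grid, seed + 2, mean=p.theta0, amp=0.2),
    )
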