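"""Runnable verification protocol for the stochastic numerical methods.

Three suites:

* **convergence** — the deterministic conduction part of the membrane
  temperature equation is evolved for a single sinusoidal mode and compared
  at a fixed time against the exact exponentially decaying continuum
  sinusoid; the max-norm error across dyadic refinements gives the observed
  spatial order (second order expected for the central finite-volume stencil).
* **covariance** — from a frozen small-grid state, n independent single
  integrator steps are drawn and the empirical increment covariance is
  compared entrywise against the fluctuation-dissipation target 2 kB K dt,
  with z-scores under the Gaussian sampling error of a covariance estimate.
* **equilibrium** — the particle block alone must reproduce equilibrium
  statistical mechanics: the Boltzmann position variance in a harmonic well,
  the free-diffusion mean-square-displacement slope, and exact energy
  conservation of the closed deterministic system.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dynamics import (
    Model,
    dense_K_blocks,
    dense_R,
    simulate_particle,
    step,
    substream,
)
from .energetics import (
    HarmonicWell,
    KernelCoupling,
    SystemState,
    ZeroPotential,
    total_energy,
)
from .fixtures import tiny_model, tiny_state
from .grid import Grid, KernelSpec
from .params import PhysicalParams
from .scenarios import gaussian_blob

__all__ = [
    "ConvergenceReport",
    "CovarianceReport",
    "transfer_operator_convergence",
    "increment_covariance_test",
    "equilibrium_suite",
    "run_all",
]


@dataclass
class ConvergenceReport:
    resolutions: list
    dx_values: list
    errors: list
    slope: float
    passed: bool

    def to_dict(self) -> dict:
        return {
            "resolutions": list(self.resolutions),
            "dx": [float(v) for v in self.dx_values],
            "max_errors": [float(v) for v in self.errors],
            "slope": float(self.slope),
            "passed": bool(self.passed),
        }


def transfer_operator_convergence(
    resolutions=(16, 32, 64),
    *,
    kappa: float = 1.0,
    C_C: float = 1.0,
    L: float = 1.0,
    amplitude: float = 0.5,
    theta0: float = 3.0,
    T: float | None = None,
    dt: float | None = None,
    mode: int = 1,
) -> ConvergenceReport:
    """Observed spatial order of the discrete temperature transfer operator.

    Initial condition theta0 + a sin(2 pi m x / L); the exact continuum
    solution decays as exp(-(kappa/C_C) (2 pi m / L)^2 t).  The time step is
    chosen so the temporal (second-order Heun) error is far below the spatial
    error at the finest grid, making the log-log slope of the max-norm error
    a clean estimate of the spatial order.
    """
    lam = (kappa / C_C) * (2.0 * np.pi * mode / L) ** 2
    if T is None:
        T = 1.0 / lam  # one e-fold of decay
    if dt is None:
        dt = T / 1024.0
    errors = []
    dxs = []
    for nres in resolutions:
        grid = Grid(nres, nres, L / nres)
        p = PhysicalParams(
            kB=0.0,
            kappa_CC=kappa,
            C_C=C_C,
            theta0=theta0,
            kappa_CI=0.0,
            kappa_0=0.0,
            # inert values for the blocks not exercised
            c0=1.0,
            kappa_bar=1.0,
            gamma_p=1.0,
            kappa_PI=1.0,
            C_P=1.0,
            C_I=1.0,
        )
        model = Model(grid=grid, params=p, potential=ZeroPotential(), include_q=False, theta_bath=None)
        x = grid.xc
        theta_line = theta0 + amplitude * np.sin(2.0 * np.pi * mode * x / L)
        Y = SystemState(
            X=np.array([0.5 * L, 0.5 * L]),
            q=None,
            thetaP=np.array(theta0),
            thetaI=np.array(theta0),
            thetaC=np.tile(theta_line, (nres, 1)),
        )
        n_steps = int(round(T / dt))
        for _ in range(n_steps):
            Y = step(Y, dt, model, None, noise=False)
        exact = theta0 + amplitude * np.exp(-lam * n_steps * dt) * np.sin(2.0 * np.pi * mode * x / L)
        err = float(np.max(np.abs(Y.thetaC - np.tile(exact, (nres, 1)))))
        errors.append(err)
        dxs.append(grid.dx)
    errs = np.array(errors)
    if np.any(errs <= 0) or np.any(np.diff(errs) >= 0):
        slope = float("nan")
        passed = False
        if np.all(errs == 0):
            # a constant (zero-mode) initial condition is represented exactly
            return ConvergenceReport(list(resolutions), dxs, errors, 0.0, True)
        raise RuntimeError(f"non-monotone error sequence under refinement: {errors}")
    slope = float(np.polyfit(np.log(dxs), np.log(errs), 1)[0])
    passed = 1.85 <= slope <= 2.15
    return ConvergenceReport(list(resolutions), dxs, errors, slope, passed)


@dataclass
class CovarianceReport:
    max_abs_error: float
    max_abs_z: float
    n: int
    dim: int
    passed: bool

    def to_dict(self) -> dict:
        return {
            "max_abs_error": float(self.max_abs_error),
            "max_abs_z": float(self.max_abs_z),
            "n": int(self.n),
            "dim": int(self.dim),
            "passed": bool(self.passed),
        }


def _batch_vectorize(Y: SystemState, model: Model) -> np.ndarray:
    """Flatten a batched state to (n_samples, state_dim)."""
    n = Y.X.shape[0]
    parts = [Y.X.reshape(n, -1)]
    if model.include_q and Y.q is not None:
        parts.append(Y.q.reshape(n, -1))
    parts.append(Y.thetaP.reshape(n, 1))
    parts.append(Y.thetaI.reshape(n, 1))
    parts.append(Y.thetaC.reshape(n, -1))
    return np.concatenate(parts, axis=1)


def _tile_state(Y: SystemState, n: int) -> SystemState:
    return SystemState(
        X=np.tile(Y.X, (n, 1)),
        q=None if Y.q is None else np.tile(Y.q, (n, 1, 1)),
        thetaP=np.full(n, float(Y.thetaP)),
        thetaI=np.full(n, float(Y.thetaI)),
        thetaC=np.tile(Y.thetaC, (n, 1, 1)),
    )


def increment_covariance_test(
    state: SystemState | None = None,
    model: Model | None = None,
    *,
    dt: float = 1.0e-5,
    n: int = 10_000,
    seed: int = 1234,
    z_max: float = 5.0,
) -> CovarianceReport:
    """Empirical one-step increment covariance vs the 2 kB K dt target.

    Uses the dense formula-built K (not the factors) as the oracle; z-scores
    use the Gaussian sampling variance (C_ii C_jj + C_ij^2)/(n-1) of a
    covariance estimate.  Any |z| > z_max fails.
    """
    if model is None:
        model = tiny_model()
    if state is None:
        state = tiny_state(model)
    rng = substream(seed)
    Yb = _tile_state(state, n)
    Y1 = step(Yb, dt, model, rng)
    dY = _batch_vectorize(Y1, model) - _batch_vectorize(Yb, model)
    S = np.cov(dY, rowvar=False)

    K = sum(dense_K_blocks(state, model).values())
    C = 2.0 * model.params.kB * K * dt
    se = np.sqrt((np.outer(np.diag(C), np.diag(C)) + C**2) / (n - 1))
    if model.params.kB == 0.0:
        max_err = float(np.max(np.abs(S)))
        return CovarianceReport(max_err, 0.0, n, C.shape[0], max_err == 0.0)
    z = (S - C) / se
    max_z = float(np.max(np.abs(z)))
    return CovarianceReport(float(np.max(np.abs(S - C))), max_z, n, C.shape[0], max_z < z_max)


def factorization_check(state: SystemState | None = None, model: Model | None = None, *, atol: float = 1.0e-12):
    """Entrywise comparison of the applied factors R R^T with the formula K.

    Returns the maximum absolute entrywise discrepancy (two independent
    construction routes: K from dense divergence/diagonal matrices, R from
    applying the sampling code to unit normals).
    """
    if model is None:
        model = tiny_model()
    if state is None:
        state = tiny_state(model)
    K = sum(dense_K_blocks(state, model).values())
    R = dense_R(state, model)
    err = float(np.max(np.abs(R @ R.T - K)))
    scale = float(np.max(np.abs(K)))
    return err, err <= atol * max(1.0, scale / 1.0)


def equilibrium_suite(
    *,
    n_paths: int = 10_000,
    seed: int = 99,
    kB: float = 1.0e-5,
    theta: float = 3.0,
    gamma_p: float = 0.1,
    k_spring: float = 1.0,
) -> dict:
    """Equilibrium statistical mechanics of the particle block, plus closed-
    system energy conservation of the full coupled model.

    Returns a report dict with measured values, targets, uncertainties and
    pass flags.
    """
    report = {}

    # (a) Boltzmann variance in a harmonic well: Var[X_d] = kB theta / k
    rng = substream(seed, 0)
    tau = gamma_p / k_spring
    dt = tau / 100.0
    burn = int(10 * tau / dt)
    pot = HarmonicWell(k_spring, center=(0.0, 0.0))
    npath_h = max(1000, n_paths // 5)
    X = np.zeros((npath_h, 2))
    X = simulate_particle(X, pot, gamma_p=gamma_p, kB=kB, thetaP=theta, dt=dt, n_steps=burn, rng=rng)
    samples = [X]
    for _ in range(4):
        X = simulate_particle(X, pot, gamma_p=gamma_p, kB=kB, thetaP=theta, dt=dt, n_steps=int(2 * tau / dt), rng=rng)
        samples.append(X)
    xs = np.concatenate(samples, axis=0).ravel()
    var = float(np.var(xs))
    target = kB * theta / k_spring
    se = var * np.sqrt(2.0 / xs.size)
    report["boltzmann_variance"] = {
        "measured": var,
        "target": target,
        "se": se,
        "passed": bool(abs(var - target) < 3.0 * se),
    }

    # (b) free-diffusion MSD slope per axis = 2 kB theta / gamma_p
    rng = substream(seed, 1)
    T = 1.0
    dtf = 1.0e-3
    X0 = np.zeros((n_paths, 2))
    Xf = simulate_particle(X0, ZeroPotential(), gamma_p=gamma_p, kB=kB, thetaP=theta, dt=dtf, n_steps=int(T / dtf), rng=rng)
    slope = float(np.mean(Xf**2) / T)
    target_slope = 2.0 * kB * theta / gamma_p
    rel = abs(slope - target_slope) / target_slope
    report["msd_slope"] = {
        "measured": slope,
        "target": target_slope,
        "rel_error": rel,
        "passed": bool(rel < 0.05),
    }

    # (c) closed-system energy conservation, noise off
    report["energy_conservation"] = closed_system_energy_drift()
    return report


def closed_system_energy_drift(*, n_steps: int = 1000, dt: float = 2.0e-4) -> dict:
    """Relative total-energy drift of the closed deterministic coupled system.

    Table-1-like parameters with the ambient bath and noise switched off; the
    particle starts offset from a concentration blob so mechanical energy,
    the concentration free energy, and all heat reservoirs exchange actively.
    """
    grid = Grid(20, 20, 0.1)
    p = PhysicalParams(
        kB=0.0,
        c0=2.1,
        kappa_bar=1.2e-3,
        gamma_p=13.0,
        kappa_PI=8.2e6,
        kappa_CI=3.0e3,
        kappa_CC=1.3e2,
        kappa_0=0.0,
        C_P=1.2,
        C_C=1.3e2,
        C_I=1.4e2,
        theta0=3.0,
    )
    kern = KernelSpec(kind="gaussian", k1=1.1, sigma0=0.2)
    model = Model(
        grid=grid,
        params=p,
        potential=KernelCoupling(kern),
        coupling=KernelSpec(kind="gaussian", k1=1.0, sigma0=0.2),
        include_q=True,
        theta_bath=None,
    )
    Y = SystemState(
        X=np.array([1.0, 1.0]),
        q=gaussian_blob(grid, (1.5, 1.5), 0.2),
        thetaP=np.array(1.2 * p.theta0),
        thetaI=np.array(0.8 * p.theta0),
        thetaC=np.full(grid.shape, p.theta0),
    )
    E0 = float(total_energy(Y, p, model.potential, grid))
    drift_max = 0.0
    for _ in range(n_steps):
        Y = step(Y, dt, model, None, noise=False)
        E = float(total_energy(Y, p, model.potential, grid))
        drift_max = max(drift_max, abs(E - E0) / abs(E0))
    return {
        "E0": E0,
        "max_rel_drift": drift_max,
        "n_steps": n_steps,
        "passed": bool(drift_max < 1.0e-6),
    }


def run_all(seed: int = 1) -> dict:
    """All three suites; JSON-serializable report."""
    conv = transfer_operator_convergence()
    cov = increment_covariance_test(seed=seed + 1000)
    fac_err, fac_ok = factorization_check()
    eq = equilibrium_suite(seed=seed + 2000)
    return {
        "convergence": conv.to_dict(),
        "covariance": cov.to_dict(),
        "factorization": {"max_abs_error": fac_err, "passed": bool(fac_ok)},
        "equilibrium": eq,
    }
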