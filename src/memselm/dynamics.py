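"""Drift assembly, thermal-fluctuation generation, and the time integrator.

The deterministic drift implements the coupled overdamped equations: particle
drift ``dX/dt = M F_X``, conserved concentration transport with diffusive and
potential-driven fluxes, membrane heat conduction with interfacial and
ambient exchange, and the protein/interface temperature ODEs.  The heating
terms entering the membrane temperature are discretized in the conservative,
face-centered form ``+c0 kappa_bar (GPhi : Gq) + (c0/gamma) q_f |GPhi|^2`` so
that with the ambient bath switched off and noise off the total energy is
conserved exactly in space: every unit of mechanical free energy released by
the particle or the concentration field reappears as heat.

Fluctuations are generated per dissipative block ``j`` as
``h_thm^(j) = sqrt(2 kB dt) R^(j) xi^(j)`` with independent standard normals
``xi^(j)`` and factors satisfying ``K^(j) = R^(j) R^(j)T``:

* particle block: ``R_X = sqrt(thetaP/gamma_p) I`` (diffusivity kB thetaP/gamma_p),
* protein-interface exchange: rank-1 antisymmetric pair with amplitude
  ``sqrt(kappa_PI thetaP thetaI)`` entering thetaP and thetaI with weights
  ``+1/C_P`` and ``-1/C_I``,
* interface-membrane exchange: one such pair per cell with the kernel-weighted
  conductivity ``kappa_CI eta(x_m - X)`` and cell-volume weights chosen so the
  operator is the dissipative generator of the exchange drift,
* membrane-ambient bath: one-sided cell noise (the bath is not tracked),
* concentration: divergence-form (conserved) multiplicative noise
  ``D( sqrt(thetaC_f q_f / (gamma c0 dV)) xi_f )`` — the Dean-Kawasaki flux
  noise, exactly mass free per draw,
* conduction: ``(1/C_C) D( sqrt(kappa_CC/dV) thetaC_f xi_f )``.

The integrator is the two-stage Euler-Heun predictor-corrector; the same
Wiener increments are used in both stages, which evaluates the multiplicative
noise in the Stratonovich sense and absorbs the kB div(K) drift implicitly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np

from .energetics import Potential, SystemState, ZeroPotential, protein_force
from .grid import (
    Grid,
    KernelSpec,
    divergence,
    face_average,
    face_minimum,
    gradient,
    kernel_field,
)
from .params import PhysicalParams

__all__ = [
    "Model",
    "NoiseDraw",
    "StepRejectionError",
    "substream",
    "deterministic_drift",
    "draw_normals",
    "apply_R",
    "sample_fluctuations",
    "step",
    "simulate_particle",
    "DissipativeOperator",
    "assemble_K",
    "dense_K_blocks",
    "dense_R",
    "state_to_vector",
    "state_dim",
]


class StepRejectionError(RuntimeError):
    """Raised when a step cannot satisfy positivity after 5 time halvings."""


def substream(seed: int, *key: int) -> np.random.Generator:
    """Independent, reproducible generator for a (seed, block/replicate) key."""
    return np.random.default_rng(np.random.SeedSequence((int(seed),) + tuple(int(k) for k in key)))


@dataclass
class Model:
    """Bundle of everything defining the dynamics besides the state.

    ``coupling`` is the normalized (amplitude-1) radial kernel used for the
    interface-membrane conductivity field ``kappa_CI(x; X)``.  ``theta_bath``
    selects the ambient mode: None disables the bath term even if kappa_0 > 0
    (a closed system), a float relaxes thetaC toward a uniform temperature,
    and an (ny, nx) array sustains a heating profile.
    """

    grid: Grid
    params: PhysicalParams
    potential: Potential = field(default_factory=ZeroPotential)
    coupling: KernelSpec = field(default_factory=lambda: KernelSpec(kind="gaussian", k1=1.0, sigma0=0.2))
    include_q: bool = True
    theta_bath: Union[None, float, np.ndarray] = None

    def kappa_CI_field(self, X: np.ndarray) -> Optional[np.ndarray]:
        if self.params.kappa_CI == 0.0:
            return None
        return self.params.kappa_CI * kernel_field(self.coupling, X, self.grid)

    def bath_field(self) -> Optional[np.ndarray]:
        if self.theta_bath is None or self.params.kappa_0 == 0.0:
            return None
        return np.asarray(self.theta_bath, dtype=float)


def _avg_faces_to_cells(fx: np.ndarray, fy: np.ndarray) -> np.ndarray:
    """Average a per-face quantity back to cells, summing the two axes.

    Each cell takes half of each of its two faces per axis, so the cell sum
    equals the face sum exactly (the discrete counterpart of integrating the
    contraction over the domain).
    """
    ax = 0.5 * (fx + np.roll(fx, 1, axis=-1))
    ay = 0.5 * (fy + np.roll(fy, 1, axis=-2))
    return ax + ay


def deterministic_drift(
    Y: SystemState,
    model: Model,
    *,
    include_PI_exchange: bool = True,
    _kci: Optional[np.ndarray] = None,
) -> SystemState:
    """Noise-free right-hand side a(Y), shaped like the state.

    ``include_PI_exchange=False`` omits the protein-interface heat exchange,
    which the integrator advances by an exact substep instead (see
    :func:`step`); the full right-hand side is the default.  ``_kci`` lets
    the integrator reuse the kernel-weighted conductivity field it already
    evaluated for the fluctuations at the same state.
    """
    p, grid = model.params, model.grid
    pot = model.potential
    dV = grid.cell_volume

    dq = None
    heatx = heaty = None
    phi = None
    F = -pot.grad_psi(Y.X)
    if model.include_q and Y.q is not None and pot.has_phi:
        # fused kernel evaluation: Phi samples and the force in one pass
        if hasattr(pot, "phi_and_gradX"):
            phi, dpx, dpy = pot.phi_and_gradX(Y.X, grid)
        else:
            phi = pot.phi(Y.X, grid)
            dpx, dpy = pot.grad_X_phi(Y.X, grid)
        F = F - p.c0 * dV * np.stack(
            [np.sum(dpx * Y.q, axis=(-2, -1)), np.sum(dpy * Y.q, axis=(-2, -1))], axis=-1
        )
    dX = F / p.gamma_p

    if model.include_q and Y.q is not None:
        gqx, gqy = gradient(Y.q, grid)
        flux_x = p.kappa_bar * gqx
        flux_y = p.kappa_bar * gqy
        if phi is not None:
            gpx, gpy = gradient(phi, grid)
            qfx, qfy = face_average(Y.q)
            flux_x = flux_x + qfx * gpx / p.gamma
            flux_y = flux_y + qfy * gpy / p.gamma
            # conservative heating: -dPhi-energy/dt deposited into thetaC
            heatx = p.c0 * (p.kappa_bar * gpx * gqx + qfx * gpx * gpx / p.gamma)
            heaty = p.c0 * (p.kappa_bar * gpy * gqy + qfy * gpy * gpy / p.gamma)
        dq = divergence((flux_x, flux_y), grid)

    # membrane temperature
    gtx, gty = gradient(Y.thetaC, grid)
    dthetaC = divergence((p.kappa_CC * gtx, p.kappa_CC * gty), grid) / p.C_C
    if heatx is not None:
        dthetaC = dthetaC + _avg_faces_to_cells(heatx, heaty) / p.C_C

    thetaI_b = Y.thetaI[..., None, None]
    kci = model.kappa_CI_field(Y.X) if _kci is None else _kci
    if kci is not None:
        dthetaC = dthetaC - kci * (Y.thetaC - thetaI_b) / p.C_C

    bath = model.bath_field()
    if bath is not None:
        dthetaC = dthetaC - p.kappa_0 * (Y.thetaC - bath) / p.C_C

    # protein and interface temperatures
    FMF = np.sum(F * F, axis=-1) / p.gamma_p
    dthetaP = FMF / p.C_P
    dthetaI = np.zeros_like(Y.thetaI)
    if include_PI_exchange:
        dthetaP = dthetaP - p.kappa_PI * (Y.thetaP - Y.thetaI) / p.C_P
        dthetaI = dthetaI + p.kappa_PI * (Y.thetaP - Y.thetaI) / p.C_I
    if kci is not None:
        dthetaI = dthetaI + np.sum(kci * (Y.thetaC - thetaI_b), axis=(-2, -1)) * dV / p.C_I

    return SystemState(X=dX, q=dq, thetaP=dthetaP, thetaI=dthetaI, thetaC=dthetaC)


@dataclass
class NoiseDraw:
    """Standard-normal variates for every fluctuation block of one step.

    The same draw must be (and by the integrator is) reused in both stages.
    """

    X: np.ndarray
    PI: np.ndarray
    CI: Optional[np.ndarray]
    bath: Optional[np.ndarray]
    q: Optional[tuple]
    cond: tuple


def draw_normals(Y: SystemState, model: Model, rng: np.random.Generator) -> NoiseDraw:
    shape = Y.batch_shape
    fshape = shape + model.grid.shape
    p = model.params
    return NoiseDraw(
        X=rng.standard_normal(shape + (2,)),
        PI=rng.standard_normal(shape),
        CI=rng.standard_normal(fshape) if p.kappa_CI > 0 else None,
        bath=rng.standard_normal(fshape) if model.bath_field() is not None else None,
        q=(
            (rng.standard_normal(fshape), rng.standard_normal(fshape))
            if (model.include_q and Y.q is not None)
            else None
        ),
        cond=(rng.standard_normal(fshape), rng.standard_normal(fshape)),
    )


def apply_R(
    Y: SystemState,
    model: Model,
    xi: NoiseDraw,
    *,
    include_PI: bool = True,
    _kci: Optional[np.ndarray] = None,
) -> SystemState:
    """Apply the block factors R^(j) to the normals (no kB/dt scaling)."""
    p, grid = model.params, model.grid
    dV = grid.cell_volume

    dX = np.sqrt(Y.thetaP / p.gamma_p)[..., None] * xi.X

    if include_PI:
        amp_PI = np.sqrt(p.kappa_PI * Y.thetaP * Y.thetaI)
        dthetaP = amp_PI / p.C_P * xi.PI
        dthetaI = -amp_PI / p.C_I * xi.PI
    else:
        dthetaP = np.zeros_like(Y.thetaP)
        dthetaI = np.zeros_like(Y.thetaI)

    dthetaC = np.zeros_like(Y.thetaC)
    if xi.CI is not None:
        kci = model.kappa_CI_field(Y.X) if _kci is None else _kci
        amp = np.sqrt(kci * Y.thetaC * Y.thetaI[..., None, None])
        dthetaC = dthetaC + amp / (p.C_C * np.sqrt(dV)) * xi.CI
        dthetaI = dthetaI - np.sum(amp * np.sqrt(dV) * xi.CI, axis=(-2, -1)) / p.C_I
    if xi.bath is not None:
        bath = model.bath_field()
        dthetaC = dthetaC + np.sqrt(p.kappa_0 * Y.thetaC * bath / dV) / p.C_C * xi.bath

    tfx, tfy = face_average(Y.thetaC)
    cx = np.sqrt(p.kappa_CC / dV) * tfx * xi.cond[0]
    cy = np.sqrt(p.kappa_CC / dV) * tfy * xi.cond[1]
    dthetaC = dthetaC + divergence((cx, cy), grid) / p.C_C

    dq = None
    if xi.q is not None:
        # noise face amplitude from the smaller neighbor (self-limiting near
        # depleted cells); drift face coefficients stay arithmetic
        qfx, qfy = face_minimum(Y.q)
        ax = np.sqrt(tfx * np.maximum(qfx, 0.0) / (p.gamma * p.c0 * dV)) * xi.q[0]
        ay = np.sqrt(tfy * np.maximum(qfy, 0.0) / (p.gamma * p.c0 * dV)) * xi.q[1]
        dq = divergence((ax, ay), grid)

    return SystemState(X=dX, q=dq, thetaP=dthetaP, thetaI=dthetaI, thetaC=dthetaC)


def sample_fluctuations(Y: SystemState, model: Model, dt: float, rng: np.random.Generator) -> SystemState:
    """One draw of the assembled fields h_thm = sqrt(2 kB dt) R xi."""
    xi = draw_normals(Y, model, rng)
    return _scale_state(apply_R(Y, model, xi), np.sqrt(2.0 * model.params.kB * dt))


def _scale_state(d: SystemState, s: float) -> SystemState:
    return SystemState(
        X=s * d.X,
        q=None if d.q is None else s * d.q,
        thetaP=s * d.thetaP,
        thetaI=s * d.thetaI,
        thetaC=s * d.thetaC,
    )


def _add_states(Y: SystemState, *terms) -> SystemState:
    """Y + sum of (coef, increment) terms."""
    X, q = Y.X.copy(), None if Y.q is None else Y.q.copy()
    tP, tI, tC = Y.thetaP.copy(), Y.thetaI.copy(), Y.thetaC.copy()
    for c, d in terms:
        X = X + c * d.X
        if q is not None and d.q is not None:
            q = q + c * d.q
        tP = tP + c * d.thetaP
        tI = tI + c * d.thetaI
        tC = tC + c * d.thetaC
    return SystemState(X=X, q=q, thetaP=tP, thetaI=tI, thetaC=tC)


def _pi_exchange_substep(
    Y: SystemState, model: Model, dt: float, rng: Optional[np.random.Generator], use_noise: bool
) -> SystemState:
    """Exact update of the protein-interface heat-exchange pair over dt.

    In the (difference, capacity-weighted sum) variables the P-I block —
    drift and noise together — is an Ornstein-Uhlenbeck process in
    Delta = thetaP - thetaI with rate kappa_PI (1/C_P + 1/C_I), while the
    energy C_P thetaP + C_I thetaI carries no noise at all (the factor
    weights +1/C_P, -1/C_I cancel exactly).  Advancing it in closed form
    sidesteps the extreme stiffness of the printed conductivities
    (kappa_PI/C_P ~ 1e7 in the concentration/sensing studies) while
    conserving the exchanged energy to machine precision and reproducing the
    equilibrium variance kB thetaP thetaI (1/C_P + 1/C_I) exactly.
    """
    p = model.params
    r = p.kappa_PI * (1.0 / p.C_P + 1.0 / p.C_I)
    decay = np.exp(-r * dt)
    delta = Y.thetaP - Y.thetaI
    Sigma = p.C_P * Y.thetaP + p.C_I * Y.thetaI
    new_delta = decay * delta
    if use_noise and rng is not None:
        b2 = 2.0 * p.kB * p.kappa_PI * Y.thetaP * Y.thetaI * (1.0 / p.C_P + 1.0 / p.C_I) ** 2
        var = b2 * (1.0 - decay**2) / (2.0 * r)
        new_delta = new_delta + np.sqrt(var) * rng.standard_normal(np.shape(delta))
    denom = p.C_P + p.C_I
    out = Y.copy()
    out.thetaP = (Sigma + p.C_I * new_delta) / denom
    out.thetaI = (Sigma - p.C_P * new_delta) / denom
    return out


def _attempt_step(
    Y: SystemState,
    dt: float,
    model: Model,
    xi: Optional[NoiseDraw],
    rng: Optional[np.random.Generator],
):
    """One split step: exact P-I exchange halves around an Euler-Heun core.

    The Heun core uses the given (shared) noise draw in both stages; returns
    None on a positivity failure.
    """
    use_noise = xi is not None
    # accepted negative-q band: a few times the self-limited one-step
    # overdraft of the conserved multiplicative noise, q* = 8 kB theta dt /
    # (gamma c0 dV dx^2); zero-noise runs keep the strict (roundoff) bound
    p = model.params
    if use_noise and Y.q is not None and model.include_q:
        theta_max = float(np.max(Y.thetaC))
        q_star = 8.0 * p.kB * theta_max * dt / (p.gamma * p.c0 * model.grid.cell_volume * model.grid.dx**2)
        q_tol = max(10.0 * q_star, 1.0e-12)
    else:
        q_tol = 1.0e-12
    Y = _pi_exchange_substep(Y, model, 0.5 * dt, rng, use_noise)
    kci0 = model.kappa_CI_field(Y.X)
    a0 = deterministic_drift(Y, model, include_PI_exchange=False, _kci=kci0)
    if use_noise:
        s = np.sqrt(2.0 * model.params.kB * dt)
        n0 = _scale_state(apply_R(Y, model, xi, include_PI=False, _kci=kci0), s)
        Yp = _add_states(Y, (dt, a0), (1.0, n0))
    else:
        Yp = _add_states(Y, (dt, a0))
    if not Yp.positivity_ok(q_tol):
        return None
    kci1 = model.kappa_CI_field(Yp.X)
    a1 = deterministic_drift(Yp, model, include_PI_exchange=False, _kci=kci1)
    if use_noise:
        n1 = _scale_state(apply_R(Yp, model, xi, include_PI=False, _kci=kci1), s)
        Yn = _add_states(Y, (0.5 * dt, a0), (0.5 * dt, a1), (0.5, n0), (0.5, n1))
    else:
        Yn = _add_states(Y, (0.5 * dt, a0), (0.5 * dt, a1))
    Yn = _pi_exchange_substep(Yn, model, 0.5 * dt, rng, use_noise)
    if not Yn.positivity_ok(q_tol):
        return None
    return Yn


def step(
    Y: SystemState,
    dt: float,
    model: Model,
    rng: Optional[np.random.Generator] = None,
    *,
    noise: bool = True,
    _depth: int = 0,
    reject_log: Optional[list] = None,
) -> SystemState:
    """Advance the state by dt with the two-stage integrator.

    On a positivity violation the step is rejected and retried as two halves
    (fresh noise, max 5 halvings) before raising :class:`StepRejectionError`.
    """
    if not (dt > 0):
        raise ValueError("dt must be positive")
    use_noise = noise and model.params.kB > 0 and rng is not None
    xi = draw_normals(Y, model, rng) if use_noise else None
    Yn = _attempt_step(Y, dt, model, xi, rng if use_noise else None)
    if Yn is not None:
        return Yn
    if _depth >= 5:
        raise StepRejectionError("positivity violation persisted after 5 time halvings")
    if reject_log is not None:
        reject_log.append((_depth, dt))
    half = dict(noise=noise, _depth=_depth + 1, reject_log=reject_log)
    Y1 = step(Y, 0.5 * dt, model, rng, **half)
    return step(Y1, 0.5 * dt, model, rng, **half)


# ---------------------------------------------------------------------------
# particle-only fast path (fixed uniform temperature)


def simulate_particle(
    X0: np.ndarray,
    pot: Potential,
    *,
    gamma_p: float,
    kB: float,
    thetaP: float,
    dt: float,
    n_steps: int,
    rng: Optional[np.random.Generator] = None,
    mobility=None,
    record_every: int = 0,
):
    """Euler-Heun integration of the particle alone at fixed temperature.

    This is the same two-stage scheme restricted to the position block, valid
    when the fields are frozen at a uniform equilibrium (the condition of the
    equilibrium-statistics checks).  ``mobility`` may be a callable
    ``m(X) -> (...,)`` scalar mobility for position-dependent-drag tests;
    default is the constant 1/gamma_p.

    Returns the final positions, or (final, trajectory) if record_every > 0.
    """
    X = np.asarray(X0, dtype=float).copy()
    mob = (lambda X: 1.0 / gamma_p) if mobility is None else mobility
    traj = []
    for n in range(n_steps):
        m0 = np.asarray(mob(X))
        F0 = -pot.grad_psi(X)
        b0 = np.sqrt(2.0 * kB * thetaP * m0)[..., None]
        if kB > 0 and rng is not None:
            dW = rng.standard_normal(X.shape) * np.sqrt(dt)
        else:
            dW = np.zeros_like(X)
        Xp = X + m0[..., None] * F0 * dt + b0 * dW
        m1 = np.asarray(mob(Xp))
        F1 = -pot.grad_psi(Xp)
        b1 = np.sqrt(2.0 * kB * thetaP * m1)[..., None]
        X = X + 0.5 * (m0[..., None] * F0 + m1[..., None] * F1) * dt + 0.5 * (b0 + b1) * dW
        if record_every and (n + 1) % record_every == 0:
            traj.append(X.copy())
    if record_every:
        return X, np.array(traj)
    return X


# ---------------------------------------------------------------------------
# dense operators for validation (small grids)


def state_dim(Y: SystemState, model: Model) -> int:
    N = model.grid.n_cells
    nq = N if (model.include_q and Y.q is not None) else 0
    return 2 + nq + 1 + 1 + N


def state_to_vector(Y: SystemState, model: Model) -> np.ndarray:
    """Flatten a (non-batched) state to [X, q, thetaP, thetaI, thetaC]."""
    parts = [np.ravel(Y.X)]
    if model.include_q and Y.q is not None:
        parts.append(np.ravel(Y.q))
    parts.append(np.atleast_1d(Y.thetaP))
    parts.append(np.atleast_1d(Y.thetaI))
    parts.append(np.ravel(Y.thetaC))
    return np.concatenate(parts)


def _noise_dims(Y: SystemState, model: Model) -> dict:
    """Ordered noise-coordinate layout per block."""
    N = model.grid.n_cells
    p = model.params
    dims = {"X": 2, "PI": 1}
    dims["CI"] = N if p.kappa_CI > 0 else 0
    dims["bath"] = N if model.bath_field() is not None else 0
    dims["q"] = 2 * N if (model.include_q and Y.q is not None) else 0
    dims["cond"] = 2 * N
    return dims


def _xi_from_vector(Y: SystemState, model: Model, v: np.ndarray) -> NoiseDraw:
    shape = model.grid.shape
    dims = _noise_dims(Y, model)
    out = {}
    off = 0
    for key, n in dims.items():
        blk = v[off : off + n]
        off += n
        if n == 0:
            out[key] = None
        elif key in ("X",):
            out[key] = blk
        elif key == "PI":
            out[key] = blk[0]
        elif key in ("CI", "bath"):
            out[key] = blk.reshape(shape)
        else:  # q / cond faces
            out[key] = (blk[: n // 2].reshape(shape), blk[n // 2 :].reshape(shape))
    return NoiseDraw(**out)


def dense_R(Y: SystemState, model: Model) -> np.ndarray:
    """Dense factor R (state_dim x noise_dim) by applying R to unit normals."""
    total = sum(_noise_dims(Y, model).values())
    cols = []
    for k in range(total):
        e = np.zeros(total)
        e[k] = 1.0
        d = apply_R(Y, model, _xi_from_vector(Y, model, e))
        cols.append(state_to_vector(d, model))
    return np.array(cols).T


def dense_K_blocks(Y: SystemState, model: Model) -> dict:
    """Independent dense construction of each K^(j) from its defining formula.

    Uses the dense divergence matrix and explicit diagonal face coefficient
    matrices (never the factors R), so comparing with R R^T is a two-route
    check of the factorization.
    """
    from .grid import dense_divergence_matrix

    p, grid = model.params, model.grid
    N = grid.n_cells
    dV = grid.cell_volume
    M = state_dim(Y, model)
    has_q = model.include_q and Y.q is not None
    iX = slice(0, 2)
    iq = slice(2, 2 + N) if has_q else None
    ip = 2 + (N if has_q else 0)
    ii = ip + 1
    iC = slice(ii + 1, ii + 1 + N)

    D = dense_divergence_matrix(grid)
    thetaP = float(Y.thetaP)
    thetaI = float(Y.thetaI)
    tC = np.ravel(Y.thetaC)
    tfx, tfy = face_average(Y.thetaC)
    tface = np.concatenate([np.ravel(tfx), np.ravel(tfy)])

    blocks = {}

    KX = np.zeros((M, M))
    KX[0, 0] = KX[1, 1] = thetaP / p.gamma_p
    blocks["protein"] = KX

    KPI = np.zeros((M, M))
    a = p.kappa_PI * thetaP * thetaI
    KPI[ip, ip] = a / p.C_P**2
    KPI[ii, ii] = a / p.C_I**2
    KPI[ip, ii] = KPI[ii, ip] = -a / (p.C_P * p.C_I)
    blocks["protein_interface"] = KPI

    idxC = iC.start + np.arange(N)
    if p.kappa_CI > 0:
        kci = np.ravel(model.kappa_CI_field(Y.X))
        KCI = np.zeros((M, M))
        amp2 = kci * tC * thetaI
        KCI[idxC, idxC] += amp2 / (p.C_C**2 * dV)
        KCI[ii, ii] += np.sum(amp2 * dV) / p.C_I**2
        KCI[idxC, ii] += -amp2 / (p.C_C * p.C_I)
        KCI[ii, idxC] += -amp2 / (p.C_C * p.C_I)
        blocks["interface_membrane"] = KCI

    bath = model.bath_field()
    if bath is not None:
        Kb = np.zeros((M, M))
        bvals = np.ravel(np.broadcast_to(bath, grid.shape))
        Kb[idxC, idxC] += p.kappa_0 * tC * bvals / (p.C_C**2 * dV)
        blocks["ambient"] = Kb

    Kcond = np.zeros((M, M))
    core = D @ np.diag(p.kappa_CC * tface**2 / dV) @ D.T / p.C_C**2
    Kcond[iC, iC.start : iC.stop] = core
    blocks["conduction"] = Kcond

    if has_q:
        from .grid import face_minimum

        qfx, qfy = face_minimum(Y.q)
        qface = np.concatenate([np.ravel(qfx), np.ravel(qfy)])
        Kq = np.zeros((M, M))
        Kq[iq, iq.start : iq.stop] = (
            D @ np.diag(tface * np.maximum(qface, 0.0) / (p.gamma * p.c0 * dV)) @ D.T
        )
        blocks["concentration"] = Kq

    return blocks


@dataclass
class DissipativeOperator:
    """A dissipative block K^(j) with its factor, dense form (validation use)."""

    label: str
    K: np.ndarray
    touches: tuple

    def apply(self, v: np.ndarray) -> np.ndarray:
        return self.K @ v

    def check(self, atol: float = 1.0e-10) -> None:
        if not np.allclose(self.K, self.K.T, atol=atol):
            raise ValueError(f"block {self.label} is not symmetric")
        w = np.linalg.eigvalsh(0.5 * (self.K + self.K.T))
        if w.min() < -atol * max(1.0, w.max()):
            raise ValueError(f"block {self.label} is not positive semidefinite")


def assemble_K(Y: SystemState, model: Model, *, check: bool = True) -> list[DissipativeOperator]:
    """Dense dissipative blocks for the current (non-batched) state."""
    ops = []
    for label, K in dense_K_blocks(Y, model).items():
        touched = tuple(np.nonzero(np.any(K != 0.0, axis=0))[0])
        op = DissipativeOperator(label=label, K=K, touches=touched)
        if check:
            op.check()
        ops.append(op)
    return ops
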