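"""Drift assembly, fluctuation blocks, and the stochastic integrator."""

import numpy as np
import pytest

from memselm.dynamics import (
    Model,
    StepRejectionError,
    apply_R,
    assemble_K,
    dense_K_blocks,
    dense_R,
    deterministic_drift,
    draw_normals,
    sample_fluctuations,
    simulate_particle,
    state_to_vector,
    step,
    substream,
)
from memselm.energetics import KernelCoupling, SystemState, ZeroPotential
from memselm.fixtures import tiny_model, tiny_state
from memselm.grid import Grid, KernelSpec
from memselm.params import PhysicalParams, preset_params
from memselm.scenarios import gaussian_blob


@pytest.fixture
def grid20():
    return Grid(20, 20, 0.1)


def make_model(grid, p, pot=None, **kw):
    return Model(
        grid=grid,
        params=p,
        potential=pot or ZeroPotential(),
        coupling=KernelSpec(k1=1.0, sigma0=0.2),
        **kw,
    )


class TestDrift:
    def test_uniform_equilibrium_is_fixed_point(self, grid20):
        p = preset_params("table1")
        model = make_model(grid20, p, include_q=True, theta_bath=p.theta0)
        Y = SystemState(
            X=np.array([1.0, 1.0]),
            q=np.ones(grid20.shape),
            thetaP=np.array(p.theta0),
            thetaI=np.array(p.theta0),
            thetaC=np.full(grid20.shape, p.theta0),
        )
        a = deterministic_drift(Y, model)
        for block in (a.X, a.q, a.thetaP, a.thetaI, a.thetaC):
            assert np.allclose(block, 0.0, atol=1e-14)

    def test_two_temperature_relaxation_closed_form(self, grid20):
        # only thetaP/thetaI active: exponential decay of the difference at
        # rate kappa_PI (1/C_P + 1/C_I), capacity-weighted sum conserved
        p = PhysicalParams(kB=0.0, kappa_PI=5.7e2, C_P=9.3e2, C_I=1.4e2,
                           kappa_CI=0.0, kappa_0=0.0, kappa_CC=1e-6)
        assert p.kappa_PI / p.C_P == pytest.approx(0.6129, rel=1e-3)
        model = make_model(grid20, p, include_q=False, theta_bath=None)
        Y = SystemState(X=np.zeros(2), q=None, thetaP=np.array(4.0),
                        thetaI=np.array(2.0), thetaC=np.full(grid20.shape, 3.0))
        Sigma0 = p.C_P * 4.0 + p.C_I * 2.0
        dt, n = 1e-2, 50
        for _ in range(n):
            Y = step(Y, dt, model, None, noise=False)
        r = p.kappa_PI * (1 / p.C_P + 1 / p.C_I)
        delta = float(Y.thetaP - Y.thetaI)
        assert delta == pytest.approx(2.0 * np.exp(-r * n * dt), rel=1e-10)
        assert float(p.C_P * Y.thetaP + p.C_I * Y.thetaI) == pytest.approx(Sigma0, rel=1e-12)


class TestDissipativeOperators:
    def test_blocks_symmetric_positive_semidefinite(self):
        model = tiny_model()
        ops = assemble_K(tiny_state(model), model)  # .check() raises on failure
        labels = {op.label for op in ops}
        assert {"protein", "protein_interface", "interface_membrane",
                "ambient", "conduction", "concentration"} <= labels

    def test_concentration_block_annihilates_constants(self):
        # a constant conjugate vector drives no flux: K_q @ 1 = 0
        model = tiny_model()
        Y = tiny_state(model)
        Kq = dense_K_blocks(Y, model)["concentration"]
        N = model.grid.n_cells
        v = np.zeros(Kq.shape[0])
        v[2 : 2 + N] = 1.0
        assert np.allclose(Kq @ v, 0.0, atol=1e-12)

    @pytest.mark.parametrize("with_q,with_bath", [(True, True), (True, False), (False, True)])
    def test_factor_squares_to_operator(self, with_q, with_bath):
        model = tiny_model(with_q=with_q, with_bath=with_bath)
        Y = tiny_state(model)
        K = sum(dense_K_blocks(Y, model).values())
        R = dense_R(Y, model)
        scale = np.max(np.abs(K))
        assert np.max(np.abs(R @ R.T - K)) <= 1e-12 * scale

    def test_protein_factor_matches_mobility_temperature(self):
        model = tiny_model()
        Y = tiny_state(model)
        KX = dense_K_blocks(Y, model)["protein"]
        assert KX[0, 0] == pytest.approx(float(Y.thetaP) / model.params.gamma_p)


class TestFluctuations:
    def test_zero_noise_at_zero_boltzmann_constant(self):
        model = tiny_model(kB=0.0)
        Y = tiny_state(model)
        h = sample_fluctuations(Y, model, 1e-3, substream(0))
        for block in (h.X, h.q, h.thetaP, h.thetaI, h.thetaC):
            assert np.all(block == 0.0)

    def test_draws_have_zero_mean(self):
        model = tiny_model()
        Y = tiny_state(model)
        n = 20000
        Yb = SystemState(
            X=np.tile(Y.X, (n, 1)), q=np.tile(Y.q, (n, 1, 1)),
            thetaP=np.full(n, float(Y.thetaP)), thetaI=np.full(n, float(Y.thetaI)),
            thetaC=np.tile(Y.thetaC, (n, 1, 1)),
        )
        h = sample_fluctuations(Yb, model, 1e-3, substream(1))
        for block, label in ((h.X, "X"), (h.q, "q"), (h.thetaC, "thetaC")):
            m = np.mean(block.reshape(n, -1), axis=0)
            sd = np.std(block.reshape(n, -1), axis=0) / np.sqrt(n)
            assert np.all(np.abs(m) < 4.5 * np.maximum(sd, 1e-15)), label

    def test_concentration_noise_is_exactly_mass_free(self):
        model = tiny_model()
        Y = tiny_state(model)
        for seed in range(5):
            h = sample_fluctuations(Y, model, 1e-3, substream(seed))
            assert abs(np.sum(h.q)) * model.grid.cell_volume < 1e-15


class TestIntegrator:
    def test_identity_at_equilibrium_without_noise(self, grid20):
        p = preset_params("table1").replace(kB=0.0)
        model = make_model(grid20, p, include_q=True, theta_bath=p.theta0)
        Y = SystemState(X=np.array([0.5, 0.5]), q=np.ones(grid20.shape),
                        thetaP=np.array(p.theta0), thetaI=np.array(p.theta0),
                        thetaC=np.full(grid20.shape, p.theta0))
        Y1 = step(Y, 1e-3, model, None, noise=False)
        assert np.array_equal(Y1.X, Y.X)
        assert np.array_equal(Y1.q, Y.q)
        assert np.array_equal(Y1.thetaC, Y.thetaC)

    def test_second_order_on_conduction_mode(self):
        # against the semi-discrete exact decay, halving dt cuts the
        # time-integration error by about four
        grid = Grid(16, 16, 1.0 / 16)
        p = PhysicalParams(kB=0.0, kappa_CC=1.0, C_C=1.0, kappa_CI=0.0,
                           kappa_0=0.0, kappa_PI=1.0, C_P=1.0, C_I=1.0)
        model = make_model(grid, p, include_q=False, theta_bath=None)
        x = grid.xc
        lam_h = (p.kappa_CC / p.C_C) * (2 / grid.dx**2) * (1 - np.cos(2 * np.pi * grid.dx / grid.Lx))
        T = 0.002
        errs = []
        for dt in (2e-4, 1e-4):
            Y = SystemState(X=np.zeros(2), q=None, thetaP=np.array(3.0), thetaI=np.array(3.0),
                            thetaC=3.0 + 0.5 * np.tile(np.sin(2 * np.pi * x / grid.Lx), (16, 1)))
            for _ in range(int(round(T / dt))):
                Y = step(Y, dt, model, None, noise=False)
            exact = 3.0 + 0.5 * np.exp(-lam_h * T) * np.tile(np.sin(2 * np.pi * x / grid.Lx), (16, 1))
            errs.append(np.max(np.abs(Y.thetaC - exact)))
        assert errs[0] / errs[1] == pytest.approx(4.0, rel=0.25)

    def test_constant_amplitude_noise_reduces_to_euler_maruyama(self):
        # frozen temperature: predictor and corrector noise coincide
        rng = substream(7)
        X0 = np.zeros((1000, 2))
        pot = ZeroPotential()
        X1 = simulate_particle(X0, pot, gamma_p=2.0, kB=1e-3, thetaP=3.0,
                               dt=1e-3, n_steps=1, rng=rng)
        rng2 = substream(7)
        dW = rng2.standard_normal((1000, 2)) * np.sqrt(1e-3)
        X_em = X0 + np.sqrt(2 * 1e-3 * 3.0 / 2.0) * dW
        assert np.allclose(X1, X_em, atol=1e-15)

    def test_mass_conserved_to_machine_precision_with_noise(self, grid20):
        p = preset_params("table1")
        pot = KernelCoupling(KernelSpec(k1=1.1, sigma0=0.2))
        model = make_model(grid20, p, pot=pot, include_q=True, theta_bath=p.theta0)
        Y = SystemState(X=np.array([0.0, 0.0]),
                        q=gaussian_blob(grid20, (1.5, 1.5), 0.2),
                        thetaP=np.array(p.theta0), thetaI=np.array(p.theta0),
                        thetaC=np.full(grid20.shape, p.theta0))
        mass0 = np.sum(Y.q) * grid20.cell_volume
        rng = substream(11)
        for _ in range(1000):
            Y = step(Y, 1e-3, model, rng)
        assert np.sum(Y.q) * grid20.cell_volume == pytest.approx(mass0, abs=1e-12)

    def test_stratonovich_mean_displacement_with_varying_mobility(self):
        # With a position-dependent scalar mobility the shared-increment Heun
        # scheme is a Stratonovich integrator: its one-step mean displacement
        # carries the spurious drift (1/2) b b' = (1/2) kB theta dm/dx, i.e.
        # it statistically matches an Ito-Euler reference that adds that
        # drift explicitly.  (The studies all use a constant mobility, where
        # the term vanishes identically.)
        kB, theta, dt, n = 1e-2, 2.0, 1e-1, 400_000
        x0 = 0.3

        def mobility(X):
            return 1.0 + 0.5 * np.sin(X[..., 0])

        rng = substream(21)
        X = np.full((n, 2), [x0, 0.0])
        X1 = simulate_particle(X, ZeroPotential(), gamma_p=1.0, kB=kB, thetaP=theta,
                               dt=dt, n_steps=1, rng=rng, mobility=mobility)
        mean_dx = np.mean(X1[:, 0] - x0)
        expected = 0.5 * kB * theta * 0.5 * np.cos(x0) * dt  # (1/2) kB theta m'
        se = np.std(X1[:, 0] - x0) / np.sqrt(n)
        assert abs(mean_dx - expected) < 4 * se
        assert abs(expected) > 4 * se  # the drift itself is resolved
        # Ito-Euler reference with the explicit Stratonovich drift
        rng2 = substream(22)
        dW = rng2.standard_normal((n, 2)) * np.sqrt(dt)
        m0 = mobility(X)
        b0 = np.sqrt(2 * kB * theta * m0)
        drift = 0.5 * kB * theta * 0.5 * np.cos(X[:, 0])
        X_ito = X[:, 0] + drift * dt + b0 * dW[:, 0]
        assert np.mean(X_ito - x0) == pytest.approx(mean_dx, abs=4 * se * np.sqrt(2))

    def test_trajectories_reproducible_from_seed(self, grid20):
        p = preset_params("table1")
        pot = KernelCoupling(KernelSpec(k1=1.1, sigma0=0.2))
        model = make_model(grid20, p, pot=pot, include_q=True, theta_bath=p.theta0)

        def run():
            Y = SystemState(X=np.array([0.0, 0.0]),
                            q=gaussian_blob(grid20, (1.5, 1.5), 0.2),
                            thetaP=np.array(p.theta0), thetaI=np.array(p.theta0),
                            thetaC=np.full(grid20.shape, p.theta0))
            rng = substream(123, 0)
            for _ in range(50):
                Y = step(Y, 1e-3, model, rng)
            return Y

        Ya, Yb = run(), run()
        assert np.array_equal(Ya.X, Yb.X)
        assert np.array_equal(Ya.q, Yb.q)
        assert np.array_equal(Ya.thetaC, Yb.thetaC)

    def test_unresolvable_stiffness_raises_after_halvings(self, grid20):
        # ambient relaxation far beyond any stable dt: rejection path ends
        # in a hard error instead of looping forever
        p = PhysicalParams(kB=0.0, kappa_0=1.0e6, C_C=1.0, kappa_CI=0.0,
                           kappa_CC=1e-6, kappa_PI=1.0, C_P=1.0, C_I=1.0)
        model = make_model(grid20, p, include_q=False, theta_bath=0.01)
        Y = SystemState(X=np.zeros(2), q=None, thetaP=np.array(3.0),
                        thetaI=np.array(3.0), thetaC=np.full(grid20.shape, 3.0))
        with pytest.raises(StepRejectionError):
            step(Y, 1.0, model, None, noise=False)


def test_state_vector_layout_roundtrip():
    model = tiny_model()
    Y = tiny_state(model)
    v = state_to_vector(Y, model)
    N = model.grid.n_cells
    assert v.shape == (2 + N + 1 + 1 + N,)
    assert np.array_equal(v[:2], Y.X)
    assert v[2 + N] == float(Y.thetaP)
    assert np.array_equal(v[-N:], Y.thetaC.ravel())
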