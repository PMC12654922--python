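"""Energy/entropy functionals, their gradients, and the protein force."""

import numpy as np
import pytest

from memselm.dynamics import Model, step
from memselm.energetics import (
    HarmonicWell,
    KernelCoupling,
    SystemState,
    WellLattice,
    ZeroPotential,
    energy_gradient,
    entropy_gradient,
    protein_force,
    total_energy,
    total_entropy,
)
from memselm.grid import Grid, KernelSpec, kernel_eval, minimum_image
from memselm.params import PhysicalParams, preset_params
from memselm.scenarios import gaussian_blob


@pytest.fixture
def grid20():
    return Grid(20, 20, 0.1)


def uniform_state(grid, theta=3.0, q=None):
    return SystemState(
        X=np.array([1.0, 1.0]),
        q=q,
        thetaP=np.array(theta),
        thetaI=np.array(theta),
        thetaC=np.full(grid.shape, theta),
    )


class TestTotalEnergy:
    def test_uniform_closed_form_with_study_constants(self, grid20):
        # Psi = Phi = 0, all temperatures at 3.0:
        # E = theta * (C_P + C_I + C_C * |Omega|) = 3 * (1.2 + 140 + 130*4)
        p = preset_params("table1")
        Y = uniform_state(grid20, theta=3.0, q=np.ones(grid20.shape))
        E = total_energy(Y, p, ZeroPotential(), grid20)
        assert E == pytest.approx(3.0 * (1.2 + 140.0 + 130.0 * 400 * 0.01))
        assert E == pytest.approx(1983.6)

    def test_linear_in_temperatures(self, grid20):
        p = PhysicalParams()
        Y = uniform_state(grid20, theta=2.0)
        Y2 = uniform_state(grid20, theta=4.0)
        assert total_energy(Y2, p, ZeroPotential(), grid20) == pytest.approx(
            2.0 * total_energy(Y, p, ZeroPotential(), grid20)
        )

    def test_interaction_term_enters_with_concentration(self, grid20):
        p = preset_params("table1")
        pot = KernelCoupling(KernelSpec(k1=1.1, sigma0=0.2))
        q = gaussian_blob(grid20, (1.0, 1.0), 0.2)
        Y = uniform_state(grid20, q=q)
        E = total_energy(Y, p, pot, grid20)
        E0 = total_energy(uniform_state(grid20, q=q), p, ZeroPotential(), grid20)
        # attractive coupling on an overlapping blob lowers the energy
        assert E < E0


class TestTotalEntropy:
    def test_uniform_q_contributes_nothing(self, grid20):
        p = PhysicalParams()
        S1 = total_entropy(uniform_state(grid20, q=np.ones(grid20.shape)), p, grid20)
        S0 = total_entropy(uniform_state(grid20, q=None), p, grid20)
        assert S1 == pytest.approx(S0)

    def test_uniform_closed_form(self, grid20):
        p = PhysicalParams()
        S = total_entropy(uniform_state(grid20, q=np.ones(grid20.shape)), p, grid20)
        area = grid20.Lx * grid20.Ly
        assert S == pytest.approx((p.C_P + p.C_I + p.C_C * area) * np.log(3.0))

    def test_rejects_nonpositive_temperature(self, grid20):
        p = PhysicalParams()
        Y = uniform_state(grid20)
        Y.thetaC[0, 0] = -1.0
        with pytest.raises(ValueError):
            total_entropy(Y, p, grid20)

    def test_uniform_distribution_maximizes_mixing_entropy(self, grid20):
        # among fields with the same total mass, -sum q ln q peaks at uniform
        p = PhysicalParams()
        rng = np.random.default_rng(4)
        S_uniform = total_entropy(uniform_state(grid20, q=np.ones(grid20.shape)), p, grid20)
        for _ in range(5):
            pert = rng.normal(size=grid20.shape)
            pert -= pert.mean()  # mass preserved
            q = 1.0 + 0.5 * pert / np.max(np.abs(pert))
            S = total_entropy(uniform_state(grid20, q=q), p, grid20)
            assert S < S_uniform


class TestGradients:
    def test_entropy_gradient_blocks(self, grid20):
        p = preset_params("table1")
        Y = uniform_state(grid20, theta=3.0, q=np.ones(grid20.shape))
        g = entropy_gradient(Y, p)
        assert np.allclose(g.q, -p.c0)
        assert g.thetaP == pytest.approx(1.2 / 3.0)  # C_P/thetaP = 0.4
        assert np.all(g.X == 0.0)

    def test_entropy_gradient_matches_finite_differences(self, grid20):
        p = PhysicalParams()
        rng = np.random.default_rng(5)
        q = 1.0 + 0.3 * rng.uniform(size=grid20.shape)
        Y = SystemState(
            X=np.array([0.8, 1.2]),
            q=q,
            thetaP=np.array(2.7),
            thetaI=np.array(3.1),
            thetaC=3.0 + 0.2 * rng.uniform(size=grid20.shape),
        )
        g = entropy_gradient(Y, p)
        h = 1e-6
        Yp, Ym = Y.copy(), Y.copy()
        Yp.thetaP = Y.thetaP + h
        Ym.thetaP = Y.thetaP - h
        fd = (total_entropy(Yp, p, grid20) - total_entropy(Ym, p, grid20)) / (2 * h)
        assert fd == pytest.approx(g.thetaP, rel=1e-5)
        # field blocks carry the cell-volume factor in the discrete sum
        for (j, i) in [(3, 3), (10, 15)]:
            Yp, Ym = Y.copy(), Y.copy()
            Yp.q[j, i] += h
            Ym.q[j, i] -= h
            fd = (total_entropy(Yp, p, grid20) - total_entropy(Ym, p, grid20)) / (2 * h)
            assert fd == pytest.approx(g.q[j, i] * grid20.cell_volume, rel=1e-4)

    def test_energy_gradient_blocks(self, grid20):
        p = PhysicalParams()
        pot = HarmonicWell(2.0, center=(0.5, 0.5))
        Y = uniform_state(grid20)
        g = energy_gradient(Y, p, pot, grid20)
        assert np.allclose(g.X, 2.0 * (Y.X - 0.5))
        assert g.thetaP == pytest.approx(p.C_P)
        assert g.thetaI == pytest.approx(p.C_I)
        assert np.allclose(g.thetaC, p.C_C)

    def test_energy_gradient_X_matches_finite_differences(self, grid20):
        p = preset_params("table1")
        pot = KernelCoupling(KernelSpec(k1=1.1, sigma0=0.2))
        q = gaussian_blob(grid20, (1.3, 1.1), 0.25)
        Y = uniform_state(grid20, q=q)
        g = energy_gradient(Y, p, pot, grid20)
        h = 1e-6
        for d in (0, 1):
            Yp, Ym = Y.copy(), Y.copy()
            Yp.X = Y.X.copy()
            Ym.X = Y.X.copy()
            Yp.X[d] += h
            Ym.X[d] -= h
            fd = (total_energy(Yp, p, pot, grid20) - total_energy(Ym, p, pot, grid20)) / (2 * h)
            assert fd == pytest.approx(g.X[d], rel=1e-5, abs=1e-10)


class TestProteinForce:
    def test_zero_at_well_center(self, grid20):
        pot = WellLattice(1.5e-4, 0.2, np.array([[1.0, 1.0]]), grid20.Lx, grid20.Ly)
        Y = uniform_state(grid20)
        F = protein_force(Y, PhysicalParams(), pot, grid20)
        assert np.allclose(F, 0.0, atol=1e-15)

    def test_well_lattice_force_matches_analytic_form(self, grid20):
        # F = -c2 (X - X_i)/sigma0^2 exp(-|X-X_i|^2 / 2 sigma0^2)
        c2, s0 = 1.5e-4, 0.2
        pot = WellLattice(c2, s0, np.array([[1.0, 1.0]]), grid20.Lx, grid20.Ly)
        X = np.array([1.15, 0.9])
        d = X - np.array([1.0, 1.0])
        expected = -c2 * d / s0**2 * np.exp(-np.sum(d * d) / (2 * s0**2))
        Y = uniform_state(grid20)
        Y.X = X
        F = protein_force(Y, PhysicalParams(), pot, grid20)
        assert np.allclose(F, expected, rtol=1e-12)

    def test_uniform_concentration_gives_no_net_force(self, grid20):
        p = preset_params("table1")
        pot = KernelCoupling(KernelSpec(k1=1.1, sigma0=0.2))
        Y = uniform_state(grid20, q=np.ones(grid20.shape))
        F = protein_force(Y, p, pot, grid20)
        assert np.allclose(F, 0.0, atol=1e-10)

    def test_displaced_blob_attracts_protein(self, grid20):
        # blob displaced along +x pulls the protein toward it; magnitude
        # cross-checked against direct quadrature of grad_X eta * c0 q
        p = preset_params("table1")
        kern = KernelSpec(k1=1.1, sigma0=0.2)
        pot = KernelCoupling(kern, attractive=True)
        q = gaussian_blob(grid20, (1.4, 1.0), 0.2)
        Y = uniform_state(grid20, q=q)
        Y.X = np.array([1.0, 1.0])
        F = protein_force(Y, p, pot, grid20)
        assert F[0] > 0  # toward the higher concentration
        gx, gy = grid20.meshgrid()
        quad = np.zeros(2)
        h = 1e-6
        for d, delta in ((0, np.array([h, 0.0])), (1, np.array([0.0, h]))):
            def V(Xp):
                dx = minimum_image(gx - Xp[0], grid20.Lx)
                dy = minimum_image(gy - Xp[1], grid20.Ly)
                w = kernel_eval(kern, np.stack([dx, dy], axis=-1))
                return -np.sum(w * q) * p.c0 * grid20.cell_volume
            quad[d] = -(V(Y.X + delta) - V(Y.X - delta)) / (2 * h)
        assert np.allclose(F, quad, rtol=1e-4)


def test_entropy_nondecreasing_in_closed_deterministic_relaxation():
    """A closed system relaxing toward equilibrium must produce entropy."""
    grid = Grid(20, 20, 0.1)
    p = PhysicalParams(
        kB=0.0, c0=2.1, kappa_bar=1.2e-3, gamma_p=13.0, kappa_PI=5.7e2,
        kappa_CI=3.0e3, kappa_CC=1.3e2, kappa_0=0.0, C_P=1.2, C_C=1.3e2,
        C_I=1.4e2, theta0=3.0,
    )
    pot = KernelCoupling(KernelSpec(k1=1.1, sigma0=0.2))
    model = Model(grid=grid, params=p, potential=pot,
                  coupling=KernelSpec(k1=1.0, sigma0=0.2), include_q=True, theta_bath=None)
    Y = SystemState(
        X=np.array([1.0, 1.0]),
        q=gaussian_blob(grid, (1.5, 1.5), 0.2),
        thetaP=np.array(3.5),
        thetaI=np.array(2.5),
        thetaC=np.full(grid.shape, 3.0),
    )
    S_prev = float(total_entropy(Y, p, grid))
    for _ in range(500):
        Y = step(Y, 2e-4, model, None, noise=False)
        S = float(total_entropy(Y, p, grid))
        assert S >= S_prev - 1e-9 * abs(S_prev)
        S_prev = S
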