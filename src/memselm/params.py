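"""Physical parameters of the membrane-protein model and the study presets.

All quantities are non-dimensional; the reference scales for converting back
to laboratory units (10 nm, 50 kDa, 1 us, kB*T = 4.1e-21 J) live in
:mod:`memselm.config`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace, asdict

__all__ = ["PhysicalParams", "PRESETS", "preset_params"]


@dataclass(frozen=True)
class PhysicalParams:
    """Rate, capacity and coupling constants of the coupled model.

    Attributes
    ----------
    kB:
        Boltzmann constant (energy/temperature) in simulation units; sets the
        fluctuation magnitude everywhere (kB = 0 switches noise off exactly).
    c0:
        Total concentration of the signaling species; the physical
        concentration is c = c0*q with q the dimensionless distribution.
    kappa_bar:
        Concentration diffusivity.  The Stokes-Einstein relation
        kappa_bar = thetaC/gamma defines the molecular drag gamma at the
        baseline temperature: gamma = theta0/kappa_bar.
    gamma_p:
        Particle (protein) translational drag; mobility M_XX = I/gamma_p.
    kappa_PI, kappa_CI, kappa_CC, kappa_0:
        Thermal conductivities: protein-interface, interface-membrane (kernel
        weighted around the particle), membrane-membrane (conduction), and
        membrane-ambient bath.  kappa_CI and kappa_0 may be zero.
    C_P, C_C, C_I:
        Specific heats of the protein (scalar), membrane field (per volume),
        and interfacial region (scalar).
    theta0:
        Baseline temperature.
    """

    kB: float = 1.0e-5
    c0: float = 2.1
    kappa_bar: float = 1.2e-3
    gamma_p: float = 13.0
    kappa_PI: float = 8.2e6
    kappa_CI: float = 3.0e3
    kappa_CC: float = 1.3e2
    kappa_0: float = 2.1e-3
    C_P: float = 1.2
    C_C: float = 1.3e2
    C_I: float = 1.4e2
    theta0: float = 3.0

    def __post_init__(self) -> None:
        for name in ("kappa_bar", "gamma_p", "kappa_PI", "kappa_CC", "C_P", "C_C", "C_I", "theta0"):
            if not (getattr(self, name) > 0):
                raise ValueError(f"{name} must be strictly positive")
        for name in ("kappa_CI", "kappa_0", "kB", "c0"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")

    @property
    def gamma(self) -> float:
        """Molecular drag of the signaling species, gamma = theta0/kappa_bar."""
        return self.theta0 / self.kappa_bar

    def replace(self, **kw) -> "PhysicalParams":
        return replace(self, **kw)

    def to_dict(self) -> dict:
        return asdict(self)


# Study presets.  Each entry carries the physical constants plus the grid and
# time-step printed alongside them; scenario-specific quantities (initial
# conditions, kernels, sweeps) live in memselm.scenarios.
PRESETS: dict[str, dict] = {
    # Concentration-positioning study.
    "table1": dict(
        params=PhysicalParams(
            kB=1.0e-5,
            c0=2.1,
            kappa_bar=1.2e-3,
            gamma_p=1.3e1,
            kappa_PI=8.2e6,
            kappa_CI=3.0e3,
            kappa_CC=1.3e2,
            kappa_0=2.1e-3,
            C_P=1.2,
            C_C=1.3e2,
            C_I=1.4e2,
            theta0=3.0,
        ),
        nx=20,
        ny=20,
        dx=0.1,
        dt=1.0e-3,
    ),
    # Thermal-sensing study.  kappa_CI = 0 decouples the interface; the
    # concentration field is inactive but c0/kappa_bar keep the table-1
    # defaults so the parameter set is complete.
    "table2": dict(
        params=PhysicalParams(
            kB=1.0e-3,
            c0=2.1,
            kappa_bar=1.2e-3,
            gamma_p=1.3e1,
            kappa_PI=8.2e6,
            kappa_CI=0.0,
            kappa_CC=8.2e4,
            kappa_0=8.2e4,
            C_P=1.0,
            C_C=4.0e1,
            C_I=1.4e2,
            theta0=3.0,
        ),
        nx=20,
        ny=20,
        dx=0.1,
        dt=1.0e-5,
    ),
    # Hot-Brownian-escape study.  No concentration field; includes the well
    # strength c2 and well/heating geometry used by the scenario.
    "table3": dict(
        params=PhysicalParams(
            kB=1.0e-5,
            c0=2.1,
            kappa_bar=1.2e-3,
            gamma_p=1.0e-1,
            kappa_PI=5.7e2,
            kappa_CI=3.0e3,
            kappa_CC=2.1e-3,
            kappa_0=8.2e6,
            C_P=9.3e2,
            C_C=1.3e4,
            C_I=1.4e2,
            theta0=3.0,
        ),
        nx=20,
        ny=20,
        dx=0.1,
        dt=3.0e-3,
        c2=1.5e-4,
        X0=(5.0 / 3.0, 1.0),
    ),
}


def preset_params(name: str) -> PhysicalParams:
    """Physical constants of a named study preset (table1/table2/table3)."""
    try:
        return PRESETS[name]["params"]
    except KeyError:
        raise KeyError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}") from None
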