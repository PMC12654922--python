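"""Configuration documents, presets, unit conversion, and result output.

Configs are YAML (or plain dicts) with the sections
``grid / params / potential / integrator / scenario / output``; unknown keys
are rejected so typos fail loudly.  Naming a preset (table1/table2/table3)
fills every physical field with the study defaults; explicit keys override.
A config echo is written alongside every run output.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict
from typing import Any, Optional

import numpy as np
import yaml

from .grid import Grid, KernelSpec
from .params import PRESETS, PhysicalParams

__all__ = [
    "ConfigDocument",
    "load_config",
    "load_preset",
    "ReferenceScales",
    "nondimensional_report",
    "write_run_outputs",
]

_SECTIONS = ("preset", "grid", "params", "potential", "integrator", "scenario", "output")
_GRID_KEYS = {"nx", "ny", "dx", "kernel_kind", "sigma0", "k1", "r_cut"}
_INTEGRATOR_KEYS = {"dt", "n_steps", "seed", "noise", "ambient"}
_POTENTIAL_KEYS = {"kind", "k", "center", "k1", "sigma0", "attractive", "c2", "lattice_spacing"}
_SCENARIO_KEYS = {
    "kind",
    "kappa_bar_values",
    "gamma_p_values",
    "a0_values",
    "c2_values",
    "c3_values",
    "replicates",
    "T_end",
    "T_max",
    "r0",
    "sigma3",
    "seed",
}
_OUTPUT_KEYS = {"dir", "hdf5", "csv", "stride"}


@dataclass
class ConfigDocument:
    """Validated, preset-expanded configuration."""

    params: PhysicalParams
    grid: Grid
    kernel: KernelSpec
    dt: float
    sections: dict = field(default_factory=dict)
    preset: Optional[str] = None

    def to_dict(self) -> dict:
        d = {
            "preset": self.preset,
            "params": self.params.to_dict(),
            "grid": {
                "nx": self.grid.nx,
                "ny": self.grid.ny,
                "dx": self.grid.dx,
                "kernel_kind": self.kernel.kind,
                "k1": self.kernel.k1,
                "sigma0": self.kernel.sigma0,
                "r_cut": self.kernel.r_cut,
            },
            "integrator": {"dt": self.dt, **self.sections.get("integrator", {})},
        }
        for key in ("potential", "scenario", "output"):
            if key in self.sections:
                d[key] = self.sections[key]
        return d

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)


def _reject_unknown(section: dict, allowed: set, name: str) -> None:
    unknown = set(section) - allowed
    if unknown:
        raise ValueError(f"unknown keys in {name!r} section: {sorted(unknown)}")


def load_preset(name: str) -> ConfigDocument:
    """Full parameter set of a named study table."""
    if name not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    entry = PRESETS[name]
    grid = Grid(entry["nx"], entry["ny"], entry["dx"])
    kernel = KernelSpec(kind="gaussian", k1=1.1 if name == "table1" else 1.0, sigma0=0.2)
    return ConfigDocument(params=entry["params"], grid=grid, kernel=kernel, dt=entry["dt"], preset=name)


def load_config(source: Any) -> ConfigDocument:
    """Load and validate a config from a YAML path, YAML string, or dict."""
    if isinstance(source, dict):
        doc = dict(source)
    else:
        text = source
        if isinstance(source, (str, os.PathLike)) and os.path.exists(source):
            with open(source) as fh:
                text = fh.read()
        doc = yaml.safe_load(text)
        if not isinstance(doc, dict):
            raise ValueError("config must be a mapping")
    _reject_unknown(doc, set(_SECTIONS), "top-level")

    preset = doc.get("preset")
    if preset is not None:
        base = load_preset(preset)
        params, grid, kernel, dt = base.params, base.grid, base.kernel, base.dt
    else:
        params, grid, kernel, dt = PhysicalParams(), Grid(20, 20, 0.1), KernelSpec(), 1.0e-3

    psec = doc.get("params", {})
    _reject_unknown(psec, set(PhysicalParams().to_dict()), "params")
    if psec:
        params = params.replace(**psec)

    gsec = doc.get("grid", {})
    _reject_unknown(gsec, _GRID_KEYS, "grid")
    if {"nx", "ny", "dx"} & set(gsec):
        grid = Grid(gsec.get("nx", grid.nx), gsec.get("ny", grid.ny), gsec.get("dx", grid.dx))
    kern_kw = {}
    if "kernel_kind" in gsec:
        kern_kw["kind"] = gsec["kernel_kind"]
    for k_src, k_dst in (("sigma0", "sigma0"), ("k1", "k1"), ("r_cut", "r_cut")):
        if k_src in gsec:
            kern_kw[k_dst] = gsec[k_src]
    if kern_kw:
        kernel = KernelSpec(
            kind=kern_kw.get("kind", kernel.kind),
            k1=kern_kw.get("k1", kernel.k1),
            sigma0=kern_kw.get("sigma0", kernel.sigma0),
            r_cut=kern_kw.get("r_cut", None),
        )

    isec = doc.get("integrator", {})
    _reject_unknown(isec, _INTEGRATOR_KEYS, "integrator")
    dt = isec.get("dt", dt)
    if not (dt > 0):
        raise ValueError("integrator dt must be positive")

    sections = {}
    for name, allowed in (("potential", _POTENTIAL_KEYS), ("scenario", _SCENARIO_KEYS), ("output", _OUTPUT_KEYS)):
        if name in doc:
            _reject_unknown(doc[name], allowed, name)
            sections[name] = dict(doc[name])
    if isec:
        sections["integrator"] = {k: v for k, v in isec.items() if k != "dt"}

    return ConfigDocument(params=params, grid=grid, kernel=kernel, dt=dt, sections=sections, preset=preset)


# ---------------------------------------------------------------------------
# unit conversion


@dataclass(frozen=True)
class ReferenceScales:
    """Characteristic scales for converting non-dimensional results.

    Defaults: length 10 nm, mass 50 kDa, time 1 us, thermal energy
    kB*T = 4.1e-21 J.  A non-dimensional quantity z maps to the dimensional
    z~ = z * Zbar.
    """

    length_nm: float = 10.0
    mass_kDa: float = 50.0
    time_us: float = 1.0
    energy_J: float = 4.1e-21

    def __post_init__(self) -> None:
        for name in ("length_nm", "mass_kDa", "time_us", "energy_J"):
            if not (getattr(self, name) > 0):
                raise ValueError(f"reference scale {name} must be positive")

    def scale(self, kind: str) -> tuple[float, str]:
        table = {
            "length": (self.length_nm, "nm"),
            "mass": (self.mass_kDa, "kDa"),
            "time": (self.time_us, "us"),
            "energy": (self.energy_J, "J"),
            "diffusivity": (self.length_nm**2 / self.time_us, "nm^2/us"),
            "velocity": (self.length_nm / self.time_us, "nm/us"),
            "force": (self.energy_J / (self.length_nm * 1e-9), "N"),
        }
        if kind not in table:
            raise KeyError(f"no reference scale for quantity kind {kind!r}")
        return table[kind]

    def dimensional(self, value: float, kind: str) -> tuple[float, str]:
        s, unit = self.scale(kind)
        return value * s, unit

    def nondimensional(self, value: float, kind: str) -> float:
        s, _ = self.scale(kind)
        return value / s


def nondimensional_report(quantities: dict, scales: ReferenceScales | None = None):
    """Tabulate dimensional equivalents of non-dimensional quantities.

    ``quantities`` maps name -> (value, kind); returns a DataFrame with the
    dimensional value and unit per row.
    """
    import pandas as pd

    scales = scales or ReferenceScales()
    rows = []
    for name, (value, kind) in quantities.items():
        dim, unit = scales.dimensional(value, kind)
        rows.append(dict(name=name, value=value, kind=kind, dimensional=dim, unit=unit))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# run outputs


def write_run_outputs(
    outdir: str,
    *,
    config_echo: dict,
    seed: int,
    tables: dict | None = None,
    trajectories: dict | None = None,
    log_lines: list | None = None,
) -> None:
    """Write the standard run directory: config echo, seed, CSVs, HDF5, log."""
    os.makedirs(outdir, exist_ok=True)
    with open(os.path.join(outdir, "config_echo.yaml"), "w") as fh:
        yaml.safe_dump({"seed": int(seed), **config_echo}, fh, sort_keys=True)
    if tables:
        for name, df in tables.items():
            df.to_csv(os.path.join(outdir, f"{name}.csv"), index=False)
    if trajectories:
        import h5py

        with h5py.File(os.path.join(outdir, "trajectories.h5"), "w") as h5:
            h5.attrs["config"] = json.dumps(config_echo, default=str)
            h5.attrs["seed"] = int(seed)
            for name, arr in trajectories.items():
                h5.create_dataset(name, data=np.asarray(arr))
    if log_lines:
        with open(os.path.join(outdir, "run.log"), "w") as fh:
            fh.write("\n".join(str(line) for line in log_lines) + "\n")
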