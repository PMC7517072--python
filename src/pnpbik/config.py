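"""Scenario configuration files (YAML) and tabular output.

A scenario config has up to five blocks::

    composition:
      temperature_K: 298.15
      steric_mode: volume          # or "uniform"
      species:                     # water last, z = 0
        - {name: "C+", z: 1, radius_A: 4.65, conc_M: 0.4}
        - {name: "A4-", z: -4, radius_A: 4.65, conc_M: 0.1}
        - {name: "H2O", z: 0, radius_A: 1.4, conc_M: 55.5}
    domain:
      L_A: 40.0
      n: 801
      sigma_e_A2: 0.02
      eps_s: 80.0
      lc_A: 7.44
      far_potential: 0.0
    solver:
      tol: 1.0e-6
      omega_4pbik: 0.5
      lambda_s_steps: 10
    transport:
      voltage_kbt_e: 2.0
      diffusion_A2: {"C+": 1.0, "A4-": 1.0, "H2O": 1.0}
      theta: 1.0
    site:
      center_A: [0, 0, 0]
      a_site_A: 0.95
      q_site_e: 1.0
      V_site_A3: 14.77
      eps_b: 3.6

Unknown keys are rejected so typos fail loudly.  Physical quantities carry
their unit in the key name.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .composition import ElectrolyteComposition, make_composition
from .errors import ValidationError
from .fourpbik import DomainSpec, SolverConfig
from .sites import BindingSite
from .state import FieldState
from .transport import TransportSpec

__all__ = [
    "load_scenario",
    "composition_from_config",
    "domain_from_config",
    "solver_from_config",
    "transport_from_config",
    "site_from_config",
    "write_profile_tsv",
]

_TOP_KEYS = {"composition", "domain", "solver", "transport", "site"}
_BLOCK_KEYS = {
    "composition": {"temperature_K", "steric_mode", "species"},
    "species": {"name", "z", "radius_A", "conc_M"},
    "domain": {"L_A", "n", "sigma_e_A2", "eps_s", "lc_A", "far_potential",
               "left_dirichlet"},
    "solver": {"tol", "omega_4pbik", "omega_pnpb", "lambda_s_steps",
               "lambda_c_steps", "delta_v", "max_iter"},
    "transport": {"voltage_kbt_e", "diffusion_A2", "theta", "pore_region_A",
                  "left_conc_M", "right_conc_M"},
    "site": {"center_A", "a_site_A", "q_site_e", "V_site_A3", "eps_b", "name"},
}


def _check_keys(block: dict, allowed_name: str) -> None:
    unknown = set(block) - _BLOCK_KEYS[allowed_name]
    if unknown:
        raise ValidationError(
            f"unknown key(s) in {allowed_name!r} block: {sorted(unknown)}"
        )


def load_scenario(path: str | Path) -> dict:
    """Load and structurally validate a scenario YAML file."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValidationError("scenario file must contain a mapping")
    unknown = set(cfg) - _TOP_KEYS
    if unknown:
        raise ValidationError(f"unknown top-level block(s): {sorted(unknown)}")
    for name in cfg:
        if name == "composition":
            _check_keys(cfg[name], "composition")
            for row in cfg[name].get("species", []):
                _check_keys(row, "species")
        else:
            _check_keys(cfg[name], name)
    return cfg


def composition_from_config(cfg: dict) -> ElectrolyteComposition:
    block = cfg.get("composition")
    if not block or "species" not in block:
        raise ValidationError("scenario needs a composition block with species")
    return make_composition(
        [(r["name"], r["z"], r["radius_A"], r["conc_M"]) for r in block["species"]],
        T=block.get("temperature_K", 298.15),
        steric_mode=block.get("steric_mode", "volume"),
    )


def domain_from_config(cfg: dict) -> DomainSpec:
    b = cfg.get("domain", {})
    return DomainSpec(
        L=float(b.get("L_A", 40.0)),
        sigma=float(b.get("sigma_e_A2", 0.0)),
        eps_s=float(b.get("eps_s", 78.45)),
        lc=float(b.get("lc_A", 0.0)),
        far_potential=float(b.get("far_potential", 0.0)),
        left_dirichlet=(None if b.get("left_dirichlet") is None
                        else float(b["left_dirichlet"])),
        n=int(b.get("n", 801)),
    )


def solver_from_config(cfg: dict) -> SolverConfig:
    b = dict(cfg.get("solver", {}))
    return SolverConfig(**b)


def transport_from_config(cfg: dict) -> TransportSpec:
    b = cfg.get("transport")
    if not b or "diffusion_A2" not in b:
        raise ValidationError("transport block with diffusion_A2 required")
    return TransportSpec(
        diffusion=dict(b["diffusion_A2"]),
        voltage=float(b.get("voltage_kbt_e", 0.0)),
        theta=float(b.get("theta", 1.0)),
        pore_region=(tuple(b["pore_region_A"]) if b.get("pore_region_A") else None),
        left_conc_M=dict(b.get("left_conc_M", {})),
        right_conc_M=dict(b.get("right_conc_M", {})),
    )


def site_from_config(cfg: dict) -> BindingSite:
    b = cfg.get("site")
    if not b:
        raise ValidationError("site block required")
    return BindingSite(
        center=np.asarray(b.get("center_A", [0.0, 0.0, 0.0]), dtype=float),
        a_site=float(b["a_site_A"]),
        q_site=float(b["q_site_e"]),
        V_site=float(b["V_site_A3"]),
        eps_b=float(b.get("eps_b", 3.6)),
        name=str(b.get("name", "")),
    )


def write_profile_tsv(path: str | Path, state: FieldState,
                      composition: ElectrolyteComposition,
                      extra: dict[str, np.ndarray] | None = None) -> None:
    """Tabulate a solved profile (x, phi, psi, C_i in M, Gamma, S, ...) as TSV."""
    from .constants import molar

    cols = {"x_A": state.x, "phi_kbt_e": state.phi}
    if state.psi is not None:
        cols["psi_A-2"] = state.psi
    for name, c in zip(composition.names, state.concentrations):
        cols[f"C_{name}_M"] = molar(c)
    cols["gamma"] = state.gamma
    cols["steric"] = state.steric
    for k, vcol in (extra or {}).items():
        cols[k] = vcol
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False, float_format="%.8g")
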