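"""Deterministic synthetic inputs: scenario presets, activity tables,
random charge clouds and a toy binding pocket.

Everything is generated programmatically; identical seeds give identical
outputs.  The double-layer preset encodes the 0.1 M 1:4 electrolyte study
conditions (equal 4.65 Å ions, 55.5 M water of radius 1.4 Å, correlation
length 1.6x the ion radius, one charge per 50 Å^2 on the wall, eps = 80,
40 Å domain) under the identical-steric-energy (uniform) weight convention
of the equal-sized binary electrolyte.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .gdh import HydrationSpec, activity_coefficient, binary_composition
from .sites import BindingSite, PointChargeSet

__all__ = ["FixtureSpec", "generate_fixture", "edl_1to4_scenario",
           "salt_activity_table", "random_charge_cloud", "toy_pocket"]

_GENERATORS = ("edl_1to4", "salt_table", "toy_pocket", "random_charges")


@dataclass(frozen=True)
class FixtureSpec:
    generator: str
    seed: int = 0
    size: int = 50

    def __post_init__(self):
        if self.generator not in _GENERATORS:
            raise ValidationError(
                f"unknown generator {self.generator!r}; choose from {_GENERATORS}"
            )


def edl_1to4_scenario(n: int = 801) -> dict:
    """Scenario config dict for the planar 1:4 double layer."""
    a = 4.65
    return {
        "composition": {
            "temperature_K": 298.15,
            "steric_mode": "uniform",
            "species": [
                {"name": "C+", "z": 1, "radius_A": a, "conc_M": 0.4},
                {"name": "A4-", "z": -4, "radius_A": a, "conc_M": 0.1},
                {"name": "H2O", "z": 0, "radius_A": 1.4, "conc_M": 55.5},
            ],
        },
        "domain": {
            "L_A": 40.0,
            "n": n,
            "sigma_e_A2": 1.0 / 50.0,
            "eps_s": 80.0,
            "lc_A": 1.6 * a,
            "far_potential": 0.0,
        },
        "solver": {"tol": 1.0e-6, "lambda_s_steps": 10, "lambda_c_steps": 5},
    }


def salt_activity_table(
    spec: HydrationSpec,
    salt: str | tuple,
    concentrations: np.ndarray,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """(salt, concentration_M, gamma) table from the generalized model,
    optionally with Gaussian noise of ``noise_sigma`` in ln gamma."""
    rng = np.random.default_rng(seed)
    rows = []
    salt_name = salt if isinstance(salt, str) else salt[0] + salt[3]
    for c in np.asarray(concentrations, dtype=float):
        lng = activity_coefficient(spec, binary_composition(salt, c), "generalized")
        if noise_sigma > 0:
            lng += rng.normal(0.0, noise_sigma)
        rows.append({"salt": salt_name, "concentration_M": c,
                     "gamma": float(np.exp(lng))})
    return pd.DataFrame(rows)


def random_charge_cloud(n: int = 50, seed: int = 0, box_A: float = 20.0,
                        exclude_radius_A: float = 2.0) -> PointChargeSet:
    """Uniform random partial charges in a cube, avoiding the origin region."""
    rng = np.random.default_rng(seed)
    pos = np.empty((0, 3))
    while len(pos) < n:
        cand = rng.uniform(-box_A / 2, box_A / 2, size=(2 * n, 3))
        cand = cand[np.linalg.norm(cand, axis=1) > exclude_radius_A]
        pos = np.vstack([pos, cand])[:n]
    q = rng.uniform(-1.0, 1.0, size=n)
    return PointChargeSet(pos, q, np.full(n, 1.5), source="synthetic")


def toy_pocket(seed: int = 0) -> tuple[PointChargeSet, list[BindingSite]]:
    """Synthetic 4-site binding pocket: 8 half-charged oxygens around a 5 Å
    axis with four candidate cation sites, loosely shaped like a channel
    selectivity filter."""
    rng = np.random.default_rng(seed)
    ring = []
    for zc in (-3.0, 3.0):
        for k in range(4):
            ang = np.pi / 2 * k + np.pi / 8
            ring.append((3.0 * np.cos(ang), 3.0 * np.sin(ang), zc))
    pos = np.array(ring) + rng.normal(0.0, 0.05, size=(8, 3))
    q = np.full(8, -0.5)
    charges = PointChargeSet(pos, q, np.full(8, 1.4), source="synthetic")
    aK = 1.33
    vK = 4.0 / 3.0 * np.pi * aK**3
    sites = [
        BindingSite(center=np.array([0.0, 0.0, zc]), a_site=aK, q_site=1.0,
                    V_site=1.5 * vK, eps_b=3.6, occupied=(i % 2 == 0),
                    name=f"S{i}")
        for i, zc in enumerate((-6.0, -2.0, 2.0, 6.0))
    ]
    return charges, sites


def generate_fixture(spec: FixtureSpec):
    """Dispatch on ``spec.generator``; deterministic in ``spec.seed``."""
    if spec.generator == "edl_1to4":
        return edl_1to4_scenario()
    if spec.generator == "salt_table":
        from .presets import hydration_spec

        h = hydration_spec("Cl-", "LiCl")
        concs = np.linspace(0.1, 1.6, spec.size if spec.size >= 3 else 8)
        return salt_activity_table(h, "LiCl", concs, seed=spec.seed)
    if spec.generator == "random_charges":
        return random_charge_cloud(n=spec.size, seed=spec.seed)
    if spec.generator == "toy_pocket":
        return toy_pocket(seed=spec.seed)
    raise ValidationError(f"unknown generator {spec.generator!r}")
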