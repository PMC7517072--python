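"""Reference parameter sets for the generalized Debye–Hückel activity model.

Pauling radii and experimental Born radii (Å) for the common alkali-halide
ions, the fitted Born-scaling parameters (alpha1, alpha2, alpha3) for eight
1:1 salts, and the salt stoichiometries.  These are the published inputs of
the activity model, collected here so analyses are reproducible from the
package alone.
"""

from __future__ import annotations

from .gdh import HydrationSpec

#: Pauling (crystal) radii in Å
PAULING_RADII_A: dict[str, float] = {
    "Li+": 0.60,
    "Na+": 0.95,
    "K+": 1.33,
    "F-": 1.36,
    "Cl-": 1.81,
    "Br-": 1.95,
    "H2O": 1.4,
}

#: experimental Born radii R_i^0 in Å (from hydration free energies)
BORN_RADII_A: dict[str, float] = {
    "Li+": 1.3,
    "Na+": 1.618,
    "K+": 1.95,
    "F-": 1.6,
    "Cl-": 2.266,
    "Br-": 2.47,
}

ION_VALENCE: dict[str, int] = {
    "Li+": 1, "Na+": 1, "K+": 1, "F-": -1, "Cl-": -1, "Br-": -1,
}

#: fitted Born-scaling parameters alpha1..3 per (salt, ion)
ALPHA_TABLE: dict[str, dict[str, tuple[float, float, float]]] = {
    "LiCl": {"Li+": (-0.006, -0.037, 0.004), "Cl-": (0.052, -0.015, 0.0)},
    "LiBr": {"Li+": (-0.006, -0.011, -0.004), "Br-": (0.026, -0.057, 0.010)},
    "NaF": {"Na+": (0.0, 0.0, 0.0), "F-": (0.027, 0.0, 0.0)},
    "NaCl": {"Na+": (-0.045, 0.009, -0.002), "Cl-": (0.063, -0.014, -0.002)},
    "NaBr": {"Na+": (-0.049, 0.042, -0.013), "Br-": (0.071, -0.048, 0.006)},
    "KF": {"K+": (0.005, 0.051, -0.015), "F-": (0.033, -0.028, 0.003)},
    "KCl": {"K+": (0.031, 0.022, -0.005), "Cl-": (0.020, -0.025, 0.004)},
    "KBr": {"K+": (0.025, -0.062, 0.018), "Br-": (0.001, 0.082, 0.0)},
}

#: (cation, anion) of each supported salt
SALT_IONS: dict[str, tuple[str, str]] = {
    "LiCl": ("Li+", "Cl-"), "LiBr": ("Li+", "Br-"),
    "NaF": ("Na+", "F-"), "NaCl": ("Na+", "Cl-"), "NaBr": ("Na+", "Br-"),
    "KF": ("K+", "F-"), "KCl": ("K+", "Cl-"), "KBr": ("K+", "Br-"),
}

#: default water coordination number used for every hydration shell
DEFAULT_COORDINATION = 18

WATER_CONC_M = 55.5
WATER_RADIUS_A = 1.4
EPS_WATER = 78.45


def hydration_spec(ion: str, salt: str | None = None,
                   coordination: int = DEFAULT_COORDINATION) -> HydrationSpec:
    """Preset :class:`HydrationSpec` for a known ion, optionally with the
    fitted Born-scaling parameters of a given salt."""
    alphas = (0.0, 0.0, 0.0)
    if salt is not None:
        try:
            alphas = ALPHA_TABLE[salt][ion]
        except KeyError as exc:
            raise KeyError(f"no fitted parameters for {ion} in {salt}") from exc
    return HydrationSpec(
        name=ion,
        z=ION_VALENCE[ion],
        pauling_radius_A=PAULING_RADII_A[ion],
        born_radius0_A=BORN_RADII_A[ion],
        coordination=coordination,
        alphas=alphas,
    )
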