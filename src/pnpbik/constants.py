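"""Unit system and physical constants.

The package works in reduced units throughout:

* lengths in angstrom (Å),
* energies in units of ``kBT``,
* electric potentials in ``kBT/e`` (dimensionless reduced potential),
* number densities in ``Å^-3`` with molar converters,
* charge densities in ``e Å^-3`` and surface charge in ``e Å^-2``.

All electrostatic constants enter through a single quantity, the Bjerrum
length ``l_B = e^2 / (4 pi eps_r eps0 kB T)``, which is the distance at
which two unit charges in the dielectric interact with energy kBT.
"""

from __future__ import annotations

from scipy import constants as _si

#: number density (Å^-3) of a 1 molar solution: N_A * 1000 L/m^3 * 1e-30 m^3/Å^3
MOLAR_TO_PER_A3: float = _si.Avogadro * 1e3 * 1e-30  # = 6.02214076e-4

#: e^2/(4 pi eps0) in eV·Å — Coulomb energy of two unit charges 1 Å apart in vacuum
COULOMB_EV_A: float = _si.e / (4.0 * _si.pi * _si.epsilon_0) * 1e10

#: Boltzmann constant in eV/K
KB_EV: float = _si.k / _si.e

#: room temperature used throughout unless overridden (K)
T_DEFAULT: float = 298.15

#: 1 kBT per particle in kcal/mol at temperature T: R*T in kcal/mol
KCAL_PER_MOL_PER_KBT = _si.R / (_si.calorie * 1e3)  # multiply by T


def thermal_energy_ev(T: float = T_DEFAULT) -> float:
    """kB*T in eV."""
    return KB_EV * T


def bjerrum_length(eps_r: float, T: float = T_DEFAULT) -> float:
    """Bjerrum length in Å for relative permittivity ``eps_r`` at ``T`` kelvin.

    For water (eps_r = 78.45) at 298.15 K this is about 7.15 Å.
    """
    if eps_r <= 0:
        raise ValueError(f"relative permittivity must be positive, got {eps_r}")
    return COULOMB_EV_A / (eps_r * thermal_energy_ev(T))


def molar(conc_per_A3: float) -> float:
    """Convert a number density in Å^-3 to molar concentration."""
    return conc_per_A3 / MOLAR_TO_PER_A3


def per_A3(conc_M: float) -> float:
    """Convert a molar concentration to number density in Å^-3."""
    return conc_M * MOLAR_TO_PER_A3


def kbt_to_kcal_per_mol(energy_kbt: float, T: float = T_DEFAULT) -> float:
    """Convert an energy in kBT units to kcal/mol."""
    return energy_kbt * KCAL_PER_MOL_PER_KBT * T
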