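"""Electrolyte compositions, void fractions and saturating Fermi distributions.

An :class:`ElectrolyteComposition` holds ionic species plus water (always the
last species, valence 0).  Each particle of species *i* occupies a hard volume
``v_i = (4 pi / 3) a_i^3``; the space not occupied by any particle is the
*void fraction*

    Gamma(r) = 1 - sum_i v_i C_i(r),            Gamma_B in bulk,

which must stay strictly positive.  Local crowding relative to bulk defines
the steric potential ``S(r) = ln(Gamma(r)/Gamma_B)``, and the equilibrium
concentrations follow the saturating (classical Fermi) law

    C_i = C_i^B exp(-z_i phi + (v_i/v0) S),     v0 = mean particle volume,

which is bounded above for any electric potential phi, unlike the Boltzmann
distribution it reduces to when all volumes vanish.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .constants import MOLAR_TO_PER_A3, T_DEFAULT
from .errors import InfeasibleCompositionError, SaturationError, ValidationError

__all__ = [
    "Species",
    "ElectrolyteComposition",
    "make_composition",
    "void_fraction",
    "steric_potential",
    "fermi_concentrations",
    "equilibrium_concentrations",
    "charge_density",
    "saturation_bound",
]

_ELECTRONEUTRALITY_RTOL = 1e-12
#: largest exponent fed to np.exp; beyond this the analytic saturation limit rules
_EXP_CAP = 700.0


@dataclass(frozen=True)
class Species:
    """One particle species: name, integer valence, hard-sphere radius, bulk conc."""

    name: str
    z: int
    radius_A: float
    conc_M: float

    def __post_init__(self):
        if self.radius_A < 0:
            raise ValidationError(f"{self.name}: radius must be >= 0, got {self.radius_A}")
        if self.conc_M < 0:
            raise ValidationError(f"{self.name}: concentration must be >= 0, got {self.conc_M}")

    @property
    def volume_A3(self) -> float:
        return 4.0 / 3.0 * np.pi * self.radius_A**3


@dataclass(frozen=True)
class ElectrolyteComposition:
    """Ionic species plus water (last, z=0) at temperature ``T`` kelvin.

    Vectorised views (volumes, valences, bulk number densities) are exposed as
    numpy arrays ordered like ``species``.
    """

    species: tuple[Species, ...]
    T: float = T_DEFAULT
    #: steric-energy weighting: "volume" gives each species the exponent
    #: v_i/v0 of the general theory; "uniform" gives every finite-volume
    #: species weight 1 (Bikerman's identical-steric-energy special case,
    #: appropriate for equal-sized binary electrolytes).
    steric_mode: str = "volume"
    _validate: bool = field(default=True, repr=False)

    def __post_init__(self):
        if len(self.species) < 2:
            raise ValidationError("need at least one ionic species plus water")
        water = self.species[-1]
        if water.z != 0:
            raise ValidationError("water (last species) must have valence 0")
        if self._validate:
            zc = sum(s.z * s.conc_M for s in self.ions)
            scale = sum(abs(s.z) * s.conc_M for s in self.ions) or 1.0
            if abs(zc) > _ELECTRONEUTRALITY_RTOL * scale:
                raise ValidationError(
                    f"ionic species are not electroneutral: sum z_i C_i = {zc:g} M"
                )
        if self.gamma_bulk <= 0.0:
            raise InfeasibleCompositionError(
                f"bulk composition over-packed: Gamma_B = {self.gamma_bulk:g} <= 0"
            )

    # -- species views -------------------------------------------------------
    @property
    def ions(self) -> tuple[Species, ...]:
        return self.species[:-1]

    @property
    def water(self) -> Species:
        return self.species[-1]

    @property
    def n_ion_species(self) -> int:
        return len(self.species) - 1

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(s.name for s in self.species)

    # -- vectorised quantities ----------------------------------------------
    @property
    def valences(self) -> np.ndarray:
        return np.array([s.z for s in self.species], dtype=float)

    @property
    def volumes(self) -> np.ndarray:
        """Per-particle volumes v_i in Å^3 (water last)."""
        return np.array([s.volume_A3 for s in self.species])

    @property
    def v0(self) -> float:
        """Average particle volume v0 = sum v_i / (K+1) in Å^3."""
        return float(self.volumes.mean())

    @property
    def bulk_densities(self) -> np.ndarray:
        """Bulk number densities C_i^B in Å^-3."""
        return np.array([s.conc_M for s in self.species]) * MOLAR_TO_PER_A3

    @property
    def gamma_bulk(self) -> float:
        """Bulk void fraction Gamma_B = 1 - sum v_i C_i^B."""
        return 1.0 - float(self.volumes @ self.bulk_densities)

    @property
    def steric_weights(self) -> np.ndarray:
        """Steric-potential exponent weights (0 for point particles)."""
        v = self.volumes
        if self.steric_mode == "uniform":
            return (v > 0).astype(float)
        v0 = self.v0
        if v0 == 0.0:  # all-point-particle limit: no steric coupling at all
            return np.zeros(len(self.species))
        return v / v0

    # -- transformations -----------------------------------------------------
    def with_scaled_radii(self, s: float) -> "ElectrolyteComposition":
        """Composition with every radius multiplied by ``s`` (volumes by s^3)."""
        return ElectrolyteComposition(
            tuple(replace(sp, radius_A=sp.radius_A * s) for sp in self.species),
            T=self.T,
            steric_mode=self.steric_mode,
            _validate=False,
        )

    def point_particle_limit(self) -> "ElectrolyteComposition":
        return self.with_scaled_radii(0.0)


def make_composition(
    species_table: Sequence[tuple[str, int, float, float] | Species | dict],
    T: float = T_DEFAULT,
    steric_mode: str = "volume",
) -> ElectrolyteComposition:
    """Build a validated composition from a table of species.

    Each row is ``(name, z, radius_A, conc_M)`` (or a dict / :class:`Species`
    with those fields); water must be the last row with ``z = 0``.
    """
    rows = []
    for row in species_table:
        if isinstance(row, Species):
            rows.append(row)
        elif isinstance(row, dict):
            rows.append(Species(row["name"], int(row["z"]), float(row["radius_A"]),
                                float(row["conc_M"])))
        else:
            name, z, a, c = row
            rows.append(Species(str(name), int(z), float(a), float(c)))
    return ElectrolyteComposition(tuple(rows), T=T, steric_mode=steric_mode)


def void_fraction(C: np.ndarray, composition: ElectrolyteComposition) -> np.ndarray | float:
    """Void fraction Gamma = 1 - sum_i v_i C_i (ions and water).

    ``C`` has shape (K+1,) or (K+1, n) in Å^-3.  Raises
    :class:`SaturationError` if Gamma <= 0 anywhere.
    """
    C = np.asarray(C, dtype=float)
    if np.any(C < 0):
        raise ValidationError("concentrations must be >= 0")
    gamma = 1.0 - np.tensordot(composition.volumes, C, axes=(0, 0))
    if np.any(gamma <= 0.0):
        raise SaturationError("packing bound violated: sum v_i C_i >= 1")
    return gamma if np.ndim(gamma) else float(gamma)


def steric_potential(gamma: np.ndarray | float, gamma_bulk: float) -> np.ndarray | float:
    """Steric potential S = ln(Gamma / Gamma_B); zero iff Gamma equals bulk."""
    gamma = np.asarray(gamma, dtype=float)
    if np.any(gamma <= 0.0) or gamma_bulk <= 0.0:
        raise SaturationError("void fractions must be strictly positive")
    out = np.log(gamma / gamma_bulk)
    return out if out.ndim else float(out)


def fermi_concentrations(
    phi: np.ndarray | float,
    S: np.ndarray | float,
    composition: ElectrolyteComposition,
) -> np.ndarray:
    """Evaluate C_i = C_i^B exp(-z_i phi + (v_i/v0) S) for a *given* S.

    Saturation is not enforced here: consistency of S with the resulting
    concentrations is the caller's concern (see
    :func:`equilibrium_concentrations`).  Infinite phi is accepted; the
    exponential saturates at the numeric cap instead of overflowing.
    Result has shape (K+1,) + shape(phi).
    """
    phi = np.asarray(phi, dtype=float)
    S = np.broadcast_to(np.asarray(S, dtype=float), phi.shape)
    z = composition.valences
    w = composition.steric_weights
    expo = -np.multiply.outer(z, phi) + np.multiply.outer(w, S)
    expo = np.clip(expo, -np.inf, _EXP_CAP)
    return composition.bulk_densities.reshape((-1,) + (1,) * phi.ndim) * np.exp(expo)


def equilibrium_concentrations(
    phi: np.ndarray | float,
    composition: ElectrolyteComposition,
    *,
    tol: float = 1e-15,
    max_iter: int = 200,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Self-consistent (C, Gamma, S) at potential phi.

    The Fermi law is implicit: S depends on Gamma which depends on C which
    depends on S.  In terms of t = S the fixed point solves

        h(t) = Gamma_B e^t + sum_i exp(a_i + w_i t) - 1 = 0,
        a_i = ln(v_i C_i^B) - z_i phi,

    and h is strictly increasing in t, so the root is unique and is found by
    bisection entirely in log space — robust for |phi| up to 1e6 and beyond
    (the analytic saturation limit is approached smoothly).  Species with
    v_i = 0 drop out of Gamma and are pure Boltzmann.

    Returns arrays C (K+1, ...), Gamma (...), S (...).
    """
    scalar_in = np.ndim(phi) == 0
    phi = np.atleast_1d(np.asarray(phi, dtype=float))
    gB = composition.gamma_bulk
    v = composition.volumes
    w = composition.steric_weights
    z = composition.valences
    CB = composition.bulk_densities

    finite = v > 0
    # log of v_i C_i^B (Gamma/GammaB)^w evaluated via exponent a_i + w_i t
    with np.errstate(divide="ignore"):
        log_vCB = np.log(np.where(finite, v * CB, 1.0))
    a = log_vCB[:, None] - np.multiply.outer(z, phi.ravel())  # (K+1, m)
    a[~finite, :] = -np.inf

    def h(t):  # t shape (m,)
        terms = np.exp(np.minimum(a + w[:, None] * t[None, :], _EXP_CAP))
        return gB * np.exp(np.minimum(t, _EXP_CAP)) + terms.sum(axis=0) - 1.0

    m = phi.size
    hi = np.full(m, np.log(1.0 / gB))  # Gamma <= 1 always
    lo = np.full(m, -1.0)
    # expand lower bracket until h(lo) < 0
    for _ in range(80):
        bad = h(lo) >= 0.0
        if not bad.any():
            break
        lo[bad] *= 2.0
    # bisection: interval halves 120 times -> far below any practical tol
    for _ in range(120):
        mid = 0.5 * (lo + hi)
        pos = h(mid) > 0.0
        hi = np.where(pos, mid, hi)
        lo = np.where(pos, lo, mid)
        if np.max(hi - lo) < tol:
            break
    S = 0.5 * (lo + hi)
    S = S.reshape(phi.shape)
    gamma = gB * np.exp(S)
    C = fermi_concentrations(phi, S, composition)
    # guard the packing bound against the last-ulp rounding of exp():
    # mathematically sum v_i C_i = 1 - gamma < 1 always
    total = np.tensordot(v, C, axes=(0, 0))
    over = total > 1.0
    if np.any(over):
        # divide by slightly more than the overshoot so re-rounding cannot
        # push the sum back above 1
        C[:, over] /= total[over] * (1.0 + 4e-16)
    if scalar_in:
        return C[:, 0], float(gamma[0]), float(S[0])
    return C, gamma, S


def charge_density(C: np.ndarray, composition: ElectrolyteComposition) -> np.ndarray | float:
    """Ionic charge density rho = sum_{i<=K} z_i C_i in e Å^-3 (water excluded)."""
    C = np.asarray(C, dtype=float)
    z = composition.valences
    rho = np.tensordot(z, C, axes=(0, 0))
    return rho if np.ndim(rho) else float(rho)


def saturation_bound(composition: ElectrolyteComposition, i: int) -> float:
    """Hard upper bound on C_i: v0/v_i^2 if v_i <= v0, else 1/v_i."""
    v = composition.volumes[i]
    if v == 0:
        return np.inf
    v0 = composition.v0
    return v0 / v**2 if v <= v0 else 1.0 / v
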