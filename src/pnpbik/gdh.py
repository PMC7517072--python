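"""Closed-form generalized Debye–Hückel (DH) activity model.

A single hydrated ion sits at the origin of a spherically symmetric domain
partitioned into the ionic cavity (radius ``R_Born``), its hydration shell
(outer radius ``R_sh``), and the surrounding electrolyte.  Linearising the
saturating charge density of the fourth-order Poisson–Bikerman operator
around zero potential gives an analytic reaction potential whose screening
is controlled by

* the Bjerrum length ``l_B``,
* the generalized Debye length ``l_D4`` (steric linearisation factor
  ``Lambda`` corrects the classical ``l_D`` for unequal ion volumes),
* the correlation length ``l_c = sqrt(l_B l_D4 / 48)``,
* spectral roots ``lambda_1 <= lambda_2`` of the fourth-order operator, and
* the interface factor ``Theta`` at the shell boundary.

The excess chemical potential is half the difference between the reaction
potential at the ion center in the electrolyte and in pure water, giving

    ln gamma = (z^2 l_B / 2) [1/R_Born - 1/R_0 + (Theta - 1)/R_sh].

Classical DH (1923) and the extended DH–Born form (1925, power series in
ionic strength) are provided as alternative modes for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq, least_squares

from .composition import ElectrolyteComposition, make_composition
from .constants import MOLAR_TO_PER_A3, T_DEFAULT, bjerrum_length
from .errors import (
    ComplexRootError,
    DegenerateGeometryError,
    NoSolutionError,
    ValidationError,
)

__all__ = [
    "HydrationSpec",
    "GDHResult",
    "binary_composition",
    "screening_lengths",
    "spectral_roots",
    "theta_factor",
    "shell_radius",
    "born_radius",
    "reaction_potential",
    "activity_coefficient",
    "excess_chemical_potential",
    "gdh_result",
    "fit_activity_parameters",
]

#: empirical divisor in the density–density correlation length l_c^2 = l_B l_D / 48
_CORRELATION_DIVISOR = 48.0


@dataclass(frozen=True)
class HydrationSpec:
    """Hydration parameters of one ionic species.

    ``alphas`` are the three Born-radius scaling coefficients of
    ``theta(C) = 1 + a1 sqrt(C) + a2 C + a3 C^(3/2)`` (C in molar);
    ``coordination`` is the number of water molecules in the first shell.
    """

    name: str
    z: int
    pauling_radius_A: float
    born_radius0_A: float
    coordination: float = 18.0
    alphas: tuple[float, float, float] = (0.0, 0.0, 0.0)
    eps_ion: float = 1.0

    def __post_init__(self):
        if self.born_radius0_A <= 0:
            raise ValidationError("Born radius R0 must be positive")
        if self.coordination < 0:
            raise ValidationError("coordination number must be >= 0")


@dataclass(frozen=True)
class GDHResult:
    """All scalars of the generalized DH model for one ion in one solution."""

    ion: str
    lB: float
    lD: float
    Lambda: float
    lD4: float
    lc: float
    lambda1: float
    lambda2: float  # inf in the lc -> 0 limit
    theta: float
    R_born: float
    R_born0: float
    R_shell: float
    V_shell: float
    ln_gamma: float
    mu_ex_kbt: float


def binary_composition(
    salt: str | tuple[str, int, float, str, int, float],
    conc_M: float,
    T: float = T_DEFAULT,
    water_conc_M: float = 55.5,
    water_radius_A: float = 1.4,
) -> ElectrolyteComposition:
    """Composition of a binary salt at ``conc_M`` molar plus water.

    ``salt`` is a preset name ("LiCl", ...) or an explicit tuple
    (cation, z+, a+, anion, z-, a-).  Stoichiometry follows from the
    valences: the cation concentration is ``conc * |z-|`` and the anion
    concentration ``conc * z+``.
    """
    if isinstance(salt, str):
        from .presets import ION_VALENCE, PAULING_RADII_A, SALT_IONS

        cat, an = SALT_IONS[salt]
        spec = (cat, ION_VALENCE[cat], PAULING_RADII_A[cat],
                an, ION_VALENCE[an], PAULING_RADII_A[an])
    else:
        spec = salt
    cat, zp, ap, an, zm, am = spec
    if zp <= 0 or zm >= 0:
        raise ValidationError("expected cation valence > 0 and anion valence < 0")
    return make_composition(
        [
            (cat, zp, ap, conc_M * abs(zm)),
            (an, zm, am, conc_M * zp),
            ("H2O", 0, water_radius_A, water_conc_M),
        ],
        T=T,
    )


def screening_lengths(
    composition: ElectrolyteComposition,
    ion_index: int = 0,
    eps_s: float = 78.45,
) -> tuple[float, float, float, float, float]:
    """(l_B, l_D, Lambda, l_D4, l_c) for a binary electrolyte plus water.

    ``ion_index`` (0 or 1) selects the ion of interest as species 1 of the
    steric linearisation

        Lambda = C1 (v1 - v2)^2 / { Gamma_B [v0 + v1^2 C1 + v2^2 C2 + v3^2 C3] },

    which vanishes for equal ionic volumes, leaving the classical Debye
    length.  The generalized Debye length is

        l_D4 = [ 4 pi l_B C1 ((1 - Lambda) z1^2 - z1 z2) ]^(-1/2)

    and the density–density correlation length ``l_c = sqrt(l_B l_D4 / 48)``.
    """
    if composition.n_ion_species != 2:
        raise ValidationError("screening_lengths requires a binary electrolyte")
    lB = bjerrum_length(eps_s, composition.T)
    z = composition.valences
    C = composition.bulk_densities
    v = composition.volumes
    ionic = 4.0 * np.pi * lB * float(np.sum(z[:-1] ** 2 * C[:-1]))
    if ionic <= 0:
        raise ValidationError("need nonzero salt for a finite Debye length")
    lD = ionic ** -0.5

    i1 = ion_index
    i2 = 1 - ion_index
    v0 = composition.v0
    gB = composition.gamma_bulk
    num = C[i1] * (v[i1] - v[i2]) ** 2
    if num == 0.0:  # equal ionic volumes (or point particles): no steric shift
        Lambda = 0.0
    else:
        Lambda = num / (
            gB * (v0 + v[i1] ** 2 * C[i1] + v[i2] ** 2 * C[i2] + v[2] ** 2 * C[2])
        )
    denom = 4.0 * np.pi * lB * C[i1] * ((1.0 - Lambda) * z[i1] ** 2 - z[i1] * z[i2])
    if denom <= 0:
        raise ValidationError("infeasible parameters: nonpositive screening argument")
    lD4 = denom ** -0.5
    lc = np.sqrt(lB * lD4 / _CORRELATION_DIVISOR)
    return lB, lD, float(Lambda), float(lD4), float(lc)


def spectral_roots(lc: float, lD4: float) -> tuple[float, float]:
    """Roots (lambda1, lambda2), in Å^-1, of the fourth-order screening operator.

    lambda_{1,2} = sqrt( [1 -/+ sqrt(1 - 4 lc^2/lD4^2)] / (2 lc^2) ).  The
    Vieta identities l1^2 + l2^2 = 1/lc^2 and l1^2 l2^2 = 1/(lc^2 lD4^2)
    follow.  At lc = 0 the limit is (1/lD4, inf).
    """
    if lc < 0 or lD4 <= 0:
        raise ValidationError("need lc >= 0 and lD4 > 0")
    if lc == 0.0:
        return 1.0 / lD4, np.inf
    disc = 1.0 - 4.0 * lc**2 / lD4**2
    if disc < 0:
        raise ComplexRootError(
            f"4 lc^2 = {4*lc**2:g} exceeds lD4^2 = {lD4**2:g}: complex roots"
        )
    s = np.sqrt(disc)
    l1 = np.sqrt((1.0 - s) / (2.0 * lc**2))
    l2 = np.sqrt((1.0 + s) / (2.0 * lc**2))
    return float(l1), float(l2)


def theta_factor(lambda1: float, lambda2: float, R_shell: float) -> float:
    """Interface factor Theta of the analytic reaction potential.

    Evaluated through the equivalent form

        Theta = (l1 + l2) / (l1 + l2 + l1 l2 R_sh),

    which continues smoothly through coalescing roots (l1 = l2) and through
    the lc -> 0 limit (l2 = inf), where Theta -> 1/(1 + R_sh/lD) so that
    (Theta - 1)/R_sh -> -1/(R_sh + lD), the classical DH screening term.
    Theta -> 1 at infinite dilution (both roots -> 0).
    """
    if R_shell < 0:
        raise ValidationError("shell radius must be >= 0")
    if np.isinf(lambda2):
        denom = 1.0 + lambda1 * R_shell
        if denom == 0.0:
            raise DegenerateGeometryError("Theta denominator vanished")
        return 1.0 / denom
    s = lambda1 + lambda2
    denom = s + lambda1 * lambda2 * R_shell
    if denom == 0.0:
        raise DegenerateGeometryError("Theta denominator vanished")
    return s / denom


def shell_radius(
    spec: HydrationSpec,
    composition: ElectrolyteComposition,
) -> tuple[float, float]:
    """(V_shell, R_shell) from the steric shell condition.

    The shell volume solves

        ln[(V - v_w O) / (V Gamma_B)] = (v0 / v_w) ln[O / (V C_w^B)],

    balancing the steric potential of a shell packed with ``O`` water
    molecules against the bulk void fraction; the outer shell radius follows
    from ``V = (4 pi/3)(R_sh^3 - a_i^3)`` with ``a_i`` the Pauling radius.
    """
    O = spec.coordination
    if O <= 0:
        raise ValidationError("shell equation needs a positive coordination number")
    v_w = composition.water.volume_A3
    C_w = composition.water.conc_M * MOLAR_TO_PER_A3
    v0 = composition.v0
    gB = composition.gamma_bulk

    def residual(V):
        return np.log((V - v_w * O) / (V * gB)) - (v0 / v_w) * np.log(O / (V * C_w))

    lo = v_w * O * (1.0 + 1e-10)
    hi = v_w * O * 1e6
    grid = np.geomspace(lo, hi, 400)
    vals = residual(grid)
    sign_change = np.where(np.diff(np.sign(vals)) != 0)[0]
    if len(sign_change) == 0:
        raise NoSolutionError("shell equation has no root in the bracket")
    k = sign_change[0]
    V = brentq(residual, grid[k], grid[k + 1], xtol=1e-12, rtol=1e-14)
    if V <= v_w * O:
        raise NoSolutionError("shell would be over-packed with water")
    R = (3.0 * V / (4.0 * np.pi) + spec.pauling_radius_A**3) ** (1.0 / 3.0)
    return float(V), float(R)


def born_radius(spec: HydrationSpec, conc_M: float) -> float:
    """Concentration-dependent Born radius R = theta(C) R0.

    theta = 1 + a1 sqrt(C) + a2 C + a3 C^(3/2) with C the ion's bulk molar
    concentration; theta must stay positive.
    """
    if conc_M < 0:
        raise ValidationError("concentration must be >= 0")
    a1, a2, a3 = spec.alphas
    c = conc_M
    theta = 1.0 + a1 * np.sqrt(c) + a2 * c + a3 * c**1.5
    if theta <= 0:
        raise ValidationError(f"Born scaling theta = {theta:g} <= 0")
    return theta * spec.born_radius0_A


def gdh_result(
    spec: HydrationSpec,
    composition: ElectrolyteComposition,
    eps_s: float = 78.45,
    ion_index: int | None = None,
) -> GDHResult:
    """Full generalized-DH pipeline for one ion in one binary solution."""
    if ion_index is None:
        try:
            ion_index = composition.names.index(spec.name)
        except ValueError:
            ion_index = 0
    lB, lD, Lambda, lD4, lc = screening_lengths(composition, ion_index, eps_s)
    l1, l2 = spectral_roots(lc, lD4)
    V_sh, R_sh = shell_radius(spec, composition)
    theta = theta_factor(l1, l2, R_sh)
    conc = composition.species[ion_index].conc_M
    R_b = born_radius(spec, conc)
    ln_g = (
        spec.z**2 * lB / 2.0
        * (1.0 / R_b - 1.0 / spec.born_radius0_A + (theta - 1.0) / R_sh)
    )
    return GDHResult(
        ion=spec.name, lB=lB, lD=lD, Lambda=Lambda, lD4=lD4, lc=lc,
        lambda1=l1, lambda2=l2, theta=theta, R_born=R_b,
        R_born0=spec.born_radius0_A, R_shell=R_sh, V_shell=V_sh,
        ln_gamma=float(ln_g), mu_ex_kbt=float(ln_g),
    )


def reaction_potential(
    r: np.ndarray | float,
    result: GDHResult,
    z: int | None = None,
) -> np.ndarray | float:
    """Three-branch analytic reaction potential phi(r) in kBT/e.

    Inside the cavity (r < R_Born) the potential is constant; in the shell it
    is the bare Coulomb potential plus the constant shell correction; in the
    electrolyte it is the double-exponential screened form of the
    fourth-order operator.  Continuous at both interfaces by construction.
    """
    if z is None:
        z = _default_valence(result)
    scalar_in = np.ndim(r) == 0
    r = np.atleast_1d(np.asarray(r, dtype=float))
    lB, Rb, Rsh = result.lB, result.R_born, result.R_shell
    l1, l2, th = result.lambda1, result.lambda2, result.theta
    pref = z * lB

    shell_const = (th - 1.0) / Rsh if Rsh > 0 else 0.0
    out = np.empty_like(r)
    inner = r < Rb
    shell = (~inner) & (r < Rsh)
    solv = ~(inner | shell)
    out[inner] = pref * (1.0 / Rb + shell_const)
    out[shell] = pref * (1.0 / r[shell] + shell_const)
    rs = r[solv]
    if np.isinf(l2):  # lc -> 0: single-exponential DH screening
        out[solv] = pref / rs * np.exp(-l1 * (rs - Rsh)) / (1.0 + l1 * Rsh)
    else:
        denom = l1**2 * (l2 * Rsh + 1.0) - l2**2 * (l1 * Rsh + 1.0)
        num = l1**2 * np.exp(-l2 * (rs - Rsh)) - l2**2 * np.exp(-l1 * (rs - Rsh))
        out[solv] = pref / rs * num / denom
    return float(out[0]) if scalar_in else out


def _default_valence(result: GDHResult) -> int:
    from .presets import ION_VALENCE

    return ION_VALENCE.get(result.ion, 1)


def activity_coefficient(
    spec: HydrationSpec,
    composition: ElectrolyteComposition,
    mode: str = "generalized",
    eps_s: float = 78.45,
    eta: tuple[float, float] = (0.0, 0.0),
) -> float:
    """ln gamma for one ion, by the requested model.

    mode "generalized": the closed-form model above.  mode "classical_DH":
    ln gamma = -z^2 l_B / (2 (l_D + R)) with R the ion's Pauling radius.
    mode "extended_DHB": classical with distance-of-closest-approach eta0 and
    salting-out term eta1 * I, I the ionic strength in molar.
    """
    if mode == "generalized":
        return gdh_result(spec, composition, eps_s).ln_gamma
    lB = bjerrum_length(eps_s, composition.T)
    z2 = spec.z**2
    zC = composition.valences[:-1] ** 2 * composition.bulk_densities[:-1]
    ionic = 4.0 * np.pi * lB * float(zC.sum())
    if ionic == 0.0:
        return 0.0
    lD = ionic ** -0.5
    if mode == "classical_DH":
        return -z2 * lB / (2.0 * (lD + spec.pauling_radius_A))
    if mode == "extended_DHB":
        I = 0.5 * float(
            np.sum(composition.valences[:-1] ** 2
                   * np.array([s.conc_M for s in composition.ions]))
        )
        eta0, eta1 = eta
        return -z2 * lB / (2.0 * lD * (1.0 + eta0 * np.sqrt(I))) + eta1 * I
    raise ValidationError(f"unknown mode {mode!r}")


def excess_chemical_potential(
    spec: HydrationSpec,
    composition: ElectrolyteComposition,
    eps_s: float = 78.45,
) -> float:
    """mu_i^ex in kBT: identical to ln gamma of the generalized model."""
    return gdh_result(spec, composition, eps_s).mu_ex_kbt


def fit_activity_parameters(
    data: "np.ndarray | list[tuple[float, float]]",
    spec: HydrationSpec,
    salt: str | tuple,
    eps_s: float = 78.45,
    water_conc_M: float = 55.5,
    water_radius_A: float = 1.4,
) -> tuple[np.ndarray, float]:
    """Least-squares Born-scaling parameters (a1, a2, a3) from activity data.

    ``data`` rows are (concentration_M, gamma).  Returns the parameter vector
    and the residual norm in ln gamma.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2 or data.shape[0] < 3:
        raise ValidationError("need at least 3 (concentration, gamma) rows")
    concs, gammas = data[:, 0], data[:, 1]
    if np.any(gammas <= 0):
        raise ValidationError("activity coefficients must be positive")
    target = np.log(gammas)

    def model(alphas):
        s = HydrationSpec(
            name=spec.name, z=spec.z, pauling_radius_A=spec.pauling_radius_A,
            born_radius0_A=spec.born_radius0_A, coordination=spec.coordination,
            alphas=tuple(alphas), eps_ion=spec.eps_ion,
        )
        out = np.empty_like(concs)
        for k, c in enumerate(concs):
            comp = binary_composition(salt, c, water_conc_M=water_conc_M,
                                      water_radius_A=water_radius_A)
            out[k] = activity_coefficient(s, comp, "generalized", eps_s)
        return out

    res = least_squares(lambda a: model(a) - target, x0=np.zeros(3), method="lm")
    return res.x, float(np.linalg.norm(res.fun))
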