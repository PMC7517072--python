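"""Steady-state Nernst–Planck–Bikerman transport.

The flux of species *i* (including water, z = 0) is

    J_i = -D_i [ C_i' + z_i C_i phi' - (v_i/v0) C_i S' ],

so ions drift in the electric field and *all* finite-size particles drift
down the steric-potential gradient (the entropic force of the voids).  The
discretization is the generalized Scharfetter–Gummel (SG) exponential
fitting scheme: on each edge the potential combination
``t = z dphi - w dS`` is treated as a constant field and the two-point flux

    J = -(D/h) [ B(-t) C_right - B(t) C_left ],      B(t) = t / (e^t - 1)

integrates the flux ODE exactly, guaranteeing positive concentrations and
spatially constant flux (current preservation).  A single edge spanning the
whole domain with a constant field recovers the Goldman–Hodgkin–Katz flux
formula.  The drift-diffusion system is coupled to the fourth-order
Poisson–Bikerman electrostatics by Gummel outer iteration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .composition import (
    ElectrolyteComposition,
    charge_density,
    equilibrium_concentrations,
    steric_potential,
    void_fraction,
)
from .constants import bjerrum_length
from .errors import ConvergenceError, ValidationError
from .fourpbik import DomainSpec, SolverConfig, _apply_phi_bcs, _solve_aux, _solve_tridiag
from .state import FieldState

__all__ = [
    "TransportSpec",
    "FluxProfile",
    "bernoulli",
    "sg_flux",
    "ghk_flux",
    "stability_margin",
    "assemble_npb",
    "solve_npb_concentrations",
    "solve_pnpb_steady",
]


@dataclass(frozen=True)
class TransportSpec:
    """Per-species diffusion data and reservoir conditions.

    ``diffusion`` maps species name to D_i in Å^2 per time unit (the time
    unit is the user's choice and only scales fluxes); ``theta`` is a
    multiplicative pore reduction factor applied inside ``pore_region``
    (x-interval in Å) if given.  ``left_conc_M``/``right_conc_M`` override
    the bulk reservoir concentrations per species when present.  ``voltage``
    (kBT/e) is applied on the left boundary; the right is grounded.
    """

    diffusion: dict[str, float]
    voltage: float = 0.0
    theta: float = 1.0
    pore_region: tuple[float, float] | None = None
    left_conc_M: dict[str, float] = field(default_factory=dict)
    right_conc_M: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if not (0.0 < self.theta <= 1.0):
            raise ValidationError("pore reduction factor theta must lie in (0, 1]")
        for name, d in self.diffusion.items():
            if d <= 0:
                raise ValidationError(f"diffusion coefficient of {name} must be > 0")


@dataclass
class FluxProfile:
    """Edge fluxes per species (Å^-2 time^-1) and derived current."""

    edge_x: np.ndarray
    species: tuple[str, ...]
    fluxes: np.ndarray  # (K+1, n-1)
    valences: np.ndarray
    margins: np.ndarray  # (K+1, n-1) SG stability margins |t|

    @property
    def mean_flux(self) -> np.ndarray:
        return self.fluxes.mean(axis=1)

    @property
    def current(self) -> float:
        """Total current density sum_i z_i J_i in e Å^-2 time^-1."""
        return float((self.valences @ self.fluxes).mean())

    def flux_uniformity(self) -> np.ndarray:
        """Max relative spatial variation of each species' flux."""
        out = np.empty(len(self.species))
        for k, J in enumerate(self.fluxes):
            scale = np.max(np.abs(J))
            out[k] = 0.0 if scale == 0 else np.ptp(J) / scale
        return out


def bernoulli(t: np.ndarray | float) -> np.ndarray | float:
    """Bernoulli function B(t) = t/(e^t - 1), numerically stable.

    A Taylor series is used for |t| < 1e-4 (B = 1 - t/2 + t^2/12 - t^4/720);
    large negative t returns -t (since e^t -> 0) and large positive t
    underflows to 0 gracefully.
    """
    t = np.asarray(t, dtype=float)
    out = np.empty_like(t)
    small = np.abs(t) < 1e-4
    ts = t[small]
    out[small] = 1.0 - ts / 2.0 + ts**2 / 12.0 - ts**4 / 720.0
    tb = t[~small]
    with np.errstate(over="ignore"):
        out[~small] = np.where(
            tb > 700.0, 0.0,
            np.where(tb < -700.0, -tb, tb / np.expm1(np.clip(tb, -700, 700))),
        )
    return out if out.ndim else float(out)


def sg_flux(C_left, C_right, t_edge, D, h):
    """Scharfetter–Gummel edge flux J = -(D/h) [B(-t) C_right - B(t) C_left].

    ``t_edge = z dphi - w dS`` is the reduced potential drop across the edge
    (left to right).  t = 0 reduces to plain diffusion.
    """
    t = np.asarray(t_edge, dtype=float)
    return -(D / h) * (bernoulli(-t) * C_right - bernoulli(t) * C_left)


def ghk_flux(D: float, L: float, z: float, V: float, C_left: float, C_right: float) -> float:
    """Goldman–Hodgkin–Katz flux: the constant-field closed form.

    J = (D z V / L) (C_left - C_right e^{-zV}) / (1 - e^{-zV}) with
    ``V = phi_left - phi_right`` in kBT/e; the zV -> 0 limit is plain
    diffusion.  Identical to the SG flux over a single edge of length L
    with ``t = -zV``.
    """
    t = z * V
    if abs(t) < 1e-12:
        return -D * (C_right - C_left) / L
    return (D * t / L) * (C_left - C_right * np.exp(-t)) / (-np.expm1(-t))


def stability_margin(dphi, dS, z: float) -> tuple[np.ndarray, np.ndarray]:
    """|−z dphi + dS| per edge and whether the naive-FD bound 2 holds.

    The SG scheme is stable regardless; the margin diagnoses where a naive
    central difference would produce negative concentrations.
    """
    m = np.abs(-z * np.asarray(dphi, float) + np.asarray(dS, float))
    return m, m <= 2.0


def _edge_t(phi: np.ndarray, S: np.ndarray, z: float, w: float) -> np.ndarray:
    return z * np.diff(phi) - w * np.diff(S)


def assemble_npb(
    grid_h: float,
    phi: np.ndarray,
    S: np.ndarray,
    z: float,
    w: float,
    D_edge: np.ndarray,
    C_left: float,
    C_right: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Tridiagonal SG system (sub, diag, sup, rhs) for one species.

    Interior rows impose zero flux divergence with the SG edge coefficients
    b_{i-1} = -B(t_{i-1}), b_i = B(-t_{i-1}) + B(t_i), b_{i+1} = -B(-t_i)
    (scaled by the edge diffusion coefficients); Dirichlet reservoir rows at
    both ends.  Off-diagonals are strictly negative, so the matrix is an
    M-matrix and the solution is positive for positive boundary data.
    """
    n = len(phi)
    t = _edge_t(phi, S, z, w)
    Bp = bernoulli(t) * D_edge  # B(t_i) D_i+1/2
    Bm = bernoulli(-t) * D_edge
    sub = np.zeros(n)
    diag = np.zeros(n)
    sup = np.zeros(n)
    rhs = np.zeros(n)
    sub[1:-1] = -Bp[:-1]
    diag[1:-1] = Bm[:-1] + Bp[1:]
    sup[1:-1] = -Bm[1:]
    diag[0], sup[0], rhs[0] = 1.0, 0.0, C_left
    diag[-1], sub[-1], rhs[-1] = 1.0, 0.0, C_right
    return sub, diag, sup, rhs


def solve_npb_concentrations(
    x: np.ndarray,
    phi: np.ndarray,
    S: np.ndarray,
    composition: ElectrolyteComposition,
    transport: TransportSpec,
) -> np.ndarray:
    """Solve the steady NPB equation for every species on fixed (phi, S)."""
    h = float(x[1] - x[0])
    C = np.empty((len(composition.species), len(x)))
    for k, sp in enumerate(composition.species):
        D_edge = _edge_diffusion(x, sp.name, transport)
        CB = composition.bulk_densities[k]
        CL = transport.left_conc_M.get(sp.name, sp.conc_M)
        CR = transport.right_conc_M.get(sp.name, sp.conc_M)
        from .constants import MOLAR_TO_PER_A3

        CL, CR = CL * MOLAR_TO_PER_A3, CR * MOLAR_TO_PER_A3
        w = composition.steric_weights[k]
        sub, diag, sup, rhs = assemble_npb(h, phi, S, sp.z, w, D_edge, CL, CR)
        C[k] = _solve_tridiag(sub, diag, sup, rhs)
    return C


def _edge_diffusion(x, name, transport):
    D = transport.diffusion.get(name)
    if D is None:
        raise ValidationError(f"no diffusion coefficient for species {name!r}")
    xe = 0.5 * (x[:-1] + x[1:])
    D_edge = np.full(len(xe), D)
    if transport.pore_region is not None:
        a, b = transport.pore_region
        D_edge[(xe >= a) & (xe <= b)] *= transport.theta
    return D_edge


def fluxes_from_state(
    state: FieldState,
    composition: ElectrolyteComposition,
    transport: TransportSpec,
) -> FluxProfile:
    """SG edge fluxes and stability margins of a solved state."""
    x, phi, S, C = state.x, state.phi, state.steric, state.concentrations
    h = float(x[1] - x[0])
    n_sp = len(composition.species)
    J = np.empty((n_sp, len(x) - 1))
    M = np.empty_like(J)
    for k, sp in enumerate(composition.species):
        w = composition.steric_weights[k]
        t = _edge_t(phi, S, sp.z, w)
        D_edge = _edge_diffusion(x, sp.name, transport)
        J[k] = sg_flux(C[k, :-1], C[k, 1:], t, D_edge, h)
        M[k] = stability_margin(np.diff(phi), w * np.diff(S), sp.z)[0]
    return FluxProfile(
        edge_x=0.5 * (x[:-1] + x[1:]),
        species=composition.names,
        fluxes=J,
        valences=composition.valences,
        margins=M,
    )


def solve_pnpb_steady(
    domain: DomainSpec,
    composition: ElectrolyteComposition,
    transport: TransportSpec,
    config: SolverConfig = SolverConfig(),
) -> tuple[FieldState, FluxProfile]:
    """Coupled steady-state PNPB solve by Gummel iteration with voltage ramp.

    Alternates NPB concentration solves (SG scheme) with the decomposed
    fourth-order electrostatics, relaxing the potential with
    ``config.omega_pnpb`` until the max-norm update is below ``config.tol``;
    the applied voltage is ramped in increments of ``config.delta_v``.
    """
    grid = domain.grid
    x, h, n = grid.x, grid.h, grid.n
    lB = bjerrum_length(domain.eps_s, composition.T)
    rs = 4.0 * np.pi * lB
    gB = composition.gamma_bulk

    V_target = transport.voltage
    n_ramp = max(1, int(np.ceil(abs(V_target) / config.delta_v)))
    phi = np.zeros(n)
    C, _, S = equilibrium_concentrations(phi, composition)
    history: list[float] = []

    for ramp in range(1, n_ramp + 1):
        V = V_target * ramp / n_ramp
        left = ("dirichlet", V)
        right = ("dirichlet", 0.0)
        for _ in range(config.max_iter):
            C = solve_npb_concentrations(x, phi, S, composition, transport)
            gamma = void_fraction(C, composition)
            S = steric_potential(gamma, gB)
            rho = charge_density(C, composition)
            psi = _solve_aux(rs * rho, h, n, domain.lc)
            aw = rs * np.tensordot(composition.valences**2, C, axes=(0, 0))
            sub = np.full(n, -1.0)
            sup = np.full(n, -1.0)
            diag = np.full(n, 2.0)
            rhs = (-psi + aw * phi) * h**2
            _apply_phi_bcs(diag, sub, sup, rhs, h, left, right, aw)
            phi_new = _solve_tridiag(sub, diag, sup, rhs)
            err = float(np.max(np.abs(phi_new - phi)))
            history.append(err)
            if err < config.tol:
                phi = phi_new
                break
            phi = config.omega_pnpb * phi + (1.0 - config.omega_pnpb) * phi_new
        else:
            raise ConvergenceError(
                f"PNPB Gummel iteration stalled at {history[-1]:.3e} "
                f"(V = {V:g})", history)

    C = solve_npb_concentrations(x, phi, S, composition, transport)
    gamma = void_fraction(C, composition)
    S = steric_potential(gamma, gB)
    psi = _solve_aux(rs * charge_density(C, composition), h, n, domain.lc)
    state = FieldState(
        x=x, phi=phi, concentrations=C, gamma=gamma, steric=S, psi=psi,
        lc=domain.lc, eps_s=domain.eps_s,
        meta={"bjerrum_length_A": lB, "residual_history": history,
              "voltage": V_target},
    )
    return state, fluxes_from_state(state, composition, transport)
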