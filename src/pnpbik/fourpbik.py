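"""One-dimensional fourth-order Poisson–Bikerman (4PBik) solver.

The planar double-layer problem solved here is, in reduced units
(phi in kBT/e, charge density in e/Å^3),

    (lc^2 Δ - 1) psi = 4 pi l_B rho_ion(phi),      psi = Δ phi,

the decomposition of ``eps_s (lc^2 Δ - 1) Δ phi = rho`` into two
second-order PDEs.  ``lc`` is the single correlation length; ``lc = 0``
recovers the classical (second-order) Poisson–Bikerman/Boltzmann equation.
The nonlinearity (saturating Fermi concentrations with self-consistent void
fraction) is handled by Newton linearisation of rho(phi) with relaxation,
plus continuation in the steric (lambda_s scales particle volumes) and
correlation (lambda_c scales lc) switches.

Boundary conditions for a charged wall at x=0 and bulk at x=L:
``-phi'(0) = 4 pi l_B sigma`` (surface charge sigma in e/Å^2, outward normal
-x), ``phi(L) = far-field value``; ``psi'(0) = 0``, ``psi(L) = 0``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import solve_banded
from scipy.sparse import csr_matrix

from .composition import (
    ElectrolyteComposition,
    charge_density,
    equilibrium_concentrations,
)
from .constants import bjerrum_length
from .errors import ConvergenceError, ValidationError
from .state import FieldState

__all__ = [
    "Grid1D",
    "DomainSpec",
    "SolverConfig",
    "assemble_poisson",
    "interface_stencil",
    "solve_linear_fourth_order",
    "solve_equilibrium",
    "polarization_field",
    "effective_permittivity",
]


@dataclass(frozen=True)
class Grid1D:
    """Uniform grid on [0, L] with n nodes; optional dielectric interfaces.

    Interfaces must sit midway between two adjacent nodes (the interface
    stencil is derived for that placement).
    """

    L: float
    n: int
    interfaces: tuple[float, ...] = ()

    def __post_init__(self):
        if self.n < 3 or self.L <= 0:
            raise ValidationError("grid needs n >= 3 nodes and L > 0")
        h = self.h
        for g in self.interfaces:
            k = (g / h) - 0.5
            if abs(k - round(k)) > 1e-9 or not (0 < g < self.L):
                raise ValidationError(
                    f"interface at {g} is not midway between adjacent nodes"
                )

    @property
    def h(self) -> float:
        return self.L / (self.n - 1)

    @property
    def x(self) -> np.ndarray:
        return np.linspace(0.0, self.L, self.n)

    def interface_left_nodes(self) -> tuple[int, ...]:
        """Index i-1 for each interface lying between nodes i-1 and i."""
        return tuple(int(round(g / self.h - 0.5)) for g in self.interfaces)


@dataclass(frozen=True)
class DomainSpec:
    """Planar double-layer scenario.

    sigma is the surface charge density (e/Å^2) on the left wall; if
    ``left_dirichlet`` is set it overrides the charge condition with a fixed
    potential (used by the transport driver).  ``lc`` is the correlation
    length (Å); ``eps_s`` the solvent relative permittivity.
    """

    L: float
    sigma: float = 0.0
    eps_s: float = 78.45
    lc: float = 0.0
    far_potential: float = 0.0
    left_dirichlet: float | None = None
    n: int = 801

    def __post_init__(self):
        if self.eps_s <= 0:
            raise ValidationError("permittivity must be positive")
        if self.lc < 0:
            raise ValidationError("correlation length must be >= 0")
        if not np.isfinite(self.sigma):
            raise ValidationError("surface charge must be finite")

    @property
    def grid(self) -> Grid1D:
        return Grid1D(self.L, self.n)


@dataclass(frozen=True)
class SolverConfig:
    """Nonlinear iteration controls.

    tol is the max-norm potential update tolerance (kBT/e); omega_* are
    relaxation weights in (0, 1]; lambda_s_steps / lambda_c_steps the number
    of continuation increments for the steric and correlation switches.
    """

    tol: float = 1e-6
    omega_4pbik: float = 0.5
    omega_pnpb: float = 0.5
    lambda_s_steps: int = 10
    lambda_c_steps: int = 5
    delta_v: float = 0.5
    max_iter: int = 4000

    def __post_init__(self):
        if self.tol <= 0:
            raise ValidationError("tolerance must be positive")
        for w in (self.omega_4pbik, self.omega_pnpb):
            if not (0.0 < w <= 1.0):
                raise ValidationError("relaxation weights must lie in (0, 1]")


# ---------------------------------------------------------------------------
# linear algebra helpers
# ---------------------------------------------------------------------------

def _solve_tridiag(sub: np.ndarray, diag: np.ndarray, sup: np.ndarray,
                   rhs: np.ndarray) -> np.ndarray:
    n = len(diag)
    ab = np.zeros((3, n))
    ab[0, 1:] = sup[:-1]
    ab[1] = diag
    ab[2, :-1] = sub[1:]
    return solve_banded((1, 1), ab, rhs)


def interface_stencil(eps_m: float, eps_s: float, jump_phi: float,
                      jump_flux: float, h: float) -> dict[str, float]:
    """Ghost-value coefficients for a dielectric interface midway between nodes.

    The interface separates a left region with permittivity ``eps_s`` (node
    i-1 side) from a right region with ``eps_m`` (node i side).  Jumps are
    oriented right minus left: ``jump_phi = phi(g+) - phi(g-)`` and
    ``jump_flux = eps_m phi'(g+) - eps_s phi'(g-)``.

    The left-side extension of phi to node i is
    ``phi~_i = A1 phi_{i-1} + A2 phi_i + A0`` and the right-side extension to
    node i-1 is ``phi~_{i-1} = B1 phi_{i-1} + B2 phi_i + B0`` with

        A1 = -(eps_m - eps_s)/(eps_m + eps_s),  A2 = 2 eps_m/(eps_m + eps_s),
        B1 = 2 eps_s/(eps_m + eps_s),           B2 = (eps_m - eps_s)/(eps_m + eps_s),

    which restores the plain central stencil when eps_m = eps_s and keeps
    O(h^2) convergence across the material jump.
    """
    s = eps_m + eps_s
    return {
        "A1": -(eps_m - eps_s) / s,
        "A2": 2.0 * eps_m / s,
        "A0": -(2.0 * eps_m * jump_phi + h * jump_flux) / s,
        "B1": 2.0 * eps_s / s,
        "B2": (eps_m - eps_s) / s,
        "B0": (2.0 * eps_s * jump_phi - h * jump_flux) / s,
    }


def assemble_poisson(
    grid: Grid1D,
    permittivity: np.ndarray | float,
    source: np.ndarray,
    bc_left: tuple[str, float] = ("dirichlet", 0.0),
    bc_right: tuple[str, float] = ("dirichlet", 0.0),
    jumps: dict[int, tuple[float, float]] | None = None,
) -> tuple[csr_matrix, np.ndarray]:
    """Sparse tridiagonal system for ``-(eps phi')' = f`` on a uniform grid.

    ``permittivity`` is constant or edge-valued (length n-1).  Boundary
    conditions are ``("dirichlet", value)`` or ``("neumann", dphi_dx)`` where
    the value is the derivative d(phi)/dx at that boundary.  ``jumps`` maps
    the left-node index of an interface (see
    :meth:`Grid1D.interface_left_nodes`) to (jump_phi, jump_flux), both
    oriented right minus left.
    """
    n, h = grid.n, grid.h
    eps = np.broadcast_to(np.asarray(permittivity, dtype=float), (n - 1,)).copy()
    f = np.asarray(source, dtype=float).copy()
    sub = np.zeros(n)
    diag = np.zeros(n)
    sup = np.zeros(n)
    rhs = f.copy()

    # interior rows
    sub[1:-1] = -eps[:-1]
    sup[1:-1] = -eps[1:]
    diag[1:-1] = eps[:-1] + eps[1:]

    if bc_left[0] == "dirichlet":
        diag[0], sup[0], rhs[0] = 1.0, 0.0, bc_left[1]
        dirich_left = True
    elif bc_left[0] == "neumann":
        # ghost node: phi_{-1} = phi_1 - 2 h g
        diag[0], sup[0] = 2.0 * eps[0], -2.0 * eps[0]
        rhs[0] = f[0] * h**2 - 2.0 * h * eps[0] * bc_left[1]
        dirich_left = False
    else:
        raise ValidationError(f"unknown boundary kind {bc_left[0]!r}")

    if bc_right[0] == "dirichlet":
        diag[-1], sub[-1], rhs[-1] = 1.0, 0.0, bc_right[1]
        dirich_right = True
    elif bc_right[0] == "neumann":
        diag[-1], sub[-1] = 2.0 * eps[-1], -2.0 * eps[-1]
        rhs[-1] = f[-1] * h**2 + 2.0 * h * eps[-1] * bc_right[1]
        dirich_right = False
    else:
        raise ValidationError(f"unknown boundary kind {bc_right[0]!r}")

    if not dirich_left and not dirich_right:
        raise ValidationError("all-Neumann problem has no gauge; fix one value")

    # scale interior rows by h^2 on the rhs
    rhs[1:-1] = f[1:-1] * h**2

    # dielectric-interface corrections: interface between nodes il and il+1
    for il in (grid.interface_left_nodes() if grid.interfaces else ()):
        if il < 1 or il + 1 > n - 2:
            raise ValidationError("interfaces adjacent to boundary nodes unsupported")
        jphi, jflux = (jumps or {}).get(il, (0.0, 0.0))
        eL = eps[il - 1]  # pure left-material edge value
        eR = eps[il + 1]  # pure right-material edge value
        st = interface_stencil(eR, eL, jphi, jflux, h)
        # row il: the crossing edge uses eL and the left-extended phi~_{il+1}
        sub[il] = -eps[il - 1]
        diag[il] = eps[il - 1] + (1.0 - st["A1"]) * eL
        sup[il] = -st["A2"] * eL
        rhs[il] = f[il] * h**2 + eL * st["A0"]
        # row il+1: the crossing edge uses eR and the right-extended phi~_il
        sub[il + 1] = -st["B1"] * eR
        diag[il + 1] = (1.0 - st["B2"]) * eR + eps[il + 1]
        sup[il + 1] = -eps[il + 1]
        rhs[il + 1] = f[il + 1] * h**2 + eR * st["B0"]

    A = csr_matrix(
        (
            np.concatenate([diag, sub[1:], sup[:-1]]),
            (
                np.concatenate([np.arange(n), np.arange(1, n), np.arange(n - 1)]),
                np.concatenate([np.arange(n), np.arange(n - 1), np.arange(1, n)]),
            ),
        ),
        shape=(n, n),
    )
    return A, rhs


def _solve_poisson_rows(diag, sub, sup, rhs):
    return _solve_tridiag(sub, diag, sup, rhs)


# ---------------------------------------------------------------------------
# linear fourth-order solve (fixed source) — used by the free-energy functional
# ---------------------------------------------------------------------------

def solve_linear_fourth_order(
    x: np.ndarray,
    rho_reduced: np.ndarray,
    lc: float,
    *,
    left: tuple[str, float] = ("dirichlet", 0.0),
    right: tuple[str, float] = ("dirichlet", 0.0),
) -> np.ndarray:
    """Solve ``(lc^2 Δ - 1) psi = rho_reduced``, ``Δ phi = psi`` for phi.

    ``rho_reduced`` is 4 pi l_B rho (Å^-2).  psi takes a zero-Neumann left /
    zero-Dirichlet right condition when lc > 0; phi takes the given boundary
    conditions.  Returns phi.
    """
    n = len(x)
    h = float(x[1] - x[0])
    psi = _solve_aux(rho_reduced, h, n, lc)
    # -Δ phi = -psi
    sub = np.full(n, -1.0)
    sup = np.full(n, -1.0)
    diag = np.full(n, 2.0)
    rhs = -psi * h**2
    _apply_phi_bcs(diag, sub, sup, rhs, h, left, right, aw=np.zeros(n))
    return _solve_tridiag(sub, diag, sup, rhs)


def _solve_aux(f: np.ndarray, h: float, n: int, lc: float) -> np.ndarray:
    """(lc^2 Δ - 1) psi = f with psi'(0)=0, psi(L)=0."""
    if lc == 0.0:
        return -f
    c = lc**2 / h**2
    sub = np.full(n, c)
    sup = np.full(n, c)
    diag = np.full(n, -2.0 * c - 1.0)
    rhs = f.copy()
    # left Neumann via ghost psi_{-1} = psi_1
    diag[0], sup[0], rhs[0] = -2.0 * c - 1.0, 2.0 * c, f[0]
    # right Dirichlet 0
    diag[-1], sub[-1], rhs[-1] = 1.0, 0.0, 0.0
    return _solve_tridiag(sub, diag, sup, rhs)


def _apply_phi_bcs(diag, sub, sup, rhs, h, left, right, aw):
    """In-place BC rows for -Δ phi + aw phi = rhs (rows pre-scaled by h^2)."""
    diag[1:-1] += aw[1:-1] * h**2
    kind, val = left
    if kind == "dirichlet":
        diag[0], sup[0], rhs[0] = 1.0, 0.0, val
    else:  # neumann: phi'(0) = val
        diag[0] = 2.0 + aw[0] * h**2
        sup[0] = -2.0
        rhs[0] = rhs[0] - 2.0 * h * val
    kind, val = right
    if kind == "dirichlet":
        diag[-1], sub[-1], rhs[-1] = 1.0, 0.0, val
    else:
        diag[-1] = 2.0 + aw[-1] * h**2
        sub[-1] = -2.0
        rhs[-1] = rhs[-1] + 2.0 * h * val


# ---------------------------------------------------------------------------
# nonlinear equilibrium solve
# ---------------------------------------------------------------------------

def _continuation_schedule(config: SolverConfig, lc: float, comp: ElectrolyteComposition):
    """(lambda_s, lambda_c) pairs: steric ramp first, then correlations."""
    steric_needed = float(np.max(comp.volumes)) > 0.0
    ns = config.lambda_s_steps if steric_needed else 1
    sched = [(k / ns, 0.0) for k in range(1, ns + 1)]
    if lc > 0.0:
        nc = config.lambda_c_steps
        sched += [(1.0, k / nc) for k in range(1, nc + 1)]
    return sched


def solve_equilibrium(
    domain: DomainSpec,
    composition: ElectrolyteComposition,
    config: SolverConfig = SolverConfig(),
    external_charge: np.ndarray | None = None,
) -> FieldState:
    """Self-consistent equilibrium double layer: returns the solved FieldState.

    Newton linearisation of the charge density (lagged void fraction) with
    relaxation ``omega_4pbik``; steric and correlation continuation as in the
    schedule.  Raises :class:`ConvergenceError` with the residual history if
    the update never falls below ``config.tol``.
    """
    grid = domain.grid
    x, h, n = grid.x, grid.h, grid.n
    lB = bjerrum_length(domain.eps_s, composition.T)
    rs = 4.0 * np.pi * lB  # reduced-units coupling constant (Å)
    rho_ext = np.zeros(n) if external_charge is None else np.asarray(external_charge, float)

    if domain.left_dirichlet is not None:
        left = ("dirichlet", float(domain.left_dirichlet))
    else:
        left = ("neumann", -rs * domain.sigma)
    right = ("dirichlet", float(domain.far_potential))

    phi = np.zeros(n)
    history: list[float] = []

    def newton_stage(phi, comp_k, lck, tol, max_iter):
        for _ in range(max_iter):
            C, gamma, S = equilibrium_concentrations(phi, comp_k)
            rho = charge_density(C, comp_k) + rho_ext
            psi = _solve_aux(rs * rho, h, n, lck)
            aw = rs * np.tensordot(comp_k.valences**2, C, axes=(0, 0))
            sub = np.full(n, -1.0)
            sup = np.full(n, -1.0)
            diag = np.full(n, 2.0)
            rhs = (-psi + aw * phi) * h**2
            _apply_phi_bcs(diag, sub, sup, rhs, h, left, right, aw)
            phi_new = _solve_tridiag(sub, diag, sup, rhs)
            err = float(np.max(np.abs(phi_new - phi)))
            history.append(err)
            if err < tol:
                return phi_new
            phi = config.omega_4pbik * phi + (1.0 - config.omega_4pbik) * phi_new
        raise ConvergenceError(
            f"4PBik equilibrium stalled at residual {history[-1]:.3e} "
            f"(tol {tol:g})", history)

    schedule = _continuation_schedule(config, domain.lc, composition)
    for i, (lam_s, lam_c) in enumerate(schedule):
        comp_k = composition.with_scaled_radii(lam_s ** (1.0 / 3.0))
        lck = domain.lc * lam_c
        stage_tol = config.tol if i == len(schedule) - 1 else max(config.tol, 1e-4)
        phi = newton_stage(phi, comp_k, lck, stage_tol, config.max_iter)

    C, gamma, S = equilibrium_concentrations(phi, composition)
    rho = charge_density(C, composition) + rho_ext
    psi = _solve_aux(rs * rho, h, n, domain.lc)
    return FieldState(
        x=x, phi=phi, concentrations=C, gamma=gamma, steric=S, psi=psi,
        lc=domain.lc, eps_s=domain.eps_s,
        meta={"bjerrum_length_A": lB, "residual_history": history,
              "sigma": domain.sigma},
    )


# ---------------------------------------------------------------------------
# derived fields
# ---------------------------------------------------------------------------

def polarization_field(state: FieldState, lc: float | None = None) -> np.ndarray:
    """Water polarization P(x) in e/Å^2 from the solved potential.

    P = eps_s lc^2 (phi'')' - (eps_r - 1) eps0 phi' in physical units; in the
    reduced system this is ``[lc^2 phi''' - ((eps_r-1)/eps_r) phi'] / (4 pi
    l_B)``.  Derivatives by repeated central differencing (one-sided at the
    boundaries).  With lc = 0 this is the standard linear-dielectric
    polarization eps0 (eps_r - 1) E.
    """
    lc = state.lc if lc is None else lc
    x, phi = state.x, state.phi
    lB = state.meta.get("bjerrum_length_A") or bjerrum_length(state.eps_s)
    d1 = np.gradient(phi, x)
    d3 = np.gradient(np.gradient(d1, x), x)
    eps_r = state.eps_s
    return (lc**2 * d3 - (eps_r - 1.0) / eps_r * d1) / (4.0 * np.pi * lB)


def effective_permittivity(
    state: FieldState,
    lc: float | None = None,
    mask_rel: float = 1e-3,
) -> np.ndarray:
    """Output dielectric function eps_hat(x) = eps_s * (phi~' / phi').

    phi~ = phi - lc^2 phi'' is the displacement potential (the field of free
    ions); the ratio of its gradient to the full field gradient measures the
    local dielectric response.  Nodes where |phi'| is below ``mask_rel`` times
    its maximum are masked with NaN.
    """
    lc = state.lc if lc is None else lc
    x, phi = state.x, state.phi
    d1 = np.gradient(phi, x)
    d2 = np.gradient(d1, x)
    phit = phi - lc**2 * d2
    d1t = np.gradient(phit, x)
    out = np.full_like(phi, np.nan)
    thresh = mask_rel * np.max(np.abs(d1)) if np.max(np.abs(d1)) > 0 else np.inf
    ok = np.abs(d1) > thresh
    out[ok] = state.eps_s * d1t[ok] / d1[ok]
    return out
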