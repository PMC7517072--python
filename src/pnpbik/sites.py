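"""Atomic-scale electric and steric potentials at ion binding sites.

Given the fixed point charges of a protein (e.g. from a PQR file), the
electric potential felt by an ion occupying a spherical binding site is the
probe-averaged screened Coulomb sum plus the ion's own Born term

    phi_site = l_B0 [ (1/6) sum_k sum_j q_j / (eps_p(r_j) |c_j - A_k|)
                      + q_site / (eps_b a_site) ]        (kBT/e),

where the A_k are six symmetric points on the site sphere, ``eps_p(r) = 1 +
77 r / (27.7 + r)`` is the distance-dependent dielectric (1 at contact,
bulk-water 78 far away), evaluated at each atom's distance from the site
center, and ``l_B0 = e^2/(4 pi eps0 kB T)`` converts to kBT/e.  The steric
potential of the occupying ion follows from the local void fraction of the
site volume relative to bulk:

    S_site = ln[ (1 - v_ion/V_site) / Gamma_B ].

Free-energy bookkeeping (Delta G per ion between pore and bulk, and the
selectivity Delta Delta G between two ions) completes the module.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .composition import ElectrolyteComposition
from .constants import COULOMB_EV_A, T_DEFAULT, thermal_energy_ev
from .errors import ValidationError

__all__ = [
    "PointChargeSet",
    "BindingSite",
    "dielectric_profile",
    "site_electric_potential",
    "site_steric_potential",
    "free_energy_balance",
    "total_potential_state",
]


@dataclass(frozen=True)
class PointChargeSet:
    """Atomic point charges: positions (N, 3) Å, charges (N,) e, radii (N,) Å."""

    positions: np.ndarray
    charges: np.ndarray
    radii: np.ndarray | None = None
    source: str = "synthetic"

    def __post_init__(self):
        pos = np.atleast_2d(np.asarray(self.positions, dtype=float))
        q = np.atleast_1d(np.asarray(self.charges, dtype=float))
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "charges", q)
        if pos.shape != (len(q), 3):
            raise ValidationError("positions must be (N, 3) matching charges")
        if not (np.all(np.isfinite(pos)) and np.all(np.isfinite(q))):
            raise ValidationError("coordinates and charges must be finite")
        if self.radii is not None:
            object.__setattr__(self, "radii", np.atleast_1d(np.asarray(self.radii, float)))

    def __len__(self):
        return len(self.charges)

    @property
    def total_charge(self) -> float:
        return float(self.charges.sum())


@dataclass(frozen=True)
class BindingSite:
    """Spherical binding site occupied by an ion of radius ``a_site`` (Å) and
    charge ``q_site`` (e), embedded in a cavity of dielectric ``eps_b``.

    ``V_site`` is the volume available to the ion at the site (must exceed
    the ion's own volume); the six probe points sit at ±a_site along the
    coordinate axes through the center.
    """

    center: np.ndarray
    a_site: float
    q_site: float
    V_site: float
    eps_b: float = 3.6
    occupied: bool = True
    name: str = ""

    def __post_init__(self):
        c = np.asarray(self.center, dtype=float).reshape(3)
        object.__setattr__(self, "center", c)
        if self.a_site <= 0 or self.eps_b <= 0:
            raise ValidationError("site radius and cavity dielectric must be > 0")
        if self.V_site <= self.ion_volume:
            raise ValidationError("site volume must exceed the ion volume")

    @property
    def ion_volume(self) -> float:
        return 4.0 / 3.0 * np.pi * self.a_site**3

    @property
    def probe_points(self) -> np.ndarray:
        """Six axis-aligned points on the site sphere, shape (6, 3)."""
        offsets = np.concatenate([np.eye(3), -np.eye(3)]) * self.a_site
        return self.center[None, :] + offsets


def dielectric_profile(r: np.ndarray | float) -> np.ndarray | float:
    """Distance-dependent dielectric eps_p(r) = 1 + 77 r / (27.7 + r).

    1 at r = 0 (no screening at contact), 78 asymptotically (bulk water).
    """
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValidationError("distance must be >= 0")
    out = 1.0 + 77.0 * r / (27.7 + r)
    return out if out.ndim else float(out)


def site_electric_potential(
    charges: PointChargeSet | None,
    site: BindingSite,
    T: float = T_DEFAULT,
    include_born_term: bool = True,
) -> float:
    """Probe-averaged electric potential at the site in kBT/e."""
    lB0 = COULOMB_EV_A / thermal_energy_ev(T)  # vacuum Bjerrum length, Å
    total = 0.0
    if charges is not None and len(charges) > 0:
        r_center = np.linalg.norm(charges.positions - site.center[None, :], axis=1)
        eps = dielectric_profile(r_center)  # per atom, distance to site center
        d = np.linalg.norm(
            charges.positions[:, None, :] - site.probe_points[None, :, :], axis=2
        )  # (N, 6)
        if np.any(d == 0.0):
            raise ValidationError("a charge coincides with a probe point")
        # probe-averaged double sum (1/6) sum_k sum_j q_j / (eps_p(r_j) d_jk)
        total += float(np.sum((charges.charges / eps)[:, None] / d) / d.shape[1])
    if include_born_term:
        total += site.q_site / (site.eps_b * site.a_site)
    return lB0 * total


def site_steric_potential(site: BindingSite, composition: ElectrolyteComposition) -> float:
    """Steric potential S = ln[(1 - v_ion/V_site)/Gamma_B] of the occupying ion."""
    v = site.ion_volume
    if site.V_site <= v:
        raise ValidationError("site over-packed: V_site <= ion volume")
    return float(np.log((1.0 - v / site.V_site) / composition.gamma_bulk))


def free_energy_balance(
    G_pore_by_ion: dict[str, float],
    G_bulk_by_ion: dict[str, float],
) -> tuple[dict[str, float], float]:
    """Per-ion Delta G = G_pore - G_bulk and the selectivity Delta Delta G.

    With exactly two ions {ref, alt} the second return value is
    ``DeltaG(alt) - DeltaG(ref)`` where the reference ion is the one with
    the *lower* Delta G (the favored species); units follow the inputs
    (kcal/mol in the usual workflow).
    """
    if set(G_pore_by_ion) != set(G_bulk_by_ion):
        raise ValidationError("pore and bulk energies must cover the same ions")
    dG = {ion: G_pore_by_ion[ion] - G_bulk_by_ion[ion] for ion in G_pore_by_ion}
    if len(dG) != 2:
        raise ValidationError("selectivity Delta Delta G needs exactly two ions")
    (i1, g1), (i2, g2) = sorted(dG.items(), key=lambda kv: kv[1])
    return dG, g2 - g1


def total_potential_state(
    charges: PointChargeSet | None,
    sites: list[BindingSite],
    composition: ElectrolyteComposition,
    T: float = T_DEFAULT,
) -> list[dict]:
    """Total (electric + steric) potential of each occupied site.

    Ions occupying other sites contribute to each site's electric sum as
    additional point charges (screened by the same distance-dependent
    dielectric).  The total energy of the ion at a site is
    ``q_site * phi_site + S_site`` in kBT; negative totals are classified
    stable.  Raises on overlapping occupied sites.
    """
    occ = [s for s in sites if s.occupied]
    for a in range(len(occ)):
        for b in range(a + 1, len(occ)):
            if np.linalg.norm(occ[a].center - occ[b].center) < occ[a].a_site + occ[b].a_site:
                raise ValidationError(
                    f"occupied sites {a} and {b} overlap geometrically"
                )
    report = []
    for s in occ:
        others = [o for o in occ if o is not s]
        pos = [charges.positions] if charges is not None and len(charges) else []
        q = [charges.charges] if charges is not None and len(charges) else []
        if others:
            pos.append(np.array([o.center for o in others]))
            q.append(np.array([o.q_site for o in others]))
        all_charges = (
            PointChargeSet(np.vstack(pos), np.concatenate(q)) if pos else None
        )
        phi = site_electric_potential(all_charges, s, T=T)
        S = site_steric_potential(s, composition)
        total = s.q_site * phi + S
        report.append({
            "site": s.name,
            "electric_kbt_e": phi,
            "steric": S,
            "total_kbt": total,
            "stable": bool(total < 0.0),
        })
    return report
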