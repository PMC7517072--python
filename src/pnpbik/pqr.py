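"""Reading and writing PQR point-charge files.

PQR is the whitespace-delimited PDB-like format emitted by PDB2PQR: ATOM /
HETATM records whose last two fields are the per-atom partial charge (e)
and radius (Å), preceded by the x, y, z coordinates.  Field widths are not
reliable across generators, so records are token-split: the final five
tokens are (x, y, z, charge, radius).
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np

from .errors import ParseError
from .sites import PointChargeSet

log = logging.getLogger(__name__)

__all__ = ["read_pqr", "write_pqr"]


def read_pqr(path: str | Path) -> PointChargeSet:
    """Parse a PQR file into a :class:`PointChargeSet`.

    Non-ATOM/HETATM lines are ignored; an empty file yields an empty set
    with a warning.  Malformed records raise :class:`ParseError` with the
    line number.
    """
    path = Path(path)
    positions, charges, radii = [], [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line.split()
            if not rec or rec[0] not in ("ATOM", "HETATM"):
                continue
            try:
                x, y, z, q, r = (float(tok) for tok in rec[-5:])
            except (ValueError, IndexError) as exc:
                raise ParseError(f"{path.name}:{lineno}: malformed PQR record") from exc
            positions.append((x, y, z))
            charges.append(q)
            radii.append(r)
    if not charges:
        log.warning("%s: no atoms found", path)
        return PointChargeSet(np.empty((0, 3)), np.empty(0), np.empty(0),
                              source=str(path))
    out = PointChargeSet(np.array(positions), np.array(charges), np.array(radii),
                         source=str(path))
    log.info("%s: %d atoms, total charge %+.4f e", path.name, len(out),
             out.total_charge)
    return out


def write_pqr(path: str | Path, charges: PointChargeSet,
              names: list[str] | None = None, resname: str = "SYN") -> None:
    """Write a point-charge set as a minimal PQR file."""
    path = Path(path)
    radii = charges.radii if charges.radii is not None else np.zeros(len(charges))
    with open(path, "w") as fh:
        for i, ((x, y, z), q, r) in enumerate(
            zip(charges.positions, charges.charges, radii), start=1
        ):
            name = (names[i - 1] if names else "Q")[:4]
            fh.write(
                f"ATOM  {i:5d} {name:<4s} {resname:<4s} {1:4d}    "
                f"{x:10.4f}{y:10.4f}{z:10.4f} {q:10.6f} {r:8.4f}\n"
            )
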