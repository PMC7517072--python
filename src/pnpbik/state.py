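"""Gridded field state of a solved (or candidate) 1D problem."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .composition import ElectrolyteComposition
from .errors import ValidationError


@dataclass
class FieldState:
    """Electric potential, auxiliary density field, concentrations and steric
    state on a 1D grid.

    Units: x in Å, phi in kBT/e, psi in Å^-2 (psi = Laplacian of phi),
    concentrations in Å^-3, gamma and steric dimensionless.
    """

    x: np.ndarray
    phi: np.ndarray
    concentrations: np.ndarray  # shape (K+1, n)
    gamma: np.ndarray
    steric: np.ndarray
    psi: np.ndarray | None = None
    lc: float = 0.0
    eps_s: float = 78.45
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        n = len(self.x)
        for name in ("phi", "gamma", "steric"):
            if len(getattr(self, name)) != n:
                raise ValidationError(f"{name} length does not match grid")
        if self.concentrations.shape[-1] != n:
            raise ValidationError("concentration array does not match grid")

    def concentration_molar(self, composition: ElectrolyteComposition) -> dict[str, np.ndarray]:
        from .constants import molar

        return {name: molar(1.0) * c for name, c in zip(composition.names, self.concentrations)}
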