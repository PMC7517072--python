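import numpy as np
import pytest

from pnpbik.composition import make_composition


@pytest.fixture
def nacl_01m():
    """0.1 M NaCl with water, standard radii."""
    return make_composition(
        [("Na+", 1, 0.95, 0.1), ("Cl-", -1, 1.81, 0.1), ("H2O", 0, 1.4, 55.5)]
    )


@pytest.fixture
def bath_nak():
    """0.4 M Na+ / 0.4 M K+ / 0.8 M Cl- / 55.5 M water bath."""
    return make_composition(
        [("Na+", 1, 0.95, 0.4), ("K+", 1, 1.33, 0.4),
         ("Cl-", -1, 1.81, 0.8), ("H2O", 0, 1.4, 55.5)]
    )


@pytest.fixture
def edl_comp():
    """Equal-sized 0.1 M 1:4 electrolyte, uniform steric weights."""
    a = 4.65
    return make_composition(
        [("C+", 1, a, 0.4), ("A4-", -4, a, 0.1), ("H2O", 0, 1.4, 55.5)],
        steric_mode="uniform",
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)
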