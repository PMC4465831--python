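"""Shared fixtures: toy complexes and the converged Brownian umbrella run.

The umbrella dataset (20 windows × 10⁶ steps on the reference double-well
landscape) is the study condition for the free-energy pipeline checks and is
expensive (~30 s), so it is generated once per session.
"""

import numpy as np
import pytest

from coopbind.toy_systems import (
    BDParams,
    DesignedContact,
    PseudoDomain,
    ToyComplexSpec,
    double_well_pmf,
    gen_bd_umbrella,
    gen_ideal_bdna,
)
from coopbind.trajectory_core import RegionSelection

N_UMBRELLA_WINDOWS = 20
UMBRELLA_STEPS = 1_000_000
UMBRELLA_K = 15.0
UMBRELLA_SPAN = (2.75, 5.25)


@pytest.fixture(scope="session")
def reference_pmf():
    return double_well_pmf()


@pytest.fixture(scope="session")
def umbrella_dataset(reference_pmf):
    """Converged Brownian umbrella sampling of the double-well landscape."""
    centers = np.linspace(*UMBRELLA_SPAN, N_UMBRELLA_WINDOWS)
    bd = BDParams(n_steps=UMBRELLA_STEPS, seed=20_240_601)
    return gen_bd_umbrella(reference_pmf,
                           [(c, UMBRELLA_K) for c in centers], bd)


@pytest.fixture(scope="session")
def ideal_duplex():
    return gen_ideal_bdna(ToyComplexSpec(n_basepairs=16))


@pytest.fixture
def duplex_selection():
    return RegionSelection("duplex", residue_range=(1, 16))


def make_contact_spec(persistence: float, seed: int = 0,
                      n_basepairs: int = 10) -> ToyComplexSpec:
    """A duplex plus one pseudo-domain with three designated contacts of a
    common persistence (two to DNA backbone atoms, one to a base atom)."""
    dom = PseudoDomain("domA", "A", n_residues=6, start_resid=1,
                       origin=(19.0, 0.0, 8.0))
    contacts = [
        DesignedContact("c1", ("A", 2, "CB"), ("I", 4, "P"), persistence),
        DesignedContact("c2", ("A", 3, "CB"), ("I", 6, "P"), persistence),
        DesignedContact("c3", ("A", 4, "CB"), ("I", 3, "C4"), persistence),
    ]
    return ToyComplexSpec(n_basepairs=n_basepairs, sequence="ATCGATCGAT",
                          domains=[dom], contacts=contacts, seed=seed)
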