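"""Shared fixtures: canonical torsion sets, small conformers and pools.

Everything is generated programmatically with fixed seeds; no stored
binary fixtures.
"""

import numpy as np
import pytest

from sahens.conformers import (
    DihedralSet,
    Ensemble,
    HelicityProfile,
    build_conformer,
    generate_pool,
)
from sahens.sequence import DREBRIN_SAH_SEQUENCE


def uniform_dihedrals(n, phi, psi, omega=180.0):
    """Backbone-only torsion set with constant phi/psi."""
    return DihedralSet(
        np.r_[np.nan, np.full(n - 1, float(phi))],
        np.full(n, float(psi)),
        np.r_[np.nan, np.full(n - 1, float(omega))],
        [np.empty(0)] * n,
    )


@pytest.fixture(scope="session")
def ideal_helix():
    """20-residue poly-Ala at canonical alpha-helical torsions."""
    return build_conformer("A" * 20, uniform_dihedrals(20, -57.0, -47.0))


@pytest.fixture(scope="session")
def extended_chain():
    """10-residue fully extended poly-Ala chain."""
    return build_conformer("A" * 10, uniform_dihedrals(10, 180.0, 180.0))


@pytest.fixture(scope="session")
def small_pool():
    """Small mixed-helicity pool of the 74-residue construct."""
    profile = HelicityProfile.uniform(74, 0.7)
    return generate_pool(DREBRIN_SAH_SEQUENCE, profile, 12, 1, seed=11)


@pytest.fixture(scope="session")
def tiny_sequence():
    return "GEKARELARKLEEAYRKLEA"


@pytest.fixture(scope="session")
def tiny_pool(tiny_sequence):
    """12-member mixed pool of a 20-residue helical peptide."""
    members = []
    for k, p in enumerate([0.0, 0.2, 0.4, 0.6, 0.8, 1.0] * 2):
        pool = generate_pool(tiny_sequence, HelicityProfile.uniform(20, p),
                             1, 1, seed=100 + k)
        pool[0].provenance["uid"] = f"initial_pool:{k}"
        members.extend(pool.members)
    return Ensemble(members, stage="initial_pool")
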