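"""Shared synthetic fixtures.

Everything is generated at run time by the synthetic_crystal generator; the
session scope keeps the direct-summation structure-factor cost to one
computation per crystal.  The working resolutions (2.2-2.8 A) are chosen so
the TPS diagnostics are fully resolved while the suite stays fast; the
diagnostics themselves are resolution-agnostic.
"""

import numpy as np
import pytest

from helixtps import (
    Atom,
    CrystalModel,
    HelixSpec,
    SpaceGroupOps,
    UnitCell,
    build_aform_duplex,
    calc_structure_factors,
    partition_turns,
    place_in_cell,
    random_atom_structure,
    simulate_reference_pair,
)
from helixtps.synthetic import DSRNA_CELL


@pytest.fixture(scope="session")
def dsrna_pair():
    """Perfect three-turn duplex in the R32:H reference cell + reflections."""
    return simulate_reference_pair("dsRNA-like", seed=1, d_min=2.2)


@pytest.fixture(scope="session")
def hairpin_pair():
    """One-turn control duplex in a tetragonal cell + reflections."""
    return simulate_reference_pair("hairpin-like", seed=1, d_min=2.2)


@pytest.fixture(scope="session")
def random_control():
    """675 equal atoms uniform in P1 — Wilson-statistics control (~1e4 refl)."""
    cell = UnitCell(40.0, 45.0, 50.0)
    model = random_atom_structure(675, cell, seed=5, b_iso=10.0)
    return model, calc_structure_factors(model, d_min=2.66)


@pytest.fixture(scope="session")
def three_copy_set():
    """40 random atoms exactly repeated 3x along z in P1 — perfect TPS, m=3."""
    rng = np.random.default_rng(1)
    base = rng.random((40, 3)) * [1.0, 1.0, 1.0 / 3.0]
    pos = np.concatenate([base, base + [0, 0, 1 / 3], base + [0, 0, 2 / 3]]) % 1.0
    model = CrystalModel(UnitCell(24.0, 26.0, 48.0), SpaceGroupOps("P1"),
                         [Atom("C", p, 1.0, 0.0) for p in pos])
    return model, calc_structure_factors(model, d_min=1.6)


@pytest.fixture(scope="session")
def asu_duplex():
    """One-strand asymmetric unit of the 32-bp duplex, with turn partition."""
    frag = build_aform_duplex(HelixSpec(n_bp=32))
    model = place_in_cell(frag, DSRNA_CELL, "R32:H",
                          origin_offset=(0.25, 0.0, 0.0), asu_strand=0)
    partition = partition_turns(model, bp_per_turn=11)
    return model, partition
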