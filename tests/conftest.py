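"""Shared fixtures: small deterministic structures and the 20-member ensemble."""

import numpy as np
import pytest

from hcpesp import (
    Atom,
    SynthSpec,
    build_hierarchy,
    generate_structure,
    generate_vertices,
)

ENSEMBLE_SEEDS = list(range(100, 120))


def make_atom(serial, position, charge, chain="A", resnum=1, radius=1.5):
    return Atom(
        serial=serial,
        name="X",
        residue_name="SYN",
        chain_id=chain,
        residue_number=resnum,
        position=np.asarray(position, dtype=float),
        charge=charge,
        radius=radius,
    )


@pytest.fixture(scope="session")
def small_structure():
    """4 strands x 15 residues x 5 atoms, uniform charges, seed 123."""
    return generate_structure(
        SynthSpec(n_strands=4, residues_per_strand=15, atoms_per_residue=5, seed=123)
    )


@pytest.fixture(scope="session")
def small_vertices(small_structure):
    return generate_vertices(small_structure, 64, seed=5)


@pytest.fixture(scope="session")
def ensemble():
    """20 (structure, vertices) pairs with recorded seeds, 300 atoms each."""
    pairs = []
    for seed in ENSEMBLE_SEEDS:
        spec = SynthSpec(n_strands=4, residues_per_strand=15, atoms_per_residue=5, seed=seed)
        structure = generate_structure(spec)
        pairs.append((structure, generate_vertices(structure, 64, seed=seed)))
    return pairs


@pytest.fixture
def toy_atoms():
    """Two chains x two residues, hand-laid coordinates and charges."""
    return [
        make_atom(1, [0.0, 0.0, 0.0], 0.4, chain="A", resnum=1),
        make_atom(2, [1.0, 0.0, 0.0], -0.1, chain="A", resnum=1),
        make_atom(3, [4.0, 0.0, 0.0], 0.2, chain="A", resnum=2),
        make_atom(4, [0.0, 5.0, 0.0], -0.3, chain="B", resnum=1),
        make_atom(5, [1.0, 5.0, 0.0], 0.25, chain="B", resnum=2),
        make_atom(6, [2.0, 5.0, 0.0], 0.15, chain="B", resnum=2),
    ]


@pytest.fixture
def toy_structure(toy_atoms):
    return build_hierarchy(toy_atoms)
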