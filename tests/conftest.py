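"""Shared fixtures: random trees, random vector sets, a tiny PDB file."""

from __future__ import annotations

import random

import dendropy
import numpy as np
import pytest

from coevo3d.phylodist import (
    SpeciesPairVector,
    assemble_vector_set,
    family_tree_from_dendropy,
)


def random_family_tree(n_leaves: int, seed: int, unit_id: str = "unit"):
    """A pure-birth tree with exponential branch lengths and standard labels."""
    from dendropy.model import birthdeath

    tree = birthdeath.birth_death_tree(
        birth_rate=1.0,
        death_rate=0.0,
        num_extant_tips=n_leaves,
        rng=random.Random(seed),
    )
    for i, leaf in enumerate(tree.leaf_node_iter()):
        leaf.taxon.label = f"{i + 1}_sp{i:03d}"
    return family_tree_from_dendropy(tree, unit_id=unit_id)


def random_vector_set(
    n_units: int,
    n_species: int,
    seed: int,
    missing_frac: float = 0.0,
):
    """A vector set of positive random distances with optional random masks."""
    rng = np.random.default_rng(seed)
    species = [f"sp{i:02d}" for i in range(n_species)]
    import itertools

    pairs = sorted(itertools.combinations(species, 2))
    vectors = []
    for u in range(n_units):
        present = rng.random(len(pairs)) >= missing_frac
        values = np.where(present, rng.uniform(0.1, 5.0, len(pairs)), np.nan)
        vectors.append(
            SpeciesPairVector(
                unit_id=f"u{u:02d}", pairs=pairs, values=values, present=present
            )
        )
    return assemble_vector_set(
        vectors, min_vector_count=1, min_units_per_species=1, min_shared_species=2
    )


@pytest.fixture
def tiny_pdb(tmp_path):
    """Three chains with hand-placed CB/CA atoms (synthetic structure).

    Chain A: two ALA residues, CB at (0,0,0) and (2,0,0) -> center (1,0,0).
    Chain B: two GLY residues, CA at (0,0,0) and (2,0,0) -> center (1,0,0)
             via the CA-for-glycine rule.
    Chain C: one ALA residue, CB at (1,2,3) -> center (1,2,3).
    A water (HOH) and a CB-less ALA (CA fallback) exercise the edge rules.
    """

    def atom(serial, name, resname, chain, resseq, x, y, z, element):
        return (
            f"ATOM  {serial:5d} {name:^4s} {resname:3s} {chain}{resseq:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00          {element:>2s}"
        )

    lines = [
        atom(1, "CA", "ALA", "A", 1, 0.5, 0.0, 0.0, "C"),
        atom(2, "CB", "ALA", "A", 1, 0.0, 0.0, 0.0, "C"),
        atom(3, "CA", "ALA", "A", 2, 1.5, 0.0, 0.0, "C"),
        atom(4, "CB", "ALA", "A", 2, 2.0, 0.0, 0.0, "C"),
        atom(5, "CA", "GLY", "B", 1, 0.0, 0.0, 0.0, "C"),
        atom(6, "CA", "GLY", "B", 2, 2.0, 0.0, 0.0, "C"),
        atom(7, "CA", "ALA", "C", 1, 9.0, 9.0, 9.0, "C"),
        atom(8, "CB", "ALA", "C", 1, 1.0, 2.0, 3.0, "C"),
        # CB-less ALA in chain D: falls back to CA
        atom(9, "CA", "ALA", "D", 1, 4.0, 4.0, 4.0, "C"),
        "HETATM   10  O   HOH A 901       9.000   9.000   9.000  1.00  0.00           O",
        "END",
    ]
    path = tmp_path / "tiny.pdb"
    path.write_text("\n".join(lines) + "\n")
    return path
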