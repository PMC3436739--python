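"""Per-family gene trees and species-level patristic distance vectors.

The mirror-tree method starts from one phylogenetic tree per protein
family (here: per subunit or assembly factor of a complex).  Each tree is
reduced to a vector of *patristic distances* — the sum of branch lengths
(substitutions/site) along the path between every pair of species.  This
module reads the trees, extracts those vectors, and assembles them onto a
single canonical species-pair index with the coverage filters used for
respiratory complex I:

* a species is kept only if it occurs in at least ``min_units_per_species``
  family trees (default 8), so that every retained species informs a
  substantial part of the complex;
* a species pair is kept only if it is present in at least
  ``min_vector_count`` vectors (default 5);
* family pairs sharing fewer than ``min_shared_species`` species
  (default 15) are flagged with a warning because their correlation rests
  on few observations.

Missing pairs are represented by an explicit ``present`` mask, never by a
zero — zero is a valid distance.
"""

from __future__ import annotations

import itertools
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_LEAF_PATTERN",
    "FamilyTree",
    "SpeciesPairVector",
    "VectorSet",
    "read_family_tree",
    "patristic_distances",
    "assemble_vector_set",
    "vectors_from_manifest",
    "write_long_table",
    "read_long_table",
]

#: Default species-extraction rule: everything after the first underscore
#: of the leaf label (labels of the form ``<id>_<species>``).
DEFAULT_LEAF_PATTERN = r"^[^_]+_(.+)$"


def _canonical_pair(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


@dataclass
class FamilyTree:
    """A per-family gene tree with a leaf-label → species mapping.

    Branch lengths are in substitutions/site.  After ortholog selection
    each species is represented by at most one leaf; duplicates are an
    error.  Trees intended for the full pipeline should have >= 4 leaves,
    though smaller trees parse fine for inspection.
    """

    unit_id: str
    tree: dendropy.Tree
    leaf_to_species: dict[str, str]

    @property
    def species(self) -> frozenset[str]:
        return frozenset(self.leaf_to_species.values())

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_to_species)


@dataclass
class SpeciesPairVector:
    """One family's patristic distances indexed by unordered species pair.

    ``pairs`` is sorted canonically (lexicographic on species ids);
    ``present[i]`` says whether ``values[i]`` is an observed distance
    (absent entries hold NaN).
    """

    unit_id: str
    pairs: list[tuple[str, str]]
    values: np.ndarray
    present: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.present = np.asarray(self.present, dtype=bool)
        if self.values.shape != self.present.shape or self.values.ndim != 1:
            raise ValueError("values/present must be 1-D arrays of equal length")
        if len(self.pairs) != self.values.size:
            raise ValueError("pair index and values disagree in length")
        obs = self.values[self.present]
        if obs.size and (not np.all(np.isfinite(obs)) or np.any(obs < 0)):
            raise ValueError(f"{self.unit_id}: distances must be finite and >= 0")

    @property
    def species(self) -> set[str]:
        out: set[str] = set()
        for (a, b), ok in zip(self.pairs, self.present):
            if ok:
                out.add(a)
                out.add(b)
        return out

    def as_dict(self) -> dict[tuple[str, str], float]:
        return {
            p: v for p, v, ok in zip(self.pairs, self.values, self.present) if ok
        }


@dataclass
class VectorSet:
    """Patristic distance vectors of all units on one common pair index."""

    unit_ids: list[str]
    pairs: list[tuple[str, str]]
    values: np.ndarray  # (n_units, n_pairs), NaN where absent
    present: np.ndarray  # (n_units, n_pairs) bool
    species_universe: list[str]
    merge_map: dict[str, list[str]] = field(default_factory=dict)

    @property
    def n_units(self) -> int:
        return len(self.unit_ids)

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def vector(self, unit_id: str) -> SpeciesPairVector:
        i = self.unit_ids.index(unit_id)
        return SpeciesPairVector(
            unit_id, self.pairs, self.values[i].copy(), self.present[i].copy()
        )


def read_family_tree(
    path: str | Path,
    leaf_pattern: str = DEFAULT_LEAF_PATTERN,
    unit_id: str | None = None,
) -> FamilyTree:
    """Read a Newick/NHX tree file into a :class:`FamilyTree`.

    ``leaf_pattern`` is a regular expression whose first capture group
    extracts the species token from each leaf label.  NHX annotations
    (bracketed comments) are ignored beyond topology and branch lengths.
    Negative branch lengths — which some tree programs emit as numerical
    artifacts — are clamped to 0 with a warning.

    Raises ``ValueError`` on an unparseable file, a leaf whose label does
    not match ``leaf_pattern``, or two leaves mapping to the same species.
    """
    path = Path(path)
    if unit_id is None:
        unit_id = path.stem
    try:
        tree = dendropy.Tree.get(
            path=str(path), schema="newick", preserve_underscores=True
        )
    except Exception as exc:  # dendropy raises several parser error types
        raise ValueError(f"{path}: cannot parse as Newick/NHX: {exc}") from exc
    return family_tree_from_dendropy(tree, leaf_pattern=leaf_pattern, unit_id=unit_id)


def family_tree_from_dendropy(
    tree: dendropy.Tree,
    leaf_pattern: str = DEFAULT_LEAF_PATTERN,
    unit_id: str = "unit",
) -> FamilyTree:
    """Wrap an in-memory dendropy tree, applying the species-extraction rule."""
    rx = re.compile(leaf_pattern)
    leaf_to_species: dict[str, str] = {}
    n_clamped = 0
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            edge.length = 0.0
            n_clamped += 1
    if n_clamped:
        warnings.warn(
            f"{unit_id}: clamped {n_clamped} negative branch length(s) to 0",
            stacklevel=2,
        )
    for leaf in tree.leaf_node_iter():
        label = leaf.taxon.label if leaf.taxon is not None else None
        if label is None:
            raise ValueError(f"{unit_id}: leaf without a label")
        m = rx.search(label)
        if m is None or not m.groups():
            raise ValueError(
                f"{unit_id}: leaf label {label!r} does not match pattern "
                f"{rx.pattern!r}"
            )
        species = m.group(1)
        if species in leaf_to_species.values():
            raise ValueError(f"{unit_id}: duplicate species {species!r}")
        leaf_to_species[label] = species
    if len(leaf_to_species) < 2:
        raise ValueError(f"{unit_id}: tree has fewer than 2 leaves")
    return FamilyTree(unit_id=unit_id, tree=tree, leaf_to_species=leaf_to_species)


def patristic_distances(ft: FamilyTree) -> SpeciesPairVector:
    """Extract the vector of species-pair patristic distances from a tree.

    The distance of a pair is the sum of branch lengths on the unique path
    between the two leaves; it does not depend on root placement.
    """
    pdm = ft.tree.phylogenetic_distance_matrix()
    taxon_of = {
        leaf.taxon.label: leaf.taxon for leaf in ft.tree.leaf_node_iter()
    }
    species_to_taxon = {
        sp: taxon_of[label] for label, sp in ft.leaf_to_species.items()
    }
    species = sorted(species_to_taxon)
    pairs = [
        _canonical_pair(a, b) for a, b in itertools.combinations(species, 2)
    ]
    values = np.array(
        [
            pdm.patristic_distance(species_to_taxon[a], species_to_taxon[b])
            for a, b in pairs
        ],
        dtype=float,
    )
    return SpeciesPairVector(
        unit_id=ft.unit_id,
        pairs=pairs,
        values=values,
        present=np.ones(len(pairs), dtype=bool),
    )


def assemble_vector_set(
    vectors: list[SpeciesPairVector],
    min_vector_count: int = 5,
    min_units_per_species: int = 8,
    min_shared_species: int = 15,
    merge_map: dict[str, list[str]] | None = None,
) -> VectorSet:
    """Join per-family vectors onto one filtered canonical pair index.

    Species occurring in fewer than ``min_units_per_species`` units are
    dropped first; then species pairs present in fewer than
    ``min_vector_count`` vectors are dropped.  Unit pairs sharing fewer
    than ``min_shared_species`` species trigger a warning (not an error).
    """
    if len(vectors) < 2:
        raise ValueError("need at least 2 vectors")
    unit_ids = [v.unit_id for v in vectors]
    if len(set(unit_ids)) != len(unit_ids):
        raise ValueError("duplicate unit_ids in vector list")

    species_sets = {v.unit_id: v.species for v in vectors}
    counts: dict[str, int] = {}
    for sp_set in species_sets.values():
        for sp in sp_set:
            counts[sp] = counts.get(sp, 0) + 1
    retained = {sp for sp, c in counts.items() if c >= min_units_per_species}

    pair_counts: dict[tuple[str, str], int] = {}
    for v in vectors:
        for (a, b), ok in zip(v.pairs, v.present):
            if ok and a in retained and b in retained:
                key = _canonical_pair(a, b)
                pair_counts[key] = pair_counts.get(key, 0) + 1
    pairs = sorted(p for p, c in pair_counts.items() if c >= min_vector_count)
    if not pairs:
        raise ValueError("empty pair index after filtering")
    pair_pos = {p: i for i, p in enumerate(pairs)}

    n_units, n_pairs = len(vectors), len(pairs)
    values = np.full((n_units, n_pairs), np.nan)
    present = np.zeros((n_units, n_pairs), dtype=bool)
    for i, v in enumerate(vectors):
        for (a, b), val, ok in zip(v.pairs, v.values, v.present):
            if not ok:
                continue
            j = pair_pos.get(_canonical_pair(a, b))
            if j is not None:
                values[i, j] = val
                present[i, j] = True

    shared_species = {sp for a, b in pairs for sp in (a, b)}
    low = []
    for ua, ub in itertools.combinations(unit_ids, 2):
        n_shared = len(
            species_sets[ua] & species_sets[ub] & shared_species
        )
        if n_shared < min_shared_species:
            low.append((ua, ub, n_shared))
    if low:
        listing = "; ".join(f"{a}-{b}: {n}" for a, b, n in low[:20])
        warnings.warn(
            f"{len(low)} unit pair(s) share fewer than {min_shared_species} "
            f"species: {listing}",
            stacklevel=2,
        )

    return VectorSet(
        unit_ids=unit_ids,
        pairs=pairs,
        values=values,
        present=present,
        species_universe=sorted(shared_species),
        merge_map=dict(merge_map or {}),
    )


def vectors_from_manifest(
    manifest: str | Path, leaf_pattern: str = DEFAULT_LEAF_PATTERN
) -> list[SpeciesPairVector]:
    """Read a two-column (unit_id, tree path) manifest and extract vectors.

    Relative tree paths are resolved against the manifest's directory.
    """
    manifest = Path(manifest)
    out = []
    for line in manifest.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        unit_id, rel = line.split("\t")
        tree_path = Path(rel)
        if not tree_path.is_absolute():
            tree_path = manifest.parent / tree_path
        ft = read_family_tree(tree_path, leaf_pattern=leaf_pattern, unit_id=unit_id)
        out.append(patristic_distances(ft))
    return out


def write_long_table(vs: VectorSet, path: str | Path) -> None:
    """Write the vector set as a long-format TSV (unit, species_a, species_b, distance)."""
    rows = []
    for i, unit in enumerate(vs.unit_ids):
        for j, (a, b) in enumerate(vs.pairs):
            if vs.present[i, j]:
                rows.append((unit, a, b, vs.values[i, j]))
    pd.DataFrame(
        rows, columns=["unit", "species_a", "species_b", "distance"]
    ).to_csv(path, sep="\t", index=False)


def read_long_table(path: str | Path) -> list[SpeciesPairVector]:
    """Read a long-format distance table back into per-unit vectors."""
    df = pd.read_csv(path, sep="\t")
    out = []
    for unit, grp in df.groupby("unit", sort=True):
        d = {
            _canonical_pair(a, b): float(v)
            for a, b, v in zip(grp["species_a"], grp["species_b"], grp["distance"])
        }
        pairs = sorted(d)
        values = np.array([d[p] for p in pairs])
        out.append(
            SpeciesPairVector(
                unit_id=str(unit),
                pairs=pairs,
                values=values,
                present=np.ones(len(pairs), dtype=bool),
            )
        )
    return out
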