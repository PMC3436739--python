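"""Per-subunit center coordinates from a reference crystal structure.

The reference topology of a complex is the set of its subunit centers,
approximated as the unweighted mean of the C-beta coordinates of each
subunit's residues (C-alpha for glycine, and C-alpha as fallback when
C-beta is missing from the model; the number of fallbacks is reported).
A chain → unit mapping table ties structure chains to the unit names used
on the evolutionary side; several chains may map to one unit, in which
case their residues are pooled before averaging (a merged unit's center is
the residue-count-weighted mean, closest to a mass-center approximation).

Only the first model of the structure is read; hetero-residues and waters
are skipped; for disordered atoms the highest-occupancy altloc is used.

An example chain map for the *T. thermophilus* complex I structure
(PDB 3M9S) ships as package data (``data/3m9s_chain_map.tsv``); its chain
IDs are a documented example that should be verified against the local
copy of the structure file.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.PDB import PDBParser
from scipy.spatial.distance import cdist

__all__ = [
    "ReferenceTopology",
    "subunit_centers",
    "physical_distances",
    "read_chain_map",
    "example_chain_map_path",
    "write_topology_tsv",
    "read_topology_tsv",
    "write_pseudo_pdb",
]


@dataclass
class ReferenceTopology:
    """Per-unit 3D centers (Angstrom) plus provenance of the mapping used."""

    unit_ids: list[str]
    centers: np.ndarray  # (n, 3)
    source: str = ""
    n_cb_fallbacks: int = 0

    def __post_init__(self) -> None:
        self.centers = np.asarray(self.centers, dtype=float)
        if self.centers.shape != (len(self.unit_ids), 3):
            raise ValueError("centers must be (n_units, 3)")
        if not np.all(np.isfinite(self.centers)):
            raise ValueError("centers must be finite")
        if len(set(self.unit_ids)) != len(self.unit_ids):
            raise ValueError("unit_ids must be unique")

    def subset(self, units: list[str]) -> "ReferenceTopology":
        idx = [self.unit_ids.index(u) for u in units]
        return ReferenceTopology(
            list(units), self.centers[idx], source=self.source,
            n_cb_fallbacks=self.n_cb_fallbacks,
        )


def _residue_center_atom(residue):
    """C-beta coordinate, C-alpha for glycine or when C-beta is absent."""
    if residue.get_resname().strip() == "GLY":
        if "CA" in residue:
            return residue["CA"].get_coord(), False
        return None, False
    if "CB" in residue:
        return residue["CB"].get_coord(), False
    if "CA" in residue:
        return residue["CA"].get_coord(), True
    return None, False


def subunit_centers(
    structure_path: str | Path,
    chain_map: dict[str, str],
    merges: dict[str, list[str]] | None = None,
) -> ReferenceTopology:
    """Compute per-unit centers from a PDB file and a chain → unit mapping.

    ``merges`` optionally pools already-mapped units into a merged unit
    (e.g. three neighboring subunits treated as one); residues of all
    members are pooled before averaging.
    """
    structure_path = Path(structure_path)
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure(structure_path.stem, str(structure_path))
    model = next(structure.get_models())  # first model only
    chains = {c.id: c for c in model.get_chains()}

    unit_coords: dict[str, list[np.ndarray]] = {}
    n_fallbacks = 0
    for chain_id, unit in chain_map.items():
        if chain_id not in chains:
            raise ValueError(
                f"chain {chain_id!r} (unit {unit!r}) absent from "
                f"{structure_path.name}"
            )
        coords = []
        for residue in chains[chain_id]:
            if residue.id[0] != " ":  # hetero / water
                continue
            xyz, fb = _residue_center_atom(residue)
            if xyz is None:
                continue
            n_fallbacks += int(fb)
            coords.append(np.asarray(xyz, dtype=float))
        if not coords:
            raise ValueError(
                f"chain {chain_id!r} has no usable residues in "
                f"{structure_path.name}"
            )
        unit_coords.setdefault(unit, []).extend(coords)

    if merges:
        for merged, members in merges.items():
            pooled: list[np.ndarray] = []
            for m in members:
                if m not in unit_coords:
                    raise ValueError(f"merge member {m!r} not among mapped units")
                pooled.extend(unit_coords.pop(m))
            unit_coords[merged] = pooled

    unit_ids = sorted(unit_coords)
    centers = np.array([np.mean(unit_coords[u], axis=0) for u in unit_ids])
    return ReferenceTopology(
        unit_ids=unit_ids,
        centers=centers,
        source=f"{structure_path.name} ({len(chain_map)} mapped chains)",
        n_cb_fallbacks=n_fallbacks,
    )


def physical_distances(topology: ReferenceTopology) -> np.ndarray:
    """Euclidean inter-center distance matrix in Angstrom."""
    return cdist(topology.centers, topology.centers)


def read_chain_map(path: str | Path) -> dict[str, str]:
    """Two-column (chain, unit) tab-delimited table; '#' lines are comments."""
    out: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        chain, unit = line.split("\t")
        out[chain] = unit
    return out


def example_chain_map_path() -> Path:
    """Path of the shipped example chain map for PDB 3M9S."""
    return Path(__file__).parent / "data" / "3m9s_chain_map.tsv"


def write_topology_tsv(topology: ReferenceTopology, path: str | Path) -> None:
    pd.DataFrame(
        topology.centers, index=topology.unit_ids, columns=["x", "y", "z"]
    ).rename_axis("unit").to_csv(path, sep="\t")


def read_topology_tsv(path: str | Path) -> ReferenceTopology:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ReferenceTopology(
        unit_ids=[str(i) for i in df.index],
        centers=df[["x", "y", "z"]].to_numpy(dtype=float),
        source=str(path),
    )


def write_pseudo_pdb(
    path: str | Path, unit_ids: list[str], coords: np.ndarray
) -> None:
    """One HETATM per unit center, for viewing in molecular-graphics tools.

    Coordinates are written as-is; unit names are truncated to three
    characters for the residue-name field and numbered sequentially.
    """
    coords = np.asarray(coords, dtype=float)
    lines = []
    for i, (unit, (x, y, z)) in enumerate(zip(unit_ids, coords), start=1):
        res = unit[:3].upper().ljust(3)
        lines.append(
            f"HETATM{i:5d}  C   {res} A{i:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C"
        )
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")
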