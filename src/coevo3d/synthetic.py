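"""Synthetic benchmark generator: ground truth, noisy dissimilarities, trees.

The generator produces the three kinds of inputs the pipeline consumes so
every stage — and the end-to-end chain — is testable without downloads.

* :func:`make_configuration` builds an L-shaped ground-truth arrangement
  of unit centers: two perpendicular arms meeting at a corner, mimicking
  the matrix-arm/membrane-arm geometry of respiratory complex I.
* :func:`noisy_dissimilarities` emulates the empirically observed linear
  relation between physical distance and co-evolutionary dissimilarity:
  ``d_ij = clip(intercept + slope * |x_i - x_j| + noise, 0, inf)``,
  rescaled to [0, 1].
* :func:`simulate_rate_correlated_trees` is a generative stand-in for the
  mirror-tree signal itself: one pure-birth species tree, and per unit a
  tree of identical topology whose branch ``e`` has length
  ``base(e) * exp(z_u(e))``, where the per-branch rate-multiplier vectors
  ``z(e)`` are multivariate normal with covariance
  ``sigma_rate^2 * exp(-|x_u - x_v| / corr_length)`` — evolutionary rates
  of physically close units co-vary, and the correlation decays with
  distance.  This lognormal/exponential-decay model is the simplest one
  producing the distance-dependent rate correlation the method detects;
  it is a modeling choice of this package, with every parameter exposed.

All generators are deterministic given their seed.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from pathlib import Path

import dendropy
import numpy as np
from scipy.spatial.distance import cdist

from .embedding import DissimilarityMatrix
from .phylodist import FamilyTree, family_tree_from_dendropy
from .structure_ref import ReferenceTopology, write_topology_tsv

__all__ = [
    "GroundTruth",
    "RateSimulationParams",
    "make_configuration",
    "noisy_dissimilarities",
    "simulate_rate_correlated_trees",
    "write_benchmark",
]


@dataclass
class GroundTruth:
    """A known 3D configuration of unit centers with arm membership."""

    unit_ids: list[str]
    configuration: np.ndarray  # (n, 3)
    geometry: str
    arms: dict[str, list[str]]  # arm name -> unit ids (arms share the corner)
    corner_id: str

    def __post_init__(self) -> None:
        self.configuration = np.asarray(self.configuration, dtype=float)
        if len(self.unit_ids) < 4:
            raise ValueError("need >= 4 units")
        if not np.all(np.isfinite(self.configuration)):
            raise ValueError("coordinates must be finite")

    def distances(self) -> np.ndarray:
        return cdist(self.configuration, self.configuration)

    def as_topology(self) -> ReferenceTopology:
        return ReferenceTopology(
            unit_ids=list(self.unit_ids),
            centers=self.configuration.copy(),
            source=f"synthetic:{self.geometry}",
        )

    def arm_of(self, unit_id: str) -> str:
        """Arm membership for separation statistics; the corner counts as arm1."""
        for arm in ("arm1", "arm2"):
            if unit_id in self.arms[arm] and (
                unit_id != self.corner_id or arm == "arm1"
            ):
                return arm
        raise KeyError(unit_id)


@dataclass
class RateSimulationParams:
    """Knobs of the rate-correlated tree generator.

    ``n_species``: extant tips of the pure-birth species tree.
    ``birth_rate``: per-lineage speciation rate (1/time).
    ``sigma_rate``: lognormal sd of the per-branch rate multipliers.
    ``corr_length``: distance scale of the rate-correlation decay, in the
    ground truth's coordinate units.
    ``dropout``: per-(unit, species) probability of a missing ortholog.
    """

    n_species: int = 60
    birth_rate: float = 1.0
    sigma_rate: float = 0.5
    corr_length: float = 2.0
    seed: int = 0
    dropout: float = 0.0

    def __post_init__(self) -> None:
        if self.n_species < 4 or self.birth_rate <= 0:
            raise ValueError("n_species >= 4 and birth_rate > 0 required")
        if self.sigma_rate < 0 or self.corr_length <= 0:
            raise ValueError("sigma_rate >= 0 and corr_length > 0 required")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must lie in [0, 1)")


def make_configuration(
    n_arm1: int = 7,
    n_arm2: int = 5,
    spacing: float = 1.0,
    jitter: float = 0.0,
    seed: int = 0,
) -> GroundTruth:
    """L-shaped ground truth: two perpendicular arms of equally spaced points.

    Arm 1 runs along +x starting at the corner (the origin); arm 2 runs
    along +y.  The corner point belongs to both arms (it is the single
    shared point) and is listed once, as the first unit of arm 1.
    Gaussian jitter of the given sd is added to every coordinate.
    """
    if n_arm1 + n_arm2 < 4:
        raise ValueError("need >= 4 units in total")
    rng = np.random.default_rng(seed)
    ids1 = [f"A{i + 1}" for i in range(n_arm1)]
    ids2 = [f"B{j + 1}" for j in range(n_arm2)]
    pts1 = np.array([[i * spacing, 0.0, 0.0] for i in range(n_arm1)])
    pts2 = np.array([[0.0, j * spacing, 0.0] for j in range(1, n_arm2 + 1)])
    coords = np.vstack([pts1, pts2])
    if jitter > 0:
        coords = coords + rng.normal(0.0, jitter, size=coords.shape)
    return GroundTruth(
        unit_ids=ids1 + ids2,
        configuration=coords,
        geometry="L-shape",
        arms={"arm1": ids1, "arm2": [ids1[0]] + ids2},
        corner_id=ids1[0],
    )


def noisy_dissimilarities(
    truth: GroundTruth,
    intercept: float = 0.1,
    slope: float = 1.0,
    noise_sd: float = 0.05,
    seed: int = 0,
) -> DissimilarityMatrix:
    """Dissimilarities as a noisy affine function of inter-unit distance."""
    if slope <= 0:
        raise ValueError("slope must be > 0")
    rng = np.random.default_rng(seed)
    dist = truth.distances()
    n = dist.shape[0]
    iu = np.triu_indices(n, 1)
    raw = intercept + slope * dist[iu]
    if noise_sd > 0:
        raw = raw + rng.normal(0.0, noise_sd, size=raw.size)
    raw = np.clip(raw, 0.0, None)
    d = np.zeros((n, n))
    d[iu] = raw
    d = d + d.T
    mx = d.max()
    if mx > 0:
        d = d / mx
    return DissimilarityMatrix(unit_ids=list(truth.unit_ids), d=d)


def _species_tree(params: RateSimulationParams) -> dendropy.Tree:
    from dendropy.model import birthdeath

    tree = birthdeath.birth_death_tree(
        birth_rate=params.birth_rate,
        death_rate=0.0,
        num_extant_tips=params.n_species,
        rng=random.Random(params.seed),
    )
    for i, leaf in enumerate(tree.leaf_node_iter()):
        leaf.taxon.label = f"{i + 1}_sp{i:03d}"
    return tree


def simulate_rate_correlated_trees(
    truth: GroundTruth, params: RateSimulationParams
) -> list[FamilyTree]:
    """One rate-scaled gene tree per unit on a shared pure-birth species tree.

    Per-branch log-rate multipliers across units are multivariate normal
    with exponential spatial covariance, so units close in the ground
    truth accelerate and decelerate together.  With ``dropout`` > 0, each
    unit's tree is thinned by random species removal (at least 4 leaves
    are always kept) to emulate missing orthologs.
    """
    species_tree = _species_tree(params)
    n_units = len(truth.unit_ids)
    edges = [
        e for e in species_tree.preorder_edge_iter() if e.length is not None
    ]
    base = np.array([e.length for e in edges])

    rng = np.random.default_rng(params.seed)
    if params.sigma_rate > 0:
        dist = truth.distances()
        cov = params.sigma_rate**2 * np.exp(-dist / params.corr_length)
        cov[np.diag_indices_from(cov)] += 1e-12
        chol = np.linalg.cholesky(cov)
        Z = rng.standard_normal((len(edges), n_units)) @ chol.T
    else:
        Z = np.zeros((len(edges), n_units))

    all_labels = [leaf.taxon.label for leaf in species_tree.leaf_node_iter()]
    out: list[FamilyTree] = []
    for u, unit_id in enumerate(truth.unit_ids):
        t = species_tree.clone(depth=1)
        for k, e in enumerate(
            e for e in t.preorder_edge_iter() if e.length is not None
        ):
            e.length = base[k] * float(np.exp(Z[k, u]))
        if params.dropout > 0:
            keep_mask = rng.random(len(all_labels)) >= params.dropout
            if keep_mask.sum() < 4:  # never drop below a usable tree
                keep_mask[rng.choice(len(all_labels), 4, replace=False)] = True
            keep = [lab for lab, ok in zip(all_labels, keep_mask) if ok]
            t.retain_taxa_with_labels(keep)
        out.append(family_tree_from_dendropy(t, unit_id=unit_id))
    return out


def write_benchmark(
    outdir: str | Path,
    truth: GroundTruth,
    trees: list[FamilyTree],
) -> Path:
    """Write trees, a manifest, and the ground-truth topology to ``outdir``.

    Returns the manifest path; all files are consumable by the CLI.
    """
    outdir = Path(outdir)
    (outdir / "trees").mkdir(parents=True, exist_ok=True)
    lines = []
    for ft in trees:
        rel = f"trees/{ft.unit_id}.nwk"
        ft.tree.write(path=str(outdir / rel), schema="newick")
        lines.append(f"{ft.unit_id}\t{rel}")
    manifest = outdir / "manifest.tsv"
    manifest.write_text("\n".join(lines) + "\n")
    write_topology_tsv(truth.as_topology(), outdir / "truth_topology.tsv")
    return manifest
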