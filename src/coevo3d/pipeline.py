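"""End-to-end orchestration: trees → correlations → embedding → validation.

`run` executes the full chain from a config: read per-family trees, build
the filtered vector set, remove the shared phylogeny, correlate, embed
each configured unit subset by cMDS, and — when a reference structure is
configured — superimpose and score the result.  Every numeric output in
the report is accompanied by the policy flags that produced it
(eigenvalue policy, rmsd denominator, reflection allowance) and a
provenance block (input hashes, seeds, package version), so a rerun with
the same config is byte-identical.

`benchmark_replicate` / `run_benchmark` drive the same chain on the
synthetic L-shape generator for calibration and testing.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .embedding import (
    DissimilarityMatrix,
    classical_mds,
    permutation_null,
    to_dissimilarity,
)
from .mirror_tree import (
    coevolution_matrix,
    read_matrix_tsv,
    reference_vector,
    write_matrix_tsv,
)
from .phylodist import (
    DEFAULT_LEAF_PATTERN,
    assemble_vector_set,
    vectors_from_manifest,
    write_long_table,
)
from .structure_ref import (
    ReferenceTopology,
    physical_distances,
    read_chain_map,
    read_topology_tsv,
    subunit_centers,
    write_pseudo_pdb,
    write_topology_tsv,
)
from .superposition import (
    axis_correlations,
    distance_agreement,
    pca_reorient,
    procrustes_fit,
)
from .synthetic import (
    GroundTruth,
    RateSimulationParams,
    make_configuration,
    simulate_rate_correlated_trees,
)

__all__ = ["RunConfig", "run", "benchmark_replicate", "run_benchmark"]


@dataclass
class RunConfig:
    """Declarative description of one pipeline run (see ``examples`` in docs)."""

    tree_manifest: str
    leaf_pattern: str = DEFAULT_LEAF_PATTERN
    merges: dict[str, list[str]] = field(default_factory=dict)
    min_vector_count: int = 5
    min_units_per_species: int = 8
    min_shared_species: int = 15
    k: int = 3
    rescale: bool = True
    subset_rescale: bool = False  # rescale each subset's slice to max 1
    eigenvalue_policy: str = "positive"
    reference_structure: str | None = None  # PDB file
    reference_chain_map: str | None = None
    reference_topology: str | None = None  # precomputed centers TSV
    allow_reflection: bool = True
    allow_scale: bool = True
    rmsd_denominator: str = "n"
    n_perm: int = 0
    seed: int = 0
    subsets: dict[str, list[str]] = field(default_factory=dict)
    pseudo_pdb: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)


def _sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _agreement_dict(a) -> dict:
    return {"axis": a.axis, "r_squared": a.r_squared, "p_value": a.p_value, "n": a.n}


def _load_reference(cfg: RunConfig) -> ReferenceTopology | None:
    if cfg.reference_topology:
        return read_topology_tsv(cfg.reference_topology)
    if cfg.reference_structure and cfg.reference_chain_map:
        return subunit_centers(
            cfg.reference_structure,
            read_chain_map(cfg.reference_chain_map),
            merges=cfg.merges or None,
        )
    return None


def run(cfg: RunConfig, outdir: str | Path) -> dict:
    """Execute the full pipeline and write all artifacts under ``outdir``.

    Returns the report dictionary (also written as ``report.json``).
    Any stage failure propagates with the offending unit or pair named.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    vectors = vectors_from_manifest(cfg.tree_manifest, leaf_pattern=cfg.leaf_pattern)
    n_species_in = len({s for v in vectors for s in v.species})
    vs = assemble_vector_set(
        vectors,
        min_vector_count=cfg.min_vector_count,
        min_units_per_species=cfg.min_units_per_species,
        min_shared_species=cfg.min_shared_species,
        merge_map=cfg.merges,
    )
    write_long_table(vs, outdir / "patristic_long.tsv")

    R = coevolution_matrix(vs, reference_vector(vs))
    write_matrix_tsv(outdir / "rho.tsv", R.unit_ids, R.rho)
    write_matrix_tsv(outdir / "n_pairs.tsv", R.unit_ids, R.n_pairs)
    D = to_dissimilarity(R, rescale=cfg.rescale)
    write_matrix_tsv(outdir / "dissimilarity.tsv", D.unit_ids, D.d)

    subsets = dict(cfg.subsets) or {}
    subsets.setdefault("all", list(D.unit_ids))
    for name, units in subsets.items():
        unknown = [u for u in units if u not in D.unit_ids]
        if unknown:
            raise ValueError(f"subset {name!r}: unknown unit(s) {unknown}")

    reference = _load_reference(cfg)
    if reference is not None:
        write_topology_tsv(reference, outdir / "reference_topology.tsv")

    report: dict = {
        "version": __version__,
        "provenance": {
            "tree_manifest": _sha256(cfg.tree_manifest),
            "seed": cfg.seed,
            "eigenvalue_policy": cfg.eigenvalue_policy,
            "rmsd_denominator": cfg.rmsd_denominator,
            "allow_reflection": cfg.allow_reflection,
            "allow_scale": cfg.allow_scale,
            "rescale": cfg.rescale,
            "subset_rescale": cfg.subset_rescale,
        },
        "attrition": {
            "n_units": vs.n_units,
            "n_unit_pairs": vs.n_units * (vs.n_units - 1) // 2,
            "n_species_input": n_species_in,
            "n_species_retained": len(vs.species_universe),
            "n_species_pairs": vs.n_pairs,
        },
        "subsets": {},
    }

    for name, units in subsets.items():
        Dsub = D.subset(units, rescale=cfg.subset_rescale)
        emb = classical_mds(Dsub, k=cfg.k, eigenvalue_policy=cfg.eigenvalue_policy)
        coords_path = outdir / f"coords_{name}.tsv"
        header = "unit\t" + "\t".join(f"x{i + 1}" for i in range(cfg.k))
        rows = [
            u + "\t" + "\t".join(f"{c:.10g}" for c in row)
            for u, row in zip(emb.unit_ids, emb.coordinates)
        ]
        coords_path.write_text(header + "\n" + "\n".join(rows) + "\n")
        np.savetxt(
            outdir / f"eigenvalues_{name}.tsv", emb.eigenvalues, fmt="%.10g"
        )
        entry: dict = {"units": list(units), "p_k": emb.p_k, "k": cfg.k}
        if cfg.pseudo_pdb:
            write_pseudo_pdb(
                outdir / f"coords_{name}.pdb", emb.unit_ids, emb.coordinates
            )
        if cfg.n_perm > 0:
            null = permutation_null(
                Dsub, n_perm=cfg.n_perm, seed=cfg.seed, k=cfg.k,
                eigenvalue_policy=cfg.eigenvalue_policy,
            )
            entry["permutation_null"] = {
                "n_perm": null.n_perm,
                "seed": null.seed,
                "mean": null.mean,
                "sd": null.sd,
                "p_value": null.p_value,
            }
        if reference is not None:
            shared = [u for u in units if u in reference.unit_ids]
            if len(shared) >= 3:
                ref_sub = reference.subset(shared)
                fit = procrustes_fit(
                    emb.unit_ids,
                    emb.coordinates,
                    ref_sub,
                    allow_reflection=cfg.allow_reflection,
                    allow_scale=cfg.allow_scale,
                    rmsd_denominator=cfg.rmsd_denominator,
                )
                frame_ref = pca_reorient(ref_sub.centers)
                frame_fit = pca_reorient(fit.fitted)
                axes = axis_correlations(frame_fit, frame_ref)
                dag = distance_agreement(
                    Dsub.d, physical_distances(ref_sub), Dsub.unit_ids,
                    subset=shared,
                )
                entry["superposition"] = {
                    "rmsd": fit.rmsd,
                    "scale": fit.scale,
                    "reflection_used": fit.reflection_used,
                    "n_units": len(fit.unit_ids),
                    "axis_correlations": [_agreement_dict(a) for a in axes],
                    "distance_agreement": _agreement_dict(dag),
                }
        report["subsets"][name] = entry

    (outdir / "report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True) + "\n"
    )
    return report


def benchmark_replicate(
    seed: int,
    n_arm1: int = 7,
    n_arm2: int = 5,
    spacing: float = 1.0,
    n_species: int = 60,
    sigma_rate: float = 0.5,
    corr_length: float | None = None,
    dropout: float = 0.0,
    k: int = 3,
) -> dict:
    """One synthetic end-to-end run: simulate, infer, validate against truth.

    ``corr_length`` defaults to a third of the first arm's length.  The
    returned dict carries the embedding, the Procrustes fit against the
    ground truth, whether the two arms separate in the embedding
    (between-arm mean embedded distance exceeds within-arm mean), and the
    agreement of inferred dissimilarities with true distances.
    """
    if corr_length is None:
        corr_length = (n_arm1 - 1) * spacing / 3.0
    truth = make_configuration(
        n_arm1=n_arm1, n_arm2=n_arm2, spacing=spacing, jitter=0.0, seed=seed
    )
    params = RateSimulationParams(
        n_species=n_species,
        sigma_rate=sigma_rate,
        corr_length=corr_length,
        seed=seed,
        dropout=dropout,
    )
    trees = simulate_rate_correlated_trees(truth, params)
    from .phylodist import patristic_distances

    vectors = [patristic_distances(t) for t in trees]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        vs = assemble_vector_set(
            vectors,
            min_vector_count=min(5, len(vectors)),
            min_units_per_species=min(8, len(vectors)),
        )
    R = coevolution_matrix(vs)
    D = to_dissimilarity(R)
    emb = classical_mds(D, k=k)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = procrustes_fit(
            emb.unit_ids, emb.coordinates, truth.as_topology()
        )

    arms = np.array([truth.arm_of(u) for u in emb.unit_ids])
    E = emb.embedded_distances()
    iu = np.triu_indices(len(arms), 1)
    same = arms[iu[0]] == arms[iu[1]]
    within = E[iu][same].mean()
    between = E[iu][~same].mean()

    dag = distance_agreement(D.d, truth.distances(), D.unit_ids)
    return {
        "truth": truth,
        "embedding": emb,
        "fit": fit,
        "arms_separated": bool(between > within),
        "between_arm_mean": float(between),
        "within_arm_mean": float(within),
        "distance_agreement": dag,
    }


def run_benchmark(n_replicates: int = 20, base_seed: int = 0, **kwargs) -> dict:
    """Run the L-shape benchmark over replicates; report the separation rate."""
    reps = [
        benchmark_replicate(seed=base_seed + 1000 * r, **kwargs)
        for r in range(n_replicates)
    ]
    n_sep = sum(r["arms_separated"] for r in reps)
    return {
        "replicates": reps,
        "n_separated": n_sep,
        "n_replicates": n_replicates,
        "separation_rate": n_sep / n_replicates,
    }
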