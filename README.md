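# coevo3d

**Quaternary topology of protein complexes from evolutionary rate
correlations.**

Subunits of a stable protein complex evolve under shared constraints: a
substitution in one subunit must be compensated in its neighbors at a
similar rate, so physically close subunits tend to show correlated
evolutionary rates. `coevo3d` turns that signal into a three-dimensional
arrangement of subunit centers and validates it against a reference
crystal structure. It was built around respiratory complex I
(NADH:ubiquinone oxidoreductase) — the L-shaped, ~45-subunit first
complex of oxidative phosphorylation — but the machinery is generic: any
set of per-family phylogenetic trees plus an optional reference structure
will do.

## Method

Given one gene tree per subunit (or assembly factor), the pipeline:

1. **Patristic distance vectors** (`phylodist`). Each tree is reduced to
   a vector *v* of species-pair patristic distances. Coverage filters:
   species in ≥ 8 subunit trees, species pairs in ≥ 5 vectors, and a
   warning for subunit pairs sharing < 15 species.
2. **Phylogeny correction** (`mirror_tree`). All vectors share the
   underlying species phylogeny. A reference vector *p* (the per-pair
   mean over subunits) is projected out:
   *v\** = *v* − (*p*ᵀ*v* / *p*ᵀ*p*) *p*,
   leaving rate residuals orthogonal to the shared signal. Corrected
   vectors are compared by Spearman rank correlation over jointly
   observed pairs, giving the co-evolutionary similarity matrix *r*.
3. **Embedding** (`embedding`). Similarities become dissimilarities,
   *d′* = 1 − *r*, *d* = *d′*/max(*d′*), and classical multidimensional
   scaling embeds *d* in *k* = 3 dimensions via the eigendecomposition of
   *B* = −½ *J D*⁽²⁾ *J*. The goodness of fit
   *P*ₖ = Σᵢ₌₁..ₖ λᵢ / Σᵢ g(λᵢ) plays the role of variance explained;
   whether the matrix is 3D-embeddable at all is calibrated against a
   permutation null (upper-triangle shuffles).
4. **Validation** (`structure_ref`, `superposition`). Reference subunit
   centers are the mean Cβ coordinates (Cα for glycine) per chain of a
   PDB structure. The embedded configuration is fitted onto them by
   similarity Procrustes (rotation, optional reflection, isometric
   scale), scored by rmsd = √(Σ|tᵢ − cᵢ|²/n), per-axis r² after PCA
   reorientation, and distance-vs-distance regressions.

A synthetic benchmark (`synthetic`) generates L-shaped ground truths,
noisy affine dissimilarities, and — the full generative stand-in — gene
trees whose branch-rate multipliers are correlated with covariance
decaying with physical distance, so the entire chain is testable without
any downloads.

## Worked example

Simulate a 12-unit L-shaped complex (two arms of 7 and 5 units) observed
through 60 species, then run the full pipeline against the known truth:

```bash
coevo3d simulate --outdir demo --n-species 60 --seed 1
cd demo
cat > config.yaml <<YAML
tree_manifest: manifest.tsv
reference_topology: truth_topology.tsv
n_perm: 1000
seed: 1
subsets:
  arm1: [A1, A2, A3, A4, A5, A6, A7]
YAML
coevo3d run --config config.yaml --outdir out
```

which prints:

```
[arm1] P_3 = 0.8904, rmsd = 1.49
[all] P_3 = 0.7967, rmsd = 1.712
```

Reading this: the 7-unit arm embeds almost perfectly in 3D
(*P*₃ = 0.89), the full 12-unit matrix still well (*P*₃ = 0.80), and the
Procrustes rmsd values are in the ground truth's coordinate units (arm
spacing 1.0). `out/report.json` additionally records that the full
matrix beats its permutation null (p ≈ 10⁻³; a shuffled matrix embeds at
mean *P*₃ ≈ 0.64), that co-evolutionary dissimilarity explains ~42% of
the variance in true inter-unit distance, and every policy flag
(eigenvalue policy, rmsd denominator, reflection allowance) behind each
number. Stage-wise subcommands (`distances`, `correlate`, `embed`,
`superpose`, `centers`) expose the same steps over TSV interchange
files; an example chain → subunit mapping for the *T. thermophilus*
complex I structure (PDB 3M9S) ships in
`src/coevo3d/data/3m9s_chain_map.tsv`.

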