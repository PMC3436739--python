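# Methods

This note documents the models, numerical choices, and open design
decisions behind `coevo3d`, and what the synthetic benchmark does and
does not establish about real data.

## The mirror-tree model and its correction

The raw signal is the matrix of patristic distances per family: for
family *u* and species pair (*a*, *b*), the sum of branch lengths
(substitutions/site) on the path between the two species' leaves. Every
family evolves inside the same species phylogeny, so raw distance
vectors of any two families correlate strongly no matter whether the
proteins interact. The correction projects each vector *v* onto a
reference *p* and keeps the residual *v\** = *v* − (*p*ᵀ*v*/*p*ᵀ*p*)*p*.
The reference is the per-pair arithmetic mean over families, which has
two consequences worth stating: it removes not only species divergence
times but also the rate covariation common to the *whole* complex, so
the resulting correlations are relative statements among subunits; and
it makes the reference data-derived, so no outgroup calibration is
needed.

**Missing data.** Species coverage is ragged. The projection
coefficients *p*ᵀ*v* and *p*ᵀ*p* are computed over the pairs present in
*v* only. The alternative (full-index products with zero-filling) breaks
the orthogonality contract per vector; the restriction keeps
⟨*v\**, *p*⟩ = 0 exactly on each vector's support, which is the property
the test suite asserts. Correlations between corrected vectors use
pairwise-complete observations, and every cell carries its joint
species-pair count `n_pairs` so low-coverage correlations are auditable.

**Ties and degenerate vectors.** Spearman uses average ranks. A
corrected vector whose norm is below 1e−10 of its raw norm is treated as
exactly zero (it is floating-point residue of a vector parallel to the
reference), and zero-variance vectors yield *undefined* (NaN)
correlations, never 0 — zero would manufacture evidence of independence.
Undefined cells block the dissimilarity transform with an error naming
the offending pair; the caller decides whether to drop units or impute.

**Filters.** Defaults are: species retained if they occur in ≥ 8 family
trees (applied before pair filtering), species pairs retained if present
in ≥ 5 vectors, and a warning (not an error) for family pairs sharing
fewer than 15 species. Raising any threshold only removes index entries
(monotone filtering, property-tested).

## Classical MDS and P_k

Dissimilarities are *d′* = 1 − *r* rescaled by the matrix maximum to
[0, 1]; negative correlations thus count as evidence of distance, not
noise. cMDS double-centers the squared dissimilarities,
*B* = −½ *J D*⁽²⁾ *J*, and takes coordinates from the positive
eigenvalues, X = Q₊Λ₊^{1/2}. If fewer than *k* eigenvalues are positive,
trailing columns are zero-filled with a warning.

The goodness of fit is P_k = Σ_{i≤k} λ_i / Σ_i g(λ_i). For
non-Euclidean input *B* has negative eigenvalues and a denominator
policy is required; the package offers three, recorded in all output
metadata:

* `positive` (default): g(λ) = max(λ, 0). The numerator's axes explain
  positive-definite structure, so the denominator counts only that mass.
* `absolute`: g(λ) = |λ| — penalizes non-Euclideanness itself.
* `raw`: the literal sum of the first n−1 eigenvalues in descending
  order.

Double-centering forces one structural zero eigenvalue; the textbook
formula's sum to n−1 exists to drop it. Since g(0) = 0 under the first
two policies, they sum over all n eigenvalues; only `raw` truncates as
written. P_k is invariant under uniform scaling of D (tested at
c ∈ {0.1, 10}) and monotone non-decreasing in k.

**Sub-model embeddings.** When a subset of units is embedded (an arm, a
conserved core), the slice of the rescaled full matrix and the re-rescaled
slice are both available (`subset(units, rescale=...)`). P_k is
invariant to the choice; raw embedded distances are not. The default is
slicing without re-rescaling.

**Permutation null.** "Is this matrix consistent with a 3D
configuration at all?" is answered by permuting the n(n−1)/2
upper-triangle values uniformly, mirroring to a symmetric zero-diagonal
matrix, and embedding each replicate. This preserves the value multiset
and symmetry while destroying geometry. The p-value uses the +1
correction, p = (1 + #{null ≥ observed})/(1 + n_perm), so it is never
exactly zero. The null mean of P₃ depends on the matrix size *and* on
the value distribution of the particular matrix, so it is reported per
matrix rather than assumed; a single seed drives the generator and is
recorded in the result.

## Reference topology and superposition

Subunit centers are approximated by the unweighted mean of Cβ
coordinates over a chain's residues — Cα for glycine, Cα as fallback
when Cβ is absent from the model (fallback count reported). First model
only, highest-occupancy altlocs, hetero-residues and waters skipped.
Merged units (several chains treated as one subunit) pool residues
before averaging, i.e. residue-count-weighted, which is closest to a
mass-center approximation. The shipped 3M9S chain map pairs the
bacterial Nqo subunits with human complex I units and pools
Nqo7/10/11 into one merged unit whose individual placement the
structure does not resolve; its chain IDs are a documented example to be
verified against the user's copy of the file.

The Procrustes fit centers both configurations, takes the rotation from
the SVD of the cross-covariance *T*ᶜᵀ*C*ᶜ, and applies the optimal
isometric scale. Reflections are allowed by default: cMDS output has
arbitrary chirality, so forbidding reflections would make the rmsd
depend on an arbitrary sign. With reflections disallowed the smallest
singular value's sign is flipped to force det(R) = +1. The rmsd
denominator is n; a flag selects n² for sensitivity analysis against
rmsd conventions that normalize differently. Axis-wise agreement is
computed after PCA reorientation of both configurations (axes by
decreasing variance, signs fixed by largest-magnitude loading); axes
with zero variance — e.g. the third axis of an exactly planar
configuration — are skipped with a warning rather than reported as a
number.

Distance-vs-distance regressions report r², a two-sided t-test p, and
the pair count n. These p-values deliberately ignore the
non-independence of pairs sharing a unit (the convention of the
regressions they reproduce); `mantel_p_value` provides the
permutation-based alternative for statistical hygiene.

## The synthetic benchmark

The generator emulates three layers of the real problem:

* **Geometry**: an L-shape of two perpendicular arms (defaults 7 + 5
  units, spacing 1.0) sharing a corner — the two-arm architecture of
  complex I at cartoon resolution.
* **Phenomenology**: dissimilarities as a noisy affine function of true
  distance (defaults intercept 0.1, slope 1.0, noise sd 0.05), matching
  the observed roughly linear distance/co-evolution relation.
* **Mechanism**: one pure-birth species tree (birth rate 1.0, 60
  species) and per-unit trees with identical topology whose branch *e*
  is scaled by exp(z_u(e)), with per-branch vectors z(e) multivariate
  normal, Σ_uv = σ² exp(−‖x_u − x_v‖/L). Defaults σ = 0.5 and
  L = arm length/3 = 2.0. The lognormal-multiplier /
  exponential-covariance form is the simplest model that yields
  distance-decaying rate correlation; it is this package's modeling
  choice, not an empirical estimate.

Degenerate limits behave as they must: σ = 0 reproduces the species tree
exactly and all corrected vectors vanish; L → ∞ gives one shared rate
process that the reference projection largely absorbs. Optional
per-(unit, species) dropout exercises the missing-data paths.

**What passing the benchmark shows — and does not.** It shows the chain
recovers geometry when rate correlation is actually generated by
distance under the stated model, at realistic problem sizes (12 units,
60 species, 66 correlations). It does not show that real evolutionary
rates follow this generative model: real data add expression-level
covariation, mito/nuclear mutation-pressure differences, supercomplex
contacts, and alignment/tree-inference error, none of which are
simulated. Benchmark success rates are therefore upper bounds on
real-data performance.

Problem sizes in the tests and the acceptance script (20 replicates,
60 species, 10⁴ permutation replicates for the 45-unit null) were chosen
as the package's standard benchmark conditions; all are config-exposed.

## Numerical details

* Eigenvalues within 1e−10 of each other form a degenerate block whose
  coordinates are rotation-arbitrary; tests compare rotation-invariant
  quantities (distances, eigenvalues) in that case.
* Negative branch lengths (tree-program artifacts) are clamped to 0 with
  a warning; zero lengths are accepted.
* Exact-fit regression p-values are clamped to the smallest positive
  float to preserve the p ∈ (0, 1] contract.
* All stochastic components (generators, permutation null) take explicit
  integer seeds and are byte-for-byte reproducible; the pipeline report
  embeds input hashes, seeds, and every policy flag next to the numbers
  they produced.

## Known limitations

* The correlation → dissimilarity transform treats negative rate
  correlation as strong negative evidence of proximity; with few species
  pairs, sampling noise in Spearman correlations maps directly into
  distances.
* The projection removes a single shared component; residual correlations
  can still reflect indirect interactions (no partial-correlation
  deconvolution is attempted).
* Procrustes validation assumes a one-to-one unit matching; units absent
  from the reference are simply excluded from rmsd.
* The mmCIF format is not parsed; convert to PDB first.
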