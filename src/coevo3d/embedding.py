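"""Classical multidimensional scaling of co-evolutionary dissimilarities.

Correlations ``r`` become dissimilarities by ``d' = 1 - r`` (a negative
rate correlation counts as evidence *against* physical proximity) and a
rescale to [0, 1], ``d = d' / max(d')``.  Classical MDS (principal
coordinates) then embeds ``d`` in ``k`` dimensions via the
eigendecomposition of the double-centered squared-dissimilarity matrix

    B = -1/2 J D^(2) J,     J = I - n^{-1} 1 1^T,

with coordinates ``X = Q_+ L_+^{1/2}`` from the largest positive
eigenvalues.  The goodness of fit of the k-dimensional solution is

    P_k = sum_{i<=k} lambda_i / sum_{i=1..n-1} g(lambda_i),

the analog of variance-explained in PCA.  For non-Euclidean input B has
negative eigenvalues and the denominator needs a policy for them:
``positive`` (default) sums positive parts, ``absolute`` sums magnitudes,
``raw`` sums the eigenvalues as written.  The policy in force is carried
in the result metadata.

Whether a dissimilarity matrix is *consistent* with a k-dimensional
configuration at all is calibrated by a permutation null: shuffling the
upper-triangle entries preserves the value multiset and symmetry but
destroys geometric structure, and the observed P_k is compared with the
null distribution of P_k over many such shuffles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, spatial

from .mirror_tree import CoevolutionMatrix

__all__ = [
    "DissimilarityMatrix",
    "EmbeddingResult",
    "PermutationNull",
    "to_dissimilarity",
    "classical_mds",
    "goodness_of_fit",
    "permutation_null",
]

_EIG_POLICIES = ("positive", "absolute", "raw")


@dataclass
class DissimilarityMatrix:
    """Symmetric dissimilarities in [0, 1] with zero diagonal."""

    unit_ids: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.unit_ids)
        if self.d.shape != (n, n):
            raise ValueError("matrix shape must match unit_ids")
        if not np.allclose(self.d, self.d.T, atol=1e-10):
            raise ValueError("dissimilarity matrix must be symmetric")
        if np.any(self.d < -1e-12):
            raise ValueError("dissimilarities must be >= 0")
        if np.any(np.abs(np.diag(self.d)) > 1e-12):
            raise ValueError("diagonal must be 0")

    @property
    def n(self) -> int:
        return len(self.unit_ids)

    def subset(self, units: list[str], rescale: bool = False) -> "DissimilarityMatrix":
        """Slice to ``units``; optionally rescale the slice to max 1."""
        idx = [self.unit_ids.index(u) for u in units]
        d = self.d[np.ix_(idx, idx)].copy()
        if rescale and d.max() > 0:
            d = d / d.max()
        return DissimilarityMatrix(list(units), d)


@dataclass
class EmbeddingResult:
    """cMDS output: coordinates, full eigenvalue spectrum, and P_k."""

    unit_ids: list[str]
    coordinates: np.ndarray  # (n, k), centered at the origin
    eigenvalues: np.ndarray  # all n eigenvalues of B, descending
    p_k: float
    k: int
    eigenvalue_policy: str = "positive"

    def embedded_distances(self) -> np.ndarray:
        """Pairwise Euclidean distances of the embedded points."""
        return spatial.distance.squareform(
            spatial.distance.pdist(self.coordinates)
        )


@dataclass
class PermutationNull:
    """Null distribution of P_k over upper-triangle permutations."""

    n_perm: int
    seed: int
    k: int
    observed: float
    null_p_k: np.ndarray
    mean: float
    sd: float
    p_value: float  # empirical upper tail with the +1 correction
    eigenvalue_policy: str = "positive"


def to_dissimilarity(
    R: CoevolutionMatrix, rescale: bool = True
) -> DissimilarityMatrix:
    """Transform a correlation matrix into dissimilarities.

    ``d' = 1 - rho`` off-diagonal, then (if ``rescale``) ``d = d'/max(d')``
    so the largest dissimilarity is exactly 1.  Any undefined correlation
    cell is an error naming the offending unit pair — the caller must drop
    units or impute first.
    """
    rho = R.rho.copy()
    n = len(R.unit_ids)
    bad = np.argwhere(~np.isfinite(rho) & ~np.eye(n, dtype=bool))
    if bad.size:
        i, j = bad[0]
        raise ValueError(
            f"undefined correlation for unit pair "
            f"({R.unit_ids[i]}, {R.unit_ids[j]}); drop units or impute"
        )
    d = 1.0 - rho
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0  # guard against asymmetric rounding
    mx = d.max()
    if rescale and mx > 0:
        d = d / mx
    d = np.clip(d, 0.0, None)
    np.fill_diagonal(d, 0.0)
    return DissimilarityMatrix(unit_ids=list(R.unit_ids), d=d)


def _double_center(d: np.ndarray) -> np.ndarray:
    n = d.shape[0]
    d2 = d**2
    J = np.eye(n) - np.ones((n, n)) / n
    return -0.5 * (J @ d2 @ J)


def classical_mds(
    D: DissimilarityMatrix, k: int = 3, eigenvalue_policy: str = "positive"
) -> EmbeddingResult:
    """Principal-coordinates embedding of ``D`` into ``k`` dimensions.

    Coordinates come from the largest ``min(k, #positive)`` eigenvalues of
    the double-centered matrix; when fewer than ``k`` eigenvalues are
    positive the trailing coordinate columns are zero and a warning is
    raised.  Column j of the coordinates has squared norm equal to
    eigenvalue j.
    """
    n = D.n
    if n < k + 1:
        raise ValueError(f"need at least k+1 = {k + 1} units, got {n}")
    B = _double_center(D.d)
    w, Q = linalg.eigh(B)
    order = np.argsort(w)[::-1]
    w = w[order]
    Q = Q[:, order]
    tol = max(np.abs(w).max(), 1.0) * 1e-12
    n_pos = int(np.sum(w > tol))
    m = min(k, n_pos)
    if n_pos < k:
        warnings.warn(
            f"only {n_pos} positive eigenvalue(s); trailing coordinate "
            f"column(s) set to 0",
            stacklevel=2,
        )
    coords = np.zeros((n, k))
    if m:
        coords[:, :m] = Q[:, :m] * np.sqrt(w[:m])
    p_k = goodness_of_fit(w, k, policy=eigenvalue_policy)
    return EmbeddingResult(
        unit_ids=list(D.unit_ids),
        coordinates=coords,
        eigenvalues=w,
        p_k=p_k,
        k=k,
        eigenvalue_policy=eigenvalue_policy,
    )


def goodness_of_fit(
    eigenvalues: np.ndarray, k: int, policy: str = "positive"
) -> float:
    """P_k: eigenvalue mass captured by the top ``k`` dimensions.

    The numerator sums the ``k`` largest eigenvalues (negative ones
    contribute their positive part only — a non-existent axis explains
    nothing); the denominator sums ``g(lambda_i)`` with ``g`` given by
    ``policy``: ``positive`` = max(l, 0), ``absolute`` = |l|, ``raw`` = l.
    Double-centering forces one structural zero eigenvalue; the written
    formula drops it by summing to n-1, which for ``positive`` and
    ``absolute`` (where g(0) = 0) equals summing over all n, while ``raw``
    sums the first n-1 eigenvalues in descending order as printed.
    P_k is invariant under uniform scaling of the dissimilarities.
    """
    if policy not in _EIG_POLICIES:
        raise ValueError(f"unknown eigenvalue policy {policy!r}")
    w = np.sort(np.asarray(eigenvalues, dtype=float))[::-1]
    num = np.sum(np.clip(w[:k], 0.0, None))
    if policy == "positive":
        den = np.sum(np.clip(w, 0.0, None))
    elif policy == "absolute":
        den = np.sum(np.abs(w))
    else:
        den = np.sum(w[: len(w) - 1])
    if den <= 0:
        raise ValueError("non-positive eigenvalue mass; cannot compute P_k")
    return float(num / den)


def permutation_null(
    D: DissimilarityMatrix,
    n_perm: int,
    seed: int,
    k: int = 3,
    eigenvalue_policy: str = "positive",
) -> PermutationNull:
    """Embeddability null: P_k of ``n_perm`` upper-triangle shuffles of ``D``.

    Each replicate permutes the n(n-1)/2 upper-triangle entries uniformly
    at random, mirrors them into a symmetric zero-diagonal matrix, and
    records its P_k.  The empirical p-value counts the observed value
    among the samples: p = (1 + #{null >= observed}) / (1 + n_perm).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    n = D.n
    if n < 4:
        raise ValueError("need n >= 4 for permutation to change the matrix")
    rng = np.random.default_rng(seed)
    iu = np.triu_indices(n, 1)
    vals = D.d[iu]
    observed = goodness_of_fit(
        linalg.eigvalsh(_double_center(D.d)), k, policy=eigenvalue_policy
    )
    null = np.empty(n_perm)
    m = np.zeros((n, n))
    for r in range(n_perm):
        perm = rng.permutation(vals)
        m[iu] = perm
        sym = m + m.T
        null[r] = goodness_of_fit(
            linalg.eigvalsh(_double_center(sym)), k, policy=eigenvalue_policy
        )
    p = (1 + int(np.sum(null >= observed))) / (1 + n_perm)
    return PermutationNull(
        n_perm=n_perm,
        seed=seed,
        k=k,
        observed=observed,
        null_p_k=null,
        mean=float(null.mean()),
        sd=float(null.std(ddof=1)),
        p_value=float(p),
        eigenvalue_policy=eigenvalue_policy,
    )
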