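"""Procrustes superposition of an inferred configuration onto a reference.

A cMDS configuration lives in arbitrary units with arbitrary orientation
and chirality, so comparing it with a crystal-structure topology requires
the best similarity transform: both configurations are centered, the
inferred one is rotated (optionally reflected) and isometrically scaled
onto the reference, and the residual root-mean-square deviation

    rmsd = sqrt( sum_i |t_i - c_i|^2 / n )

quantifies the disagreement in Angstrom.  The rotation comes from the SVD
of the cross-covariance of the matched, centered point sets; with
reflections disallowed the smallest singular value's sign is flipped to
force a proper rotation.  A flag divides by n^2 instead of n for
sensitivity analysis against alternative rmsd conventions.

Agreement is further dissected per principal axis (squared Pearson
correlation of predicted vs reference coordinates after PCA reorientation)
and at the level of pairwise distances (regression of one distance matrix
on another over a unit subset).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .structure_ref import ReferenceTopology

__all__ = [
    "SuperpositionResult",
    "AgreementStats",
    "procrustes_fit",
    "pca_reorient",
    "axis_correlations",
    "distance_agreement",
    "mantel_p_value",
]


@dataclass
class SuperpositionResult:
    """Optimal similarity transform and its residual."""

    unit_ids: list[str]
    rotation: np.ndarray  # (3, 3) orthogonal, applied to the inferred config
    scale: float
    translation_ref: np.ndarray  # centroid of the reference points
    translation_conf: np.ndarray  # centroid of the inferred points
    rmsd: float
    fitted: np.ndarray  # inferred points mapped into the reference frame
    reflection_used: bool
    allow_reflection: bool
    rmsd_denominator: str = "n"

    def __post_init__(self) -> None:
        R = self.rotation
        if not np.allclose(R.T @ R, np.eye(R.shape[0]), atol=1e-8):
            raise ValueError("rotation must be orthogonal")
        if self.scale <= 0:
            raise ValueError("scale must be positive")
        if self.rmsd < 0:
            raise ValueError("rmsd must be >= 0")


@dataclass
class AgreementStats:
    """r^2, two-sided p and sample size for one axis or for pairwise distances."""

    axis: str
    r_squared: float
    p_value: float
    n: int

    def __post_init__(self) -> None:
        if not (-1e-12 <= self.r_squared <= 1 + 1e-12):
            raise ValueError("r_squared must lie in [0, 1]")
        if not (0 < self.p_value <= 1):
            raise ValueError("p_value must lie in (0, 1]")
        if self.n < 3:
            raise ValueError("need n >= 3")


def _match(
    c_ids: list[str], C: np.ndarray, t_ids: list[str], T: np.ndarray
) -> tuple[list[str], np.ndarray, np.ndarray]:
    shared = [u for u in t_ids if u in c_ids]
    if len(shared) < 3:
        raise ValueError(f"need >= 3 shared units, got {len(shared)}")
    ci = [c_ids.index(u) for u in shared]
    ti = [t_ids.index(u) for u in shared]
    return shared, np.asarray(C, float)[ci], np.asarray(T, float)[ti]


def procrustes_fit(
    c_ids: list[str],
    C: np.ndarray,
    reference: ReferenceTopology,
    allow_reflection: bool = True,
    allow_scale: bool = True,
    rmsd_denominator: str = "n",
) -> SuperpositionResult:
    """Fit configuration ``C`` onto the reference by similarity Procrustes.

    Units are matched by id (reference order); both point sets are
    centered, the optimal rotation is taken from the SVD of the
    cross-covariance, and the isometric scale minimizing the residual is
    applied to ``C`` (unless ``allow_scale`` is off).  ``rmsd_denominator``
    is ``"n"`` (standard) or ``"n2"`` (divide by n^2, for sensitivity
    analysis).  Collinear configurations yield a warning but still a fit.
    """
    if rmsd_denominator not in ("n", "n2"):
        raise ValueError("rmsd_denominator must be 'n' or 'n2'")
    shared, Cm, Tm = _match(c_ids, C, reference.unit_ids, reference.centers)
    n = len(shared)
    mu_c = Cm.mean(axis=0)
    mu_t = Tm.mean(axis=0)
    Cc = Cm - mu_c
    Tc = Tm - mu_t
    if min(np.linalg.matrix_rank(Cc), np.linalg.matrix_rank(Tc)) < 2:
        warnings.warn("rank-deficient (collinear) configuration", stacklevel=2)

    M = Tc.T @ Cc
    U, S, Vt = np.linalg.svd(M)
    signs = np.ones(len(S))
    reflection = bool(np.linalg.det(U) * np.linalg.det(Vt) < 0)
    if reflection and not allow_reflection:
        signs[-1] = -1.0
        reflection_used = False
    else:
        reflection_used = reflection
    R = U @ np.diag(signs) @ Vt  # maps C-frame vectors into the T frame
    denom_c = float(np.sum(Cc**2))
    if denom_c == 0:
        raise ValueError("degenerate configuration (all points coincide)")
    scale = float(np.sum(S * signs)) / denom_c if allow_scale else 1.0
    if scale <= 0:
        warnings.warn("optimal scale non-positive; clamped to tiny", stacklevel=2)
        scale = np.finfo(float).tiny
    fitted_centered = scale * (Cc @ R.T)
    resid = float(np.sum((Tc - fitted_centered) ** 2))
    den = n if rmsd_denominator == "n" else n * n
    rmsd = float(np.sqrt(resid / den))
    return SuperpositionResult(
        unit_ids=shared,
        rotation=R,
        scale=scale,
        translation_ref=mu_t,
        translation_conf=mu_c,
        rmsd=rmsd,
        fitted=fitted_centered + mu_t,
        reflection_used=reflection_used,
        allow_reflection=allow_reflection,
        rmsd_denominator=rmsd_denominator,
    )


def pca_reorient(coords: np.ndarray) -> np.ndarray:
    """Rotate a configuration into its principal-axis frame.

    Axes are ordered by decreasing variance; each axis's sign is fixed so
    that its largest-magnitude loading is positive, making the operation
    idempotent up to that convention.
    """
    X = np.asarray(coords, dtype=float)
    if X.shape[0] < 3:
        raise ValueError("need >= 3 points")
    Xc = X - X.mean(axis=0)
    _, _, Vt = np.linalg.svd(Xc, full_matrices=False)
    for i in range(Vt.shape[0]):
        j = np.argmax(np.abs(Vt[i]))
        if Vt[i, j] < 0:
            Vt[i] *= -1
    return Xc @ Vt.T


def axis_correlations(
    fitted: np.ndarray,
    reference: np.ndarray,
    unit_ids: list[str] | None = None,
) -> list[AgreementStats]:
    """Per-axis squared Pearson correlation of predicted vs reference coords.

    Both configurations must already be expressed in the same (typically
    PCA-reoriented) frame and matched row-by-row.  The p-value is the
    two-sided t-test on n-2 degrees of freedom.
    """
    F = np.asarray(fitted, dtype=float)
    T = np.asarray(reference, dtype=float)
    if F.shape != T.shape:
        raise ValueError("configurations must have identical shape")
    n = F.shape[0]
    if n < 3:
        raise ValueError("need >= 3 points")
    out = []
    for ax in range(F.shape[1]):
        f, t = F[:, ax], T[:, ax]
        if np.ptp(f) < 1e-12 * max(1.0, np.abs(f).max()) or np.ptp(t) < 1e-12 * max(
            1.0, np.abs(t).max()
        ):
            warnings.warn(
                f"axis {ax + 1} has no variance; correlation undefined, skipped",
                stacklevel=2,
            )
            continue
        r, p = stats.pearsonr(f, t)
        out.append(
            AgreementStats(
                axis=f"axis{ax + 1}", r_squared=min(float(r**2), 1.0),
                p_value=max(float(p), np.finfo(float).tiny), n=n,
            )
        )
    return out


def distance_agreement(
    D_a: np.ndarray,
    D_b: np.ndarray,
    unit_ids: list[str],
    subset: list[str] | None = None,
) -> AgreementStats:
    """Regression of the upper triangle of ``D_a`` on that of ``D_b``.

    Restricted to ``subset`` when given.  This is the distance-vs-distance
    comparison behind "co-evolutionary distance correlates with physical
    distance"; n is the number of unit pairs.  p-values ignore the
    non-independence of shared-unit pairs (see :func:`mantel_p_value` for
    a permutation alternative).
    """
    D_a = np.asarray(D_a, float)
    D_b = np.asarray(D_b, float)
    if subset is not None:
        idx = [unit_ids.index(u) for u in subset]
        D_a = D_a[np.ix_(idx, idx)]
        D_b = D_b[np.ix_(idx, idx)]
    m = D_a.shape[0]
    if m < 3:
        raise ValueError("need a subset of >= 3 units")
    iu = np.triu_indices(m, 1)
    a, b = D_a[iu], D_b[iu]
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("zero variance in a distance vector")
    res = stats.linregress(b, a)
    return AgreementStats(
        axis="pairwise-distances",
        r_squared=min(float(res.rvalue**2), 1.0),
        p_value=max(float(res.pvalue), np.finfo(float).tiny),
        n=len(a),
    )


def mantel_p_value(
    D_a: np.ndarray, D_b: np.ndarray, n_perm: int = 999, seed: int = 0
) -> float:
    """Mantel permutation p-value for the correlation of two distance matrices.

    Supplementary to :func:`distance_agreement`: rows/columns of one
    matrix are permuted jointly, which respects the dependence structure
    of pairwise distances.
    """
    D_a = np.asarray(D_a, float)
    D_b = np.asarray(D_b, float)
    n = D_a.shape[0]
    iu = np.triu_indices(n, 1)
    obs = abs(stats.pearsonr(D_a[iu], D_b[iu])[0])
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        Dp = D_b[np.ix_(perm, perm)]
        if abs(stats.pearsonr(D_a[iu], Dp[iu])[0]) >= obs:
            hits += 1
    return (1 + hits) / (1 + n_perm)
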