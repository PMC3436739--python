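"""Phylogeny correction and the co-evolutionary correlation matrix.

All family trees of one complex share the underlying species phylogeny, so
raw patristic distance vectors are highly correlated with each other no
matter what.  The orthogonal-projection correction removes this shared
signal: each vector ``v`` is projected onto a reference vector ``p``
(the per-pair average over families) and replaced by its residual

    v* = v - (p.v / p.p) p

which is orthogonal to ``p``.  Corrected vectors are then compared by
Spearman rank correlation over their jointly observed species pairs,
yielding a symmetric co-evolutionary similarity matrix.

Under ragged species coverage the projection coefficients ``p.v`` and
``p.p`` are computed over the pairs present in ``v`` only, which keeps
the orthogonality contract exact per vector.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .phylodist import SpeciesPairVector, VectorSet

__all__ = [
    "ReferenceVector",
    "CorrectedVector",
    "CoevolutionMatrix",
    "reference_vector",
    "project_out",
    "coevolution_matrix",
    "write_matrix_tsv",
    "read_matrix_tsv",
]


@dataclass
class ReferenceVector:
    """Average patristic distance per species pair over all families."""

    pairs: list[tuple[str, str]]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < 0):
            raise ValueError("reference distances must be >= 0")


@dataclass
class CorrectedVector:
    """Residual distances after projecting out the reference; may be negative."""

    unit_id: str
    pairs: list[tuple[str, str]]
    values: np.ndarray
    present: np.ndarray


@dataclass
class CoevolutionMatrix:
    """Spearman correlations of corrected vectors, with per-cell pair counts.

    ``rho`` is symmetric with unit diagonal; cells whose joint coverage is
    < 2 species pairs, or where a corrected vector has zero variance, are
    NaN (undefined), never silently 0.  ``n_pairs`` records the joint
    species-pair count behind every cell so low-coverage correlations can
    be audited.
    """

    unit_ids: list[str]
    rho: np.ndarray
    n_pairs: np.ndarray

    def __post_init__(self) -> None:
        self.rho = np.asarray(self.rho, dtype=float)
        self.n_pairs = np.asarray(self.n_pairs, dtype=int)
        n = len(self.unit_ids)
        if self.rho.shape != (n, n) or self.n_pairs.shape != (n, n):
            raise ValueError("matrix shapes must match unit_ids")
        finite = np.isfinite(self.rho)
        if np.any(np.abs(self.rho[finite]) > 1 + 1e-12):
            raise ValueError("correlations must lie in [-1, 1]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rho, index=self.unit_ids, columns=self.unit_ids)

    def subset(self, units: list[str]) -> "CoevolutionMatrix":
        idx = [self.unit_ids.index(u) for u in units]
        return CoevolutionMatrix(
            list(units), self.rho[np.ix_(idx, idx)], self.n_pairs[np.ix_(idx, idx)]
        )


def reference_vector(vs: VectorSet) -> ReferenceVector:
    """Per-pair arithmetic mean of the distances of the units observing it."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN cols cannot occur
        means = np.nanmean(np.where(vs.present, vs.values, np.nan), axis=0)
    return ReferenceVector(pairs=list(vs.pairs), values=means)


def project_out(
    v: SpeciesPairVector | CorrectedVector, p: ReferenceVector
) -> CorrectedVector:
    """Residual of ``v`` after orthogonal projection onto ``p``.

    Restricted to the pairs present in ``v``.  Raises ``ValueError`` when
    the reference is degenerate (p.p = 0 on those pairs) or the pair
    indices disagree.
    """
    if list(v.pairs) != list(p.pairs):
        raise ValueError("vector and reference must share the pair index")
    mask = np.asarray(v.present, dtype=bool)
    vv = np.asarray(v.values, dtype=float)[mask]
    pp = p.values[mask]
    denom = float(pp @ pp)
    if denom == 0.0:
        raise ValueError("degenerate reference vector (p.p = 0 on present pairs)")
    coef = float(pp @ vv) / denom
    out = np.full(len(v.pairs), np.nan)
    out[mask] = vv - coef * pp
    return CorrectedVector(
        unit_id=v.unit_id, pairs=list(v.pairs), values=out, present=mask.copy()
    )


def _spearman(x: np.ndarray, y: np.ndarray) -> float:
    """Spearman rho with average ranks; NaN when either side has no variance."""
    if x.size < 2:
        return np.nan
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    if np.all(rx == rx[0]) or np.all(ry == ry[0]):
        return np.nan
    c = np.corrcoef(rx, ry)[0, 1]
    return float(np.clip(c, -1.0, 1.0))


def coevolution_matrix(
    vs: VectorSet, p: ReferenceVector | None = None
) -> CoevolutionMatrix:
    """Pairwise Spearman correlations of the phylogeny-corrected vectors.

    Correlations use the species pairs jointly present in both corrected
    vectors (pairwise-complete).  The diagonal is 1 by definition.
    """
    if vs.n_units < 2:
        raise ValueError("need at least 2 units")
    if p is None:
        p = reference_vector(vs)
    corrected = []
    for u in vs.unit_ids:
        raw = vs.vector(u)
        cv = project_out(raw, p)
        m = cv.present
        # a residual that is pure floating-point noise (vector parallel to
        # the reference) counts as zero variance, not as signal
        if np.linalg.norm(cv.values[m]) < 1e-10 * np.linalg.norm(raw.values[m]):
            cv.values[m] = 0.0
        corrected.append(cv)

    n = vs.n_units
    rho = np.eye(n)
    n_pairs = np.zeros((n, n), dtype=int)
    for i in range(n):
        n_pairs[i, i] = int(corrected[i].present.sum())
    for i in range(n):
        for j in range(i + 1, n):
            joint = corrected[i].present & corrected[j].present
            m = int(joint.sum())
            n_pairs[i, j] = n_pairs[j, i] = m
            r = _spearman(corrected[i].values[joint], corrected[j].values[joint])
            rho[i, j] = rho[j, i] = r
    return CoevolutionMatrix(unit_ids=list(vs.unit_ids), rho=rho, n_pairs=n_pairs)


def write_matrix_tsv(
    path: str | Path, unit_ids: list[str], matrix: np.ndarray
) -> None:
    """Square tab-delimited matrix, unit ids as first row and column."""
    pd.DataFrame(matrix, index=unit_ids, columns=unit_ids).to_csv(path, sep="\t")


def read_matrix_tsv(path: str | Path) -> tuple[list[str], np.ndarray]:
    """Read a square labeled TSV matrix; checks row/column label agreement."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    ids = [str(c) for c in df.columns]
    if [str(i) for i in df.index] != ids:
        raise ValueError(f"{path}: row and column labels differ")
    return ids, df.to_numpy(dtype=float)
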