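"""Per-class confidence ellipsoids in PCA score space and the asymmetric
class-overlap similarity index.

Each class of samples is modelled as approximately Gaussian in score space:
its confidence ellipsoid is the set of points whose squared Mahalanobis
distance from the class mean (under the class sample covariance) is at most
the χ²_k quantile at the chosen confidence level.  For an ordered class pair
(p, q) the similarity index is

    S(p, q) = #{x in class p : x inside ellipsoid(p) AND inside ellipsoid(q)}
              ─────────────────────────────────────────────────────────────
                                   |class p|

— the fraction of class-p samples in the overlap region.  It is asymmetric
because the denominator is class p's size; S(p, p) measures how tightly class
p aggregates inside its own ellipsoid (≈ the confidence level for Gaussian
data).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_config import AnalysisError
from .pca_reduce import ScoreMatrix

logger = logging.getLogger(__name__)

DEFAULT_LEVEL = 0.95
#: condition-number threshold above which the class covariance gets a ridge
_COND_MAX = 1e10
_RIDGE_EPS = 1e-8


class ClassTooSmallError(AnalysisError):
    """A class has too few samples to estimate a k-dimensional covariance."""


@dataclass
class ConfidenceEllipsoid:
    """Gaussian confidence region of one class in k-dim score space."""

    block: str
    label: str
    center: np.ndarray   # (k,)
    shape: np.ndarray    # (k, k) SPD covariance
    level: float
    radius2: float       # chi2.ppf(level, k)

    @property
    def k(self) -> int:
        return self.center.shape[0]

    def mahalanobis2(self, points: np.ndarray) -> np.ndarray:
        """Squared Mahalanobis distance of each row of ``points``."""
        P = np.atleast_2d(np.asarray(points, dtype=float))
        if P.shape[1] != self.k:
            raise ValueError(
                f"points have dimension {P.shape[1]}, ellipsoid is {self.k}-D"
            )
        L = np.linalg.cholesky(self.shape)
        z = np.linalg.solve(L, (P - self.center).T)
        return (z**2).sum(axis=0)


def fit_ellipsoid(
    class_scores: np.ndarray,
    level: float = DEFAULT_LEVEL,
    block: str = "",
    label: str = "",
) -> ConfidenceEllipsoid:
    """Fit the χ² confidence ellipsoid of one class.

    Center is the column mean, shape the sample covariance (ridge-regularized
    when near-singular), and the squared radius the χ²_k quantile at
    ``level``.  Requires n_p >= k + 2 so the covariance is estimable with at
    least one spare degree of freedom.
    """
    X = np.atleast_2d(np.asarray(class_scores, dtype=float))
    n_p, k = X.shape
    if not 0 < level < 1:
        raise ValueError(f"level must be in (0, 1), got {level}")
    if n_p < k + 2:
        raise ClassTooSmallError(
            f"class {label!r}: n={n_p} < k+2={k + 2}, covariance not estimable"
        )
    center = X.mean(axis=0)
    cov = np.cov(X, rowvar=False, ddof=1)
    cov = np.atleast_2d(cov)
    cov = 0.5 * (cov + cov.T)
    eigvals = np.linalg.eigvalsh(cov)
    if eigvals[0] <= 0 or eigvals[-1] / max(eigvals[0], 1e-300) > _COND_MAX:
        ridge = _RIDGE_EPS * max(np.trace(cov) / k, 1e-12)
        cov = cov + ridge * np.eye(k)
        logger.warning(
            "class %r (block %r): near-singular covariance, ridge %.3g added",
            label, block, ridge,
        )
    return ConfidenceEllipsoid(
        block=block,
        label=label,
        center=center,
        shape=cov,
        level=level,
        radius2=float(stats.chi2.ppf(level, df=k)),
    )


def contains(e: ConfidenceEllipsoid, points: np.ndarray) -> np.ndarray:
    """Boolean membership vector; boundary points count as inside (<=)."""
    return e.mahalanobis2(points) <= e.radius2


def overlap_count(
    e_p: ConfidenceEllipsoid,
    e_q: ConfidenceEllipsoid,
    class_p_scores: np.ndarray,
) -> int:
    """Number of class-p samples lying inside BOTH ellipsoids.

    This is the numerator of the similarity index: samples of class p in the
    overlap region of the two confidence ellipsoids.
    """
    if e_p.k != e_q.k:
        raise ValueError(f"dimension mismatch: {e_p.k} vs {e_q.k}")
    inside = contains(e_p, class_p_scores) & contains(e_q, class_p_scores)
    return int(inside.sum())


@dataclass
class SimilarityMatrix:
    """All ordered-pair similarity values for one block's score space."""

    block: str
    labels: list[str]
    values: np.ndarray        # (|d|, |d|), entry (p, q) = S(p, q) in [0, 1]
    counts: np.ndarray        # integer overlap counts (numerators)
    class_sizes: np.ndarray   # denominators |D_p| aligned with labels
    level: float
    dims: int
    dropped: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def row(self, label: str) -> pd.Series:
        return self.to_frame().loc[label]


def similarity_matrix(
    block_scores: ScoreMatrix,
    labels: Sequence[str],
    level: float = DEFAULT_LEVEL,
    dims: int = 2,
) -> SimilarityMatrix:
    """Compute the full |d|×|d| similarity matrix for one block.

    Uses the first ``dims`` score columns.  Classes too small to fit an
    ellipsoid (n_p < dims + 2) are dropped from both rows and columns, with a
    warning; at least two usable classes must remain.
    """
    T = block_scores.scores
    if dims < 1 or dims > block_scores.k:
        raise ValueError(f"dims={dims} out of range [1, {block_scores.k}]")
    T = T[:, :dims]
    lab = np.asarray([str(l) for l in labels])
    if lab.shape[0] != T.shape[0]:
        raise ValueError("labels length does not match number of score rows")

    class_names = sorted(set(lab.tolist()))
    ellipsoids: dict[str, ConfidenceEllipsoid] = {}
    class_points: dict[str, np.ndarray] = {}
    dropped: list[str] = []
    for name in class_names:
        pts = T[lab == name]
        class_points[name] = pts
        try:
            ellipsoids[name] = fit_ellipsoid(
                pts, level=level, block=block_scores.block, label=name
            )
        except ClassTooSmallError as exc:
            logger.warning("block %r: dropping class: %s", block_scores.block, exc)
            dropped.append(name)
    usable = [n for n in class_names if n in ellipsoids]
    if len(usable) < 2:
        raise AnalysisError(
            f"block {block_scores.block!r}: fewer than 2 usable classes "
            f"after the minimum-size filter ({len(usable)} usable)"
        )

    d = len(usable)
    counts = np.zeros((d, d), dtype=int)
    sizes = np.array([class_points[n].shape[0] for n in usable])
    # membership of every class-p point in every ellipsoid, p-major
    for i, p in enumerate(usable):
        pts = class_points[p]
        in_own = contains(ellipsoids[p], pts)
        for j, q in enumerate(usable):
            in_q = in_own if q == p else contains(ellipsoids[q], pts)
            counts[i, j] = int((in_own & in_q).sum())
    values = counts / sizes[:, None]
    return SimilarityMatrix(
        block=block_scores.block,
        labels=usable,
        values=values,
        counts=counts,
        class_sizes=sizes,
        level=level,
        dims=dims,
        dropped=dropped,
    )


def self_similarity(
    class_scores: np.ndarray, level: float = DEFAULT_LEVEL
) -> float:
    """S(p, p) for a single class: fraction of its samples inside its own
    fitted confidence ellipsoid, via the overlap-count machinery with p = q."""
    e = fit_ellipsoid(class_scores, level=level)
    return overlap_count(e, e, class_scores) / class_scores.shape[0]
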