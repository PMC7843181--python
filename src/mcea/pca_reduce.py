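"""Per-block PCA by singular value decomposition and the shared
retained-dimension rule.

Each block's centered data matrix A is decomposed as A = U Σ Vᵀ; the columns
of V are the loadings and U Σ the variance-carrying scores.  The retained
dimension for the joint analysis is chosen by a cumulative explained-variance
threshold σ: per block, k_i is the smallest k whose first k components explain
at least σ of the block's variance, and the global k is the maximum of the
k_i (so every block meets the threshold).  When extracting scores, k is capped
at a block's own rank.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd


@dataclass
class PCAModel:
    """SVD of one centered block: center, orthonormal loadings, singular
    values (nonincreasing) and explained-variance ratios (sum to 1)."""

    block: str
    center: np.ndarray          # (m,)
    loadings: np.ndarray        # (m, r), columns orthonormal
    singular_values: np.ndarray  # (r,), nonincreasing
    explained_ratio: np.ndarray  # (r,), sums to 1
    n_samples: int

    @property
    def n_features(self) -> int:
        return self.center.shape[0]

    @property
    def n_components(self) -> int:
        return self.singular_values.shape[0]

    def transform(self, data: np.ndarray | pd.DataFrame, k: int) -> np.ndarray:
        """Project ``data`` onto the first ``k`` loadings: (X − center)·V[:, :k]."""
        if not 1 <= k <= self.n_components:
            raise ValueError(
                f"k={k} out of range [1, {self.n_components}] for block "
                f"{self.block!r}"
            )
        X = np.asarray(data, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != self.n_features:
            raise ValueError(
                f"data has {X.shape[1]} columns, model expects {self.n_features}"
            )
        return (X - self.center) @ self.loadings[:, :k]


@dataclass
class ScoreMatrix:
    """The retained k-column score matrix T_i of one block."""

    block: str
    scores: np.ndarray  # (n, k)
    k: int
    explained_cum: float  # cumulative variance fraction at k

    @property
    def n(self) -> int:
        return self.scores.shape[0]


def fit_pca(data: np.ndarray | pd.DataFrame, block: str = "") -> PCAModel:
    """Fit PCA on a block via thin SVD of the column-centered matrix.

    explained_ratio_j = s_j² / Σ s².  Loading signs follow the convention that
    each column's largest-magnitude element is positive, so repeated runs give
    identical score plots.
    """
    X = np.asarray(data, dtype=float)
    if X.ndim != 2:
        raise ValueError("data must be 2-D (n samples × m variables)")
    n, m = X.shape
    if n < 2:
        raise ValueError(f"need n >= 2 samples to fit PCA, got {n}")
    if m < 1:
        raise ValueError("need at least one variable")
    if np.isnan(X).any():
        raise ValueError(
            f"block {block!r} contains missing values; run preprocessing first"
        )
    center = X.mean(axis=0)
    U, s, Vt = np.linalg.svd(X - center, full_matrices=False)
    # deterministic sign: largest |loading| element positive per component
    V = Vt.T
    flip = np.sign(V[np.abs(V).argmax(axis=0), np.arange(V.shape[1])])
    flip[flip == 0] = 1.0
    V = V * flip
    total = float((s**2).sum())
    if total <= 0:
        raise ValueError(f"block {block!r} has zero total variance")
    ratio = s**2 / total
    return PCAModel(
        block=block,
        center=center,
        loadings=V,
        singular_values=s,
        explained_ratio=ratio,
        n_samples=n,
    )


@dataclass
class KSelection:
    """Result of the shared retained-dimension rule."""

    global_k: int
    per_block_k: dict[str, int]   # minimum k_i meeting the threshold per block
    extract_k: dict[str, int]     # global k capped at each block's rank
    threshold: float


def min_components(model: PCAModel, threshold: float) -> int:
    """Smallest k with cumulative explained variance >= threshold."""
    cum = np.cumsum(model.explained_ratio)
    # numerical guard: the final cumulative value is 1 by construction
    idx = int(np.searchsorted(cum, threshold - 1e-12) + 1)
    return min(idx, model.n_components)


def select_k(
    models: Sequence[PCAModel] | Mapping[str, PCAModel],
    threshold: float,
) -> KSelection:
    """Apply the max-over-blocks retained-dimension rule.

    Per block, k_i is the minimum component count reaching the cumulative
    variance threshold; the global k is max_i k_i.  For score extraction the
    global k is capped at each block's own component count (projection beyond
    a block's rank is undefined).
    """
    if isinstance(models, Mapping):
        model_list = list(models.values())
    else:
        model_list = list(models)
    if not model_list:
        raise ValueError("need at least one PCA model")
    if not 0 < threshold <= 1:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    per_block = {m.block: min_components(m, threshold) for m in model_list}
    global_k = max(per_block.values())
    extract = {m.block: min(global_k, m.n_components) for m in model_list}
    return KSelection(
        global_k=global_k,
        per_block_k=per_block,
        extract_k=extract,
        threshold=threshold,
    )


def scores(
    model: PCAModel, k: int, data: np.ndarray | pd.DataFrame
) -> ScoreMatrix:
    """Extract the k-column score matrix for ``data`` under ``model``.

    On the training matrix this equals the first k columns of UΣ.
    """
    T = model.transform(data, k)
    explained_cum = float(np.cumsum(model.explained_ratio)[k - 1])
    return ScoreMatrix(block=model.block, scores=T, k=k,
                       explained_cum=explained_cum)


def explained_variance_table(model: PCAModel) -> pd.DataFrame:
    """Per-component singular value, variance ratio and cumulative ratio."""
    cum = np.cumsum(model.explained_ratio)
    return pd.DataFrame(
        {
            "component": np.arange(1, model.n_components + 1),
            "singular_value": model.singular_values,
            "explained_ratio": model.explained_ratio,
            "cumulative_ratio": cum,
        }
    )
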