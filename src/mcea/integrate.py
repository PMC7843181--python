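"""Integrated cross-block correlation.

Two blocks agree about a class p when their similarity profiles for p — the
rows S_a(p, ·) and S_b(p, ·) over the other classes — move together.  The
integrated analysis computes, per class, the Pearson (or Spearman)
correlation between the two rows, restricted to classes usable in both
blocks, and summarises the per-class values by (min, mean, max).  The
self-entry S(p, p) is excluded by default: it measures within-class
aggregation, not cross-class similarity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .io_config import AnalysisError
from .mcea_core import SimilarityMatrix

logger = logging.getLogger(__name__)


@dataclass
class IntegrationResult:
    """Per-class profile correlations for one block pair and their summary."""

    pair: tuple[str, str]
    per_class: dict[str, float]
    summary: tuple[float, float, float]  # (min, mean, max)
    method: str
    exclude_self: bool
    skipped: dict[str, str] = field(default_factory=dict)  # class -> reason

    def to_dict(self) -> dict:
        return {
            "pair": list(self.pair),
            "per_class": self.per_class,
            "summary": {
                "min": self.summary[0],
                "mean": self.summary[1],
                "max": self.summary[2],
            },
            "method": self.method,
            "exclude_self": self.exclude_self,
            "skipped": self.skipped,
        }


def _paired_rows(
    sa: SimilarityMatrix,
    sb: SimilarityMatrix,
    p: str,
    exclude_self: bool,
) -> tuple[np.ndarray, np.ndarray]:
    common = [c for c in sa.labels if c in set(sb.labels)]
    if p not in common:
        raise AnalysisError(f"class {p!r} not usable in both blocks")
    cols = [c for c in common if not (exclude_self and c == p)]
    if len(cols) < 3:
        raise AnalysisError(
            f"class {p!r}: only {len(cols)} paired entries; need >= 3 for a "
            "correlation"
        )
    fa, fb = sa.to_frame(), sb.to_frame()
    return fa.loc[p, cols].to_numpy(float), fb.loc[p, cols].to_numpy(float)


def per_class_correlation(
    sa: SimilarityMatrix,
    sb: SimilarityMatrix,
    p: str,
    exclude_self: bool = True,
    method: str = "pearson",
) -> float:
    """Correlation between the two blocks' similarity profiles for class p.

    Raises :class:`AnalysisError` for fewer than three paired entries or a
    zero-variance profile (correlation undefined).
    """
    xa, xb = _paired_rows(sa, sb, p, exclude_self)
    if np.std(xa) == 0 or np.std(xb) == 0:
        raise AnalysisError(f"class {p!r}: zero-variance similarity profile")
    if method == "pearson":
        r = stats.pearsonr(xa, xb).statistic
    elif method == "spearman":
        r = stats.spearmanr(xa, xb).statistic
    else:
        raise ValueError(f"unknown correlation method {method!r}")
    return float(r)


def integrate_pair(
    sa: SimilarityMatrix,
    sb: SimilarityMatrix,
    exclude_self: bool = True,
    method: str = "pearson",
) -> IntegrationResult:
    """Per-class profile correlations for one block pair, with summary.

    Classes whose correlation is undefined (zero-variance profile, too few
    paired entries) are skipped and recorded, not imputed.
    """
    common = [c for c in sa.labels if c in set(sb.labels)]
    if len(common) < 3:
        raise AnalysisError(
            f"blocks {sa.block!r}/{sb.block!r} share only {len(common)} classes"
        )
    per_class: dict[str, float] = {}
    skipped: dict[str, str] = {}
    for p in common:
        try:
            per_class[p] = per_class_correlation(sa, sb, p, exclude_self, method)
        except AnalysisError as exc:
            logger.warning("pair (%s, %s): skipping class %r: %s",
                           sa.block, sb.block, p, exc)
            skipped[p] = str(exc)
    if not per_class:
        raise AnalysisError(
            f"pair ({sa.block!r}, {sb.block!r}): no class with a defined "
            "profile correlation"
        )
    vals = np.array(list(per_class.values()))
    return IntegrationResult(
        pair=(sa.block, sb.block),
        per_class=per_class,
        summary=(float(vals.min()), float(vals.mean()), float(vals.max())),
        method=method,
        exclude_self=exclude_self,
        skipped=skipped,
    )


def integrate_blocks(
    matrices: Mapping[str, SimilarityMatrix] | Sequence[SimilarityMatrix],
    pairs: Sequence[tuple[str, str]] | None = None,
    exclude_self: bool = True,
    method: str = "pearson",
) -> list[IntegrationResult]:
    """Integrated correlation for each requested block pair.

    With ``pairs=None`` every unordered pair of distinct blocks is analysed
    (three blocks give the three pairings independent–dependent and
    independent–independent).
    """
    if not isinstance(matrices, Mapping):
        matrices = {m.block: m for m in matrices}
    if len(matrices) < 2:
        raise AnalysisError("need at least two similarity matrices")
    names = list(matrices)
    if pairs is None:
        pairs = [(a, b) for i, a in enumerate(names) for b in names[i + 1:]]
    results = []
    for a, b in pairs:
        for name in (a, b):
            if name not in matrices:
                raise KeyError(f"unknown block name {name!r} in pair ({a}, {b})")
        results.append(integrate_pair(matrices[a], matrices[b],
                                      exclude_self, method))
    return results
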