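"""Data-quality pipeline: missing-row deletion, box-plot outlier removal,
z-score normalization — applied in that fixed order.

Rules operate on the numeric (independent/dependent) block columns only;
description columns never trigger removal.  Quartiles use linear interpolation
of order statistics (the common "type 7" rule) and the outlier fences are
Tukey's Q1 − f·IQR, Q3 + f·IQR with f = 1.5 by default.  The z-score uses the
sample (n−1) standard deviation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_config import AnalysisError, BlockCollection


@dataclass
class PreprocessReport:
    """Bookkeeping for one preprocessing stage (or the whole pipeline)."""

    n_input: int
    n_after_missing: int | None = None
    n_after_outliers: int | None = None
    #: reason -> row indices (original frame index labels), disjoint lists
    removed: dict[str, list] = field(default_factory=dict)
    #: column -> stats relevant to the stage (fences, mu/sigma, quartiles)
    column_stats: dict[str, dict] = field(default_factory=dict)
    quartile_rule: str = "linear interpolation (type 7)"

    @property
    def n_output(self) -> int:
        for n in (self.n_after_outliers, self.n_after_missing):
            if n is not None:
                return n
        return self.n_input

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_after_missing": self.n_after_missing,
            "n_after_outliers": self.n_after_outliers,
            "removed": {k: list(map(int, v)) for k, v in self.removed.items()},
            "column_stats": self.column_stats,
            "quartile_rule": self.quartile_rule,
        }


def drop_missing(bc: BlockCollection) -> tuple[BlockCollection, PreprocessReport]:
    """Remove rows with any missing value in a numeric block column.

    Missing cells in description columns do not cause removal.
    """
    cols = bc.numeric_columns()
    if not cols:
        raise AnalysisError("no numeric block columns to screen for missingness")
    mask = bc.samples[cols].isna().any(axis=1)
    removed_idx = bc.samples.index[mask].tolist()
    kept = bc.samples.loc[~mask]
    report = PreprocessReport(
        n_input=bc.n,
        n_after_missing=len(kept),
        removed={"missing": removed_idx},
    )
    if len(kept) == 0:
        err = AnalysisError("all rows removed by missing-value deletion")
        err.report = report  # type: ignore[attr-defined]
        raise err
    return bc.replace_samples(kept), report


def iqr_outlier_filter(
    bc: BlockCollection,
    fence_multiplier: float = 1.5,
    per_class: bool = False,
) -> tuple[BlockCollection, PreprocessReport]:
    """Box-plot (Tukey fence) outlier removal, whole-row semantics.

    Per numeric column: Q1, Q3 and IQR = Q3 − Q1 give fences
    [Q1 − f·IQR, Q3 + f·IQR]; a row is removed if ANY of its numeric values
    falls outside its column's fences.  Fences are computed globally by
    default, or within each class with ``per_class=True``.
    """
    if fence_multiplier <= 0:
        raise ValueError("fence_multiplier must be positive")
    if bc.n < 4:
        raise AnalysisError(f"need n >= 4 for quartile fences, have n={bc.n}")
    cols = bc.numeric_columns()
    report = PreprocessReport(n_input=bc.n)

    def fences(frame: pd.DataFrame) -> pd.DataFrame:
        q1 = frame[cols].quantile(0.25, interpolation="linear")
        q3 = frame[cols].quantile(0.75, interpolation="linear")
        iqr = q3 - q1
        return pd.DataFrame(
            {"lo": q1 - fence_multiplier * iqr, "hi": q3 + fence_multiplier * iqr}
        )

    outlier_mask = pd.Series(False, index=bc.samples.index)
    flagged_by_col: dict[str, list] = {c: [] for c in cols}
    groups = (
        bc.samples.groupby(bc.class_labels.astype(str), sort=False)
        if per_class
        else [("__all__", bc.samples)]
    )
    for gname, frame in groups:
        f = fences(frame)
        for c in cols:
            bad = (frame[c] < f.loc[c, "lo"]) | (frame[c] > f.loc[c, "hi"])
            flagged_by_col[c].extend(frame.index[bad].tolist())
            outlier_mask.loc[frame.index[bad]] = True
            key = c if not per_class else f"{c}[{gname}]"
            report.column_stats[key] = {
                "q1": float(frame[c].quantile(0.25)),
                "q3": float(frame[c].quantile(0.75)),
                "lower_fence": float(f.loc[c, "lo"]),
                "upper_fence": float(f.loc[c, "hi"]),
                "n_flagged": int(bad.sum()),
            }
    removed_idx = bc.samples.index[outlier_mask].tolist()
    kept = bc.samples.loc[~outlier_mask]
    report.n_after_outliers = len(kept)
    report.removed = {"outlier": removed_idx}
    report.column_stats["__flagged_rows_by_column__"] = {
        c: sorted(set(map(int, v))) for c, v in flagged_by_col.items() if v
    }
    if len(kept) == 0:
        err = AnalysisError("all rows removed by outlier filtering")
        err.report = report  # type: ignore[attr-defined]
        raise err
    return bc.replace_samples(kept), report


def zscore(bc: BlockCollection) -> tuple[BlockCollection, PreprocessReport]:
    """Standardize every numeric block column to (x − μ)/σ, σ the sample SD.

    The (μ, σ) pair per column is stored in the report so the transform is
    invertible.  A zero-variance column is an error — it carries no signal and
    would divide by zero.
    """
    cols = bc.numeric_columns()
    frame = bc.samples.copy()
    report = PreprocessReport(n_input=bc.n, n_after_missing=bc.n,
                              n_after_outliers=bc.n)
    for c in cols:
        mu = float(frame[c].mean())
        sd = float(frame[c].std(ddof=1))
        if not np.isfinite(sd) or sd <= 0:
            raise AnalysisError(f"zero-variance column {c!r}: cannot z-score")
        frame[c] = (frame[c] - mu) / sd
        report.column_stats[c] = {"mu": mu, "sigma": sd}
    return bc.replace_samples(frame), report


def preprocess_pipeline(
    bc: BlockCollection,
    fence_multiplier: float = 1.5,
    per_class: bool = False,
) -> tuple[BlockCollection, PreprocessReport]:
    """Missing-row deletion, then outlier filtering, then z-scoring.

    The outlier filter runs exactly once and the normalization is fit on the
    post-filter rows only.  Returns the cleaned collection and a merged
    report.
    """
    bc1, rep_missing = drop_missing(bc)
    bc2, rep_outlier = iqr_outlier_filter(bc1, fence_multiplier, per_class)
    bc3, rep_z = zscore(bc2)
    merged = PreprocessReport(
        n_input=rep_missing.n_input,
        n_after_missing=rep_missing.n_after_missing,
        n_after_outliers=rep_outlier.n_after_outliers,
        removed={
            "missing": rep_missing.removed.get("missing", []),
            "outlier": rep_outlier.removed.get("outlier", []),
        },
        column_stats={
            "fences": rep_outlier.column_stats,
            "zscore": rep_z.column_stats,
        },
    )
    return bc3, merged
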