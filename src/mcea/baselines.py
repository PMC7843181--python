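"""Regression baselines with leave-one-out validation.

Three conventional routes from the independent blocks to one response:
forward stepwise OLS with partial-F entry, PLS1 regression, and
ε-insensitive support-vector regression.  Each is scored by leave-one-out
R² = 1 − SSE_pred / SST over held-out predictions — the quantity that stays
low when the cross-block relationship is weak, which is exactly the regime
the ellipsoid-overlap analysis targets.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cross_decomposition import PLSRegression
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR

logger = logging.getLogger(__name__)


@dataclass
class RegressionReport:
    """Fit summary for one baseline method on one response."""

    method: str
    response: str
    predictors: list[str]
    params: dict
    loo_r2: float | None = None
    #: stepwise only: per-step (entered variable, partial-F, critical value)
    path: list[dict] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "response": self.response,
            "predictors": self.predictors,
            "params": self.params,
            "loo_r2": self.loo_r2,
            "path": self.path,
        }


def _as_matrix(X) -> tuple[np.ndarray, list[str]]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(float), [str(c) for c in X.columns]
    A = np.asarray(X, dtype=float)
    return A, [f"x{i}" for i in range(A.shape[1])]


def _ols_rss(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Residual sum of squares of OLS of y on [1, X]."""
    n = len(y)
    Z = np.column_stack([np.ones(n), X]) if X.size else np.ones((n, 1))
    beta, *_ = np.linalg.lstsq(Z, y, rcond=None)
    r = y - Z @ beta
    return float(r @ r)


def stepwise_select(
    X: np.ndarray, y: np.ndarray, alpha: float = 0.05
) -> tuple[list[int], list[dict]]:
    """Forward selection by partial-F: at each step the candidate with the
    largest partial-F enters if it exceeds the F(1, n−p−1) critical value at
    ``alpha``; ties break by column order.  Returns selected column indices
    (entry order) and the step log."""
    n, m = X.shape
    col_sd = X.std(axis=0)
    candidates = [j for j in range(m) if col_sd[j] > 0]
    skipped = [j for j in range(m) if col_sd[j] <= 0]
    if skipped:
        logger.warning("stepwise: skipping zero-variance column(s) %s", skipped)
    selected: list[int] = []
    path: list[dict] = []
    rss_cur = _ols_rss(X[:, []], y)
    while candidates:
        p_new = len(selected) + 2  # intercept + selected + candidate
        dof = n - p_new
        if dof < 1:
            break
        best_j, best_f, best_rss = -1, -np.inf, None
        for j in candidates:
            rss_j = _ols_rss(X[:, selected + [j]], y)
            if rss_j <= 0:
                f_j = np.inf
            else:
                f_j = (rss_cur - rss_j) / (rss_j / dof)
            if f_j > best_f:
                best_j, best_f, best_rss = j, f_j, rss_j
        f_crit = float(stats.f.ppf(1 - alpha, 1, dof))
        if best_f <= f_crit:
            break
        selected.append(best_j)
        candidates.remove(best_j)
        rss_cur = best_rss
        path.append({"entered": best_j, "partial_F": float(best_f),
                     "F_critical": f_crit, "rss": float(rss_cur)})
    return selected, path


def loo_r2(
    fit_predict: Callable[[np.ndarray, np.ndarray, np.ndarray], np.ndarray],
    X: np.ndarray,
    y: np.ndarray,
) -> float:
    """Leave-one-out R²: 1 − Σ(y_i − ŷ_{−i})² / Σ(y_i − ȳ)².

    ``fit_predict(X_train, y_train, X_test)`` must return held-out
    predictions.  Can be negative (worse than predicting the mean).
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float).ravel()
    n = len(y)
    if n < 3:
        raise ValueError(f"need n >= 3 for leave-one-out, got {n}")
    sst = float(((y - y.mean()) ** 2).sum())
    if sst == 0:
        raise ValueError("constant response: leave-one-out R² undefined")
    preds = np.empty(n)
    idx = np.arange(n)
    for i in range(n):
        tr = idx != i
        preds[i] = np.asarray(
            fit_predict(X[tr], y[tr], X[i:i + 1])
        ).ravel()[0]
    sse = float(((y - preds) ** 2).sum())
    return 1.0 - sse / sst


def _stepwise_fit_predict(alpha: float):
    def fp(Xtr, ytr, Xte):
        sel, _ = stepwise_select(Xtr, ytr, alpha)
        n = len(ytr)
        Ztr = np.column_stack([np.ones(n), Xtr[:, sel]])
        beta, *_ = np.linalg.lstsq(Ztr, ytr, rcond=None)
        Zte = np.column_stack([np.ones(len(Xte)), Xte[:, sel]])
        return Zte @ beta
    return fp


def stepwise_forward(
    X, y, alpha: float = 0.05, response: str = "y", compute_loo: bool = True
) -> RegressionReport:
    """Forward stepwise OLS with F-to-enter at significance level ``alpha``."""
    A, names = _as_matrix(X)
    y = np.asarray(y, float).ravel()
    n, m = A.shape
    if n <= m + 2:
        raise ValueError(f"need n > m + 2 (n={n}, m={m})")
    if np.isnan(A).any() or np.isnan(y).any():
        raise ValueError("missing values not allowed")
    sel, path = stepwise_select(A, y, alpha)
    for step in path:
        step["entered"] = names[step["entered"]]
    Z = np.column_stack([np.ones(n), A[:, sel]])
    beta, *_ = np.linalg.lstsq(Z, y, rcond=None)
    report = RegressionReport(
        method="stepwise",
        response=response,
        predictors=[names[j] for j in sel],
        params={"alpha": alpha, "intercept": float(beta[0]),
                "coefficients": dict(zip([names[j] for j in sel],
                                         map(float, beta[1:])))},
        path=path,
    )
    if compute_loo:
        report.loo_r2 = loo_r2(_stepwise_fit_predict(alpha), A, y)
    return report


def _pls_fit_predict(n_components: int):
    def fp(Xtr, ytr, Xte):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = PLSRegression(n_components=n_components, scale=True)
            model.fit(Xtr, ytr)
            return model.predict(Xte).ravel()
    return fp


def pls_fit(
    X, y, n_components: int | None = None, response: str = "y",
    max_components: int = 10, compute_loo: bool = True,
) -> RegressionReport:
    """PLS1 regression; the component count is chosen by a leave-one-out grid
    unless fixed."""
    A, names = _as_matrix(X)
    y = np.asarray(y, float).ravel()
    rank = int(np.linalg.matrix_rank(A - A.mean(axis=0)))
    if n_components is not None:
        if not 1 <= n_components <= rank:
            raise ValueError(
                f"n_components={n_components} outside [1, rank={rank}]"
            )
        best_nc, best_r2 = n_components, None
        if compute_loo:
            best_r2 = loo_r2(_pls_fit_predict(best_nc), A, y)
    else:
        grid = range(1, min(max_components, rank) + 1)
        scored = [(nc, loo_r2(_pls_fit_predict(nc), A, y)) for nc in grid]
        best_nc, best_r2 = max(scored, key=lambda t: t[1])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = PLSRegression(n_components=best_nc, scale=True)
        model.fit(A, y)
    return RegressionReport(
        method="pls",
        response=response,
        predictors=names,
        params={"n_components": int(best_nc)},
        loo_r2=best_r2,
    )


def _svr_fit_predict(epsilon: float, C: float, kernel: str):
    def fp(Xtr, ytr, Xte):
        model = make_pipeline(
            StandardScaler(), SVR(kernel=kernel, epsilon=epsilon, C=C)
        )
        model.fit(Xtr, ytr)
        return model.predict(Xte)
    return fp


def svr_fit(
    X, y, epsilon: float = 0.1, C: float = 1.0, kernel: str = "linear",
    response: str = "y", compute_loo: bool = True,
) -> RegressionReport:
    """ε-insensitive support-vector regression (linear kernel by default,
    standardized inputs)."""
    if epsilon < 0:
        raise ValueError(f"epsilon must be >= 0, got {epsilon}")
    A, names = _as_matrix(X)
    y = np.asarray(y, float).ravel()
    model = make_pipeline(StandardScaler(),
                          SVR(kernel=kernel, epsilon=epsilon, C=C))
    model.fit(A, y)
    n_sv = int(model[-1].support_.shape[0])
    report = RegressionReport(
        method="svr",
        response=response,
        predictors=names,
        params={"epsilon": epsilon, "C": C, "kernel": kernel,
                "n_support_vectors": n_sv},
    )
    if compute_loo:
        report.loo_r2 = loo_r2(_svr_fit_predict(epsilon, C, kernel), A, y)
    return report
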