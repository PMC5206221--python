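"""Ordinary least-squares machinery: univariate K_d ~ K_ow models,
leverage-based outlier handling, forward-backward stepwise selection, and
the fit statistics reported throughout (R^2, adjusted/predicted R^2, LOO
cross-validated R^2, mean unsigned error).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "UnivariateModel",
    "LinearModel",
    "LeverageReport",
    "FitMetrics",
    "fit_univariate",
    "fit_ols",
    "hat_diagonal",
    "leverage_filter_refit",
    "stepwise_regression",
    "fit_metrics",
    "loo_press_ols",
]


@dataclass
class UnivariateModel:
    """log K_d = a + b * x for one charge class (or the pooled dataset)."""

    slope: float
    intercept: float
    r2: float
    n: int
    predictor_name: str = "log_kow"
    charge_class: str = "combined"

    def predict(self, x) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(x, dtype=float)


@dataclass
class LinearModel:
    """Multiple OLS fit on named columns (intercept always included)."""

    coef: np.ndarray
    intercept: float
    names: list[str]
    r2: float
    n: int

    def predict(self, X) -> np.ndarray:
        return self.intercept + np.asarray(X, dtype=float) @ self.coef


@dataclass
class LeverageReport:
    leverages: np.ndarray
    flagged: np.ndarray  # integer row indices with h_ii above threshold
    threshold: float
    model: LinearModel


@dataclass
class FitMetrics:
    r2: float
    r2_adj: Optional[float]
    r2_pred: Optional[float]
    mue: float
    s: Optional[float]
    n: int
    n_params: int
    small_sample: bool = False  # adjusted/predicted metrics undefined


def _r2(y: np.ndarray, yhat: np.ndarray) -> float:
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst <= 0:
        return 0.0
    sse = float(np.sum((y - yhat) ** 2))
    return 1.0 - sse / sst


def fit_univariate(x, y, predictor_name: str = "log_kow", charge_class: str = "combined") -> UnivariateModel:
    """OLS line with intercept; the classic log K_d = a + b log K_ow model."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need >= 3 paired observations")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values in input")
    sxx = float(np.sum((x - x.mean()) ** 2))
    if sxx <= 0:
        raise ValueError("predictor has zero variance")
    syy = float(np.sum((y - y.mean()) ** 2))
    if syy <= 0:
        return UnivariateModel(0.0, float(y.mean()), 0.0, x.size, predictor_name, charge_class)
    b = float(np.sum((x - x.mean()) * (y - y.mean())) / sxx)
    a = float(y.mean() - b * x.mean())
    return UnivariateModel(b, a, _r2(y, a + b * x), x.size, predictor_name, charge_class)


def fit_ols(X, y, names: Sequence[str] | None = None) -> LinearModel:
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y, dtype=float)
    A = np.column_stack([np.ones(len(y)), X])
    beta, *_ = np.linalg.lstsq(A, y, rcond=None)
    yhat = A @ beta
    return LinearModel(
        coef=beta[1:],
        intercept=float(beta[0]),
        names=list(names) if names is not None else [f"x{i}" for i in range(X.shape[1])],
        r2=_r2(y, yhat),
        n=len(y),
    )


def hat_diagonal(X: np.ndarray) -> np.ndarray:
    """Diagonal of the hat matrix for the design [1, X] via QR."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    A = np.column_stack([np.ones(X.shape[0]), X])
    Q, _ = np.linalg.qr(A)
    return np.sum(Q**2, axis=1)


def leverage_filter_refit(X, y, multiplier: float = 3.0, names: Sequence[str] | None = None) -> LeverageReport:
    """Flag rows with hat-diagonal above multiplier*p/n, refit once without them.

    A single pass: leverages come from the full-data fit; the model is refit
    on the survivors and not re-screened.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y, dtype=float)
    n, k = X.shape
    p = k + 1
    if n <= p:
        raise ValueError(f"need n > p ({n} rows, {p} parameters)")
    h = hat_diagonal(X)
    threshold = multiplier * p / n
    flagged = np.flatnonzero(h > threshold)
    if flagged.size == n:
        raise ValueError("every row flagged as high leverage; design is degenerate")
    keep = np.setdiff1d(np.arange(n), flagged)
    model = fit_ols(X[keep], y[keep], names)
    return LeverageReport(leverages=h, flagged=flagged, threshold=threshold, model=model)


def _coef_pvalues(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Two-sided t-test p-values for each slope of the OLS fit [1, X]."""
    n, k = X.shape
    A = np.column_stack([np.ones(n), X])
    beta, _, rank, _ = np.linalg.lstsq(A, y, rcond=None)
    dof = n - rank
    if dof <= 0:
        return np.ones(k)
    resid = y - A @ beta
    sigma2 = float(resid @ resid) / dof
    XtX_inv = np.linalg.pinv(A.T @ A)
    se = np.sqrt(np.maximum(sigma2 * np.diag(XtX_inv), 0.0))[1:]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta[1:] / se, 0.0)
    return 2.0 * stats.t.sf(np.abs(t), dof)


def _is_collinear(candidate: np.ndarray, design: np.ndarray) -> bool:
    """True if candidate lies (numerically) in the span of [1, design]."""
    A = np.column_stack([np.ones(candidate.size), design]) if design.size else np.ones((candidate.size, 1))
    coef, *_ = np.linalg.lstsq(A, candidate, rcond=None)
    resid = candidate - A @ coef
    scale = float(candidate @ candidate) + 1e-300
    return float(resid @ resid) / scale < 1e-12


def stepwise_regression(
    X,
    y,
    alpha_enter: float = 0.15,
    alpha_remove: float = 0.15,
    names: Sequence[str] | None = None,
) -> tuple[LinearModel, list[str]]:
    """Classic forward-backward stepwise OLS on coefficient p-values.

    At each forward step the candidate with the smallest entry p-value is
    added if that p-value is below ``alpha_enter``; after every addition,
    included variables with p-value above ``alpha_remove`` are removed
    (largest first).  Ties break toward the smallest column index.
    Perfectly collinear candidates are treated as having entry p-value 1.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if n <= 2:
        raise ValueError("need n > 2")
    if not (0 < alpha_enter < 1 and 0 < alpha_remove < 1):
        raise ValueError("alphas must lie in (0, 1)")
    if alpha_remove < alpha_enter:
        raise ValueError("alpha_remove must be >= alpha_enter")
    if names is None:
        names = [f"x{i}" for i in range(p)]
    names = list(names)

    selected: list[int] = []
    while True:
        moved = False
        # forward
        candidates = [j for j in range(p) if j not in selected]
        if candidates:
            pvals = []
            for j in candidates:
                if _is_collinear(X[:, j], X[:, selected] if selected else np.empty((n, 0))):
                    pvals.append(1.0)
                    continue
                trial = selected + [j]
                pv = _coef_pvalues(X[:, trial], y)
                pvals.append(float(pv[-1]))
            best = int(np.argmin(pvals))
            if pvals[best] < alpha_enter:
                selected.append(candidates[best])
                moved = True
        # backward
        while len(selected) > 0:
            pv = _coef_pvalues(X[:, selected], y)
            worst = int(np.argmax(pv))
            if pv[worst] > alpha_remove:
                selected.pop(worst)
                moved = True
            else:
                break
        if not moved:
            break
    model = fit_ols(X[:, selected], y, [names[j] for j in selected]) if selected else LinearModel(
        coef=np.zeros(0), intercept=float(y.mean()), names=[], r2=0.0, n=n
    )
    return model, [names[j] for j in selected]


def loo_press_ols(X, y) -> float:
    """PRESS statistic of the OLS fit [1, X] via the leave-one-out identity
    e_i / (1 - h_ii)."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y, dtype=float)
    model = fit_ols(X, y)
    resid = y - model.predict(X)
    h = hat_diagonal(X)
    denom = np.clip(1.0 - h, 1e-12, None)
    return float(np.sum((resid / denom) ** 2))


def fit_metrics(y_true, y_pred, n_params: int, press: Optional[float] = None) -> FitMetrics:
    """Standard regression summary used in every report table.

    ``n_params`` counts slopes only (the intercept is implicit, matching the
    p in R^2_adj = 1 - (1-R^2)(n-1)/(n-p-1)).  ``press`` — the LOO
    prediction sum of squares of the same model family — yields predicted
    R^2 = 1 - PRESS/SST when supplied.  For n <= p+1 the adjusted and
    predicted statistics are undefined and flagged rather than NaN.
    """
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape:
        raise ValueError("length mismatch")
    n = y_true.size
    sse = float(np.sum((y_true - y_pred) ** 2))
    sst = float(np.sum((y_true - y_true.mean()) ** 2))
    r2 = 1.0 - sse / sst if sst > 0 else 0.0
    mue = float(np.mean(np.abs(y_true - y_pred)))
    small = n <= n_params + 1
    r2_adj = None if small else 1.0 - (1.0 - r2) * (n - 1) / (n - n_params - 1)
    s = None if small else float(np.sqrt(sse / (n - n_params - 1)))
    r2_pred = None
    if press is not None and not small and sst > 0:
        r2_pred = 1.0 - press / sst
    return FitMetrics(
        r2=r2, r2_adj=r2_adj, r2_pred=r2_pred, mue=mue, s=s,
        n=n, n_params=n_params, small_sample=small,
    )
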