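"""Partial least squares regression by NIPALS (single response).

X is autoscaled (mean 0, sd 1 per column) and y centered but not scaled —
with a single response the back-transformed coefficients are unaffected by
y scaling.  After each component X is deflated by the extracted score/
loading pair; with a single y the NIPALS inner iteration converges in one
step, so each weight vector is computed directly as X^T y (normalised).
The sign of each weight vector is fixed so its largest-magnitude element
is positive, which makes loadings and loading-based rankings reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "PLSModel",
    "fit_pls",
    "select_ncomp_loo",
    "pls_loading_ranking",
]


@dataclass
class PLSModel:
    n_components: int
    x_weights: np.ndarray    # p x A
    x_loadings: np.ndarray   # p x A
    y_loadings: np.ndarray   # A
    x_mean: np.ndarray
    x_sd: np.ndarray
    y_mean: float
    coef: np.ndarray         # original-scale regression coefficients, p
    intercept: float
    names: list[str] = field(default_factory=list)
    x_variance: np.ndarray = field(default_factory=lambda: np.zeros(0))  # per-component fraction

    def predict(self, X) -> np.ndarray:
        """Predictions through the back-transformed coefficients."""
        return self.intercept + np.asarray(X, dtype=float) @ self.coef

    def predict_latent(self, X) -> np.ndarray:
        """Predictions through the sequential latent-variable path.

        Algebraically identical to :meth:`predict`; kept as an internal
        consistency check of the deflation bookkeeping.
        """
        Z = (np.asarray(X, dtype=float) - self.x_mean) / self.x_sd
        yhat = np.full(Z.shape[0], 0.0)
        for a in range(self.n_components):
            t = Z @ self.x_weights[:, a]
            yhat += self.y_loadings[a] * t
            Z = Z - np.outer(t, self.x_loadings[:, a])
        return yhat + self.y_mean

    @property
    def cumulative_x_variance(self) -> float:
        """Fraction of (autoscaled) X variance captured by the components."""
        return float(np.sum(self.x_variance))


def fit_pls(X, y, n_components: int, names: Sequence[str] | None = None) -> PLSModel:
    """NIPALS PLS1 with autoscaled X and centered y."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, p = X.shape
    if y.size != n:
        raise ValueError("X and y length mismatch")
    if float(np.var(y)) <= 0:
        raise ValueError("response has zero variance")
    x_mean = X.mean(axis=0)
    x_sd = X.std(axis=0, ddof=1)
    if np.any(x_sd <= 0):
        raise ValueError("zero-variance descriptor column; filter before PLS")
    Z0 = (X - x_mean) / x_sd
    rank = np.linalg.matrix_rank(Z0 - Z0.mean(axis=0))
    if n_components > rank:
        raise ValueError(f"requested {n_components} components but achievable rank is {rank}")
    y_mean = float(y.mean())
    u = y - y_mean

    Z = Z0.copy()
    ssx_total = float(np.sum(Z0**2))
    W = np.zeros((p, n_components))
    P = np.zeros((p, n_components))
    q = np.zeros(n_components)
    xvar = np.zeros(n_components)
    for a in range(n_components):
        w = Z.T @ u
        nw = np.linalg.norm(w)
        if nw <= 1e-300:
            raise ValueError(f"component {a + 1}: residual X carries no covariance with y")
        w /= nw
        # sign convention: largest-|.| element positive
        k = int(np.argmax(np.abs(w)))
        if w[k] < 0:
            w = -w
        t = Z @ w
        tt = float(t @ t)
        pvec = Z.T @ t / tt
        qa = float(u @ t / tt)
        Z = Z - np.outer(t, pvec)
        u = u - qa * t
        W[:, a] = w
        P[:, a] = pvec
        q[a] = qa
        xvar[a] = tt * float(pvec @ pvec) / ssx_total

    # B = W (P^T W)^-1 q in autoscaled space
    B = W @ np.linalg.solve(P.T @ W, q)
    coef = B / x_sd
    intercept = y_mean - float(coef @ x_mean)
    return PLSModel(
        n_components=n_components,
        x_weights=W,
        x_loadings=P,
        y_loadings=q,
        x_mean=x_mean,
        x_sd=x_sd,
        y_mean=y_mean,
        coef=coef,
        intercept=intercept,
        names=list(names) if names is not None else [f"x{i}" for i in range(p)],
        x_variance=xvar,
    )


def select_ncomp_loo(X, y, max_comp: int) -> tuple[int, float]:
    """Choose the component count by leave-one-out cross-validated R^2.

    Each fold refits the autoscaling and the PLS model on n-1 samples and
    predicts the held-out one; R^2_cv(k) = 1 - PRESS(k)/SST.  Ties (and
    ``max_comp == 1``) resolve to the smallest k.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n = len(y)
    if n < 5:
        raise ValueError("need at least 5 samples for LOO selection")
    kmax = max(1, int(max_comp))
    press = np.zeros(kmax)
    counts = np.zeros(kmax, dtype=int)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        Xi, yi = X[mask], y[mask]
        sds = Xi.std(axis=0, ddof=1)
        keep = sds > 0
        Zi = Xi[:, keep]
        rank = np.linalg.matrix_rank(Zi - Zi.mean(axis=0))
        k_i = min(kmax, rank)
        model = fit_pls(Zi, yi, k_i)
        # truncated predictions for every k <= k_i from one fitted model
        z = (X[i, keep] - model.x_mean) / model.x_sd
        zres = z.copy()
        yhat = model.y_mean
        for a in range(k_i):
            t = float(zres @ model.x_weights[:, a])
            yhat += model.y_loadings[a] * t
            zres = zres - t * model.x_loadings[:, a]
            press[a] += (y[i] - yhat) ** 2
            counts[a] += 1
        for a in range(k_i, kmax):  # components unavailable in this fold
            press[a] += (y[i] - yhat) ** 2
            counts[a] += 1
    sst = float(np.sum((y - y.mean()) ** 2))
    r2_cv = 1.0 - press / sst
    best = int(np.argmax(r2_cv))  # first maximum -> smallest k on ties
    return best + 1, float(r2_cv[best])


def pls_loading_ranking(models: Sequence[PLSModel], k_components: int = 3) -> list[list[str]]:
    """Rank descriptors by mean |x-loading| per component across models.

    Models fitted to different training splits may disagree on loading sign;
    taking absolute values before averaging makes the ranking sign-invariant.
    Models with fewer than ``k_components`` contribute what they have.
    Returns one descending name list per component.
    """
    if not models:
        raise ValueError("no models given")
    names = models[0].names
    for m in models:
        if m.names != names:
            raise ValueError("models must share descriptor names")
    rankings: list[list[str]] = []
    for comp in range(k_components):
        contributing = [m for m in models if m.n_components > comp]
        if not contributing:
            rankings.append([])
            continue
        mean_abs = np.mean([np.abs(m.x_loadings[:, comp]) for m in contributing], axis=0)
        # descending |loading|, name as deterministic tie-break
        order = sorted(range(len(names)), key=lambda i: (-mean_abs[i], names[i]))
        rankings.append([names[i] for i in order])
    return rankings
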