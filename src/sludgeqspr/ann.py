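"""Bayesian-evidence regularized neural networks with ARD.

A single-hidden-layer perceptron (tanh hidden units, one linear output)
is trained to a maximum-a-posteriori weight vector under a Gaussian prior
whose precision differs per weight *group*: one group per input (all the
first-layer weights fanning out of that input — this is automatic
relevance determination), one for the hidden biases, one for the
hidden-to-output weights and one for the output bias.  The evidence
framework alternates MAP training at fixed hyperparameters with
closed-form re-estimation of the group precisions alpha_g and the noise
precision beta from the Gaussian approximation of the posterior, and
scores each trained network by its log marginal likelihood ("evidence").
Committees keep the top-k networks by evidence and average their outputs.

The curvature matrix uses the Gauss-Newton approximation
A = beta J^T J + diag(alpha), which is positive semidefinite (exact for
the linear test mode) and stable near saddle points; eigenvalues are
floored before inversion and log-determinants.

A testing hook (``linear_mode``) replaces the network with a genuinely
linear map y = b + w.x under the same grouping, for which the whole
procedure has a closed form (Bayesian ridge regression) used as an oracle.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy import optimize

logger = logging.getLogger("sludgeqspr")

__all__ = [
    "NetworkArchitecture",
    "HyperParams",
    "BayesAnnModel",
    "Committee",
    "weight_groups",
    "init_weights",
    "forward",
    "total_error",
    "train_map",
    "gauss_newton_matrix",
    "reestimate_hyperparameters",
    "log_evidence",
    "train_one",
    "train_committee",
    "predict_committee",
    "ard_ranking",
]

ALPHA_FLOOR = 1e-8
ALPHA_CAP = 1e8
BETA_FLOOR = 1e-8
EIG_FLOOR = 1e-10


@dataclass(frozen=True)
class NetworkArchitecture:
    """One hidden tanh layer, single linear output.

    ``linear_mode`` is a testing-only hook replacing the network with the
    identity-activation single-layer map y = b + w.x (same ARD grouping).
    """

    n_inputs: int
    n_hidden: int = 2
    linear_mode: bool = False

    @property
    def n_weights(self) -> int:
        if self.linear_mode:
            return self.n_inputs + 1
        return self.n_hidden * self.n_inputs + 2 * self.n_hidden + 1

    def unpack(self, w: np.ndarray):
        d, h = self.n_inputs, self.n_hidden
        if self.linear_mode:
            return w[:d], float(w[d])
        W1 = w[: h * d].reshape(h, d)
        b1 = w[h * d : h * d + h]
        w2 = w[h * d + h : h * d + 2 * h]
        b2 = float(w[-1])
        return W1, b1, w2, b2


def weight_groups(arch: NetworkArchitecture) -> list[tuple[str, np.ndarray]]:
    """ARD partition of the weight vector: per-input fan-out groups plus
    hidden-bias, output-weight and output-bias groups."""
    d, h = arch.n_inputs, arch.n_hidden
    groups: list[tuple[str, np.ndarray]] = []
    if arch.linear_mode:
        for i in range(d):
            groups.append((f"input_{i}", np.array([i])))
        groups.append(("output_bias", np.array([d])))
        return groups
    for i in range(d):
        groups.append((f"input_{i}", np.arange(h) * d + i))
    groups.append(("hidden_bias", np.arange(h * d, h * d + h)))
    groups.append(("output_weights", np.arange(h * d + h, h * d + 2 * h)))
    groups.append(("output_bias", np.array([h * d + 2 * h])))
    return groups


@dataclass
class HyperParams:
    """Group prior precisions alpha_g (aligned with ``weight_groups``) and
    noise precision beta."""

    alphas: np.ndarray
    beta: float

    def validate(self) -> None:
        if not (np.all(np.isfinite(self.alphas)) and np.all(self.alphas > 0)):
            raise ValueError("all alphas must be finite and positive")
        if not (np.isfinite(self.beta) and self.beta > 0):
            raise ValueError("beta must be finite and positive")

    def alpha_vector(self, arch: NetworkArchitecture) -> np.ndarray:
        vec = np.empty(arch.n_weights)
        for a, (_, idx) in zip(self.alphas, weight_groups(arch)):
            vec[idx] = a
        return vec


@dataclass
class BayesAnnModel:
    architecture: NetworkArchitecture
    w: np.ndarray
    hyper: HyperParams
    log_evidence: float = np.nan
    gamma: np.ndarray = field(default_factory=lambda: np.zeros(0))
    input_names: list[str] = field(default_factory=list)
    trace: list[dict] = field(default_factory=list)

    def predict(self, X) -> np.ndarray:
        return forward(self.architecture, self.w, X)

    @property
    def input_alphas(self) -> np.ndarray:
        """Per-input ARD precisions, in input order."""
        return self.hyper.alphas[: self.architecture.n_inputs]


def init_weights(arch: NetworkArchitecture, rng: np.random.Generator) -> np.ndarray:
    """Zero-mean Gaussian initialization, sd 1/sqrt(fan-in) per layer."""
    d, h = arch.n_inputs, arch.n_hidden
    if arch.linear_mode:
        return rng.normal(0.0, 1.0 / np.sqrt(d + 1), size=d + 1)
    s1 = 1.0 / np.sqrt(d + 1)
    s2 = 1.0 / np.sqrt(h + 1)
    w = np.empty(arch.n_weights)
    w[: h * d + h] = rng.normal(0.0, s1, size=h * d + h)
    w[h * d + h :] = rng.normal(0.0, s2, size=h + 1)
    return w


def forward(arch: NetworkArchitecture, w: np.ndarray, X) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[1] != arch.n_inputs:
        raise ValueError(f"expected {arch.n_inputs} input columns, got {X.shape[1]}")
    if arch.linear_mode:
        wv, b = arch.unpack(np.asarray(w, dtype=float))
        return X @ wv + b
    W1, b1, w2, b2 = arch.unpack(np.asarray(w, dtype=float))
    Z = np.tanh(X @ W1.T + b1)
    return Z @ w2 + b2


def _jacobian(arch: NetworkArchitecture, w: np.ndarray, X: np.ndarray) -> np.ndarray:
    """d yhat / d w, one row per sample (Gauss-Newton building block)."""
    n = X.shape[0]
    if arch.linear_mode:
        return np.column_stack([X, np.ones(n)])
    W1, b1, w2, _ = arch.unpack(w)
    h, d = W1.shape
    Z = np.tanh(X @ W1.T + b1)
    dZ = (1.0 - Z**2) * w2  # n x h
    J = np.empty((n, arch.n_weights))
    J[:, : h * d] = (dZ[:, :, None] * X[:, None, :]).reshape(n, h * d)
    J[:, h * d : h * d + h] = dZ
    J[:, h * d + h : h * d + 2 * h] = Z
    J[:, -1] = 1.0
    return J


def total_error(
    arch: NetworkArchitecture,
    w: np.ndarray,
    X: np.ndarray,
    y: np.ndarray,
    hyper: HyperParams,
) -> tuple[float, np.ndarray]:
    """Regularized error beta*E_D + sum_g alpha_g*E_W(g) and its exact gradient.

    E_D = 1/2 sum (y - yhat)^2, E_W(g) = 1/2 sum_{w in g} w^2; the data-term
    gradient comes from back-propagation.
    """
    w = np.asarray(w, dtype=float)
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    alpha_vec = hyper.alpha_vector(arch)
    if arch.linear_mode:
        wv, b = arch.unpack(w)
        r = X @ wv + b - y
        grad = np.empty_like(w)
        grad[: arch.n_inputs] = hyper.beta * (X.T @ r)
        grad[-1] = hyper.beta * r.sum()
    else:
        W1, b1, w2, b2 = arch.unpack(w)
        h, d = W1.shape
        Z = np.tanh(X @ W1.T + b1)
        r = Z @ w2 + b2 - y
        D = hyper.beta * (r[:, None] * w2) * (1.0 - Z**2)  # n x h
        grad = np.empty_like(w)
        grad[: h * d] = (D.T @ X).ravel()
        grad[h * d : h * d + h] = D.sum(axis=0)
        grad[h * d + h : h * d + 2 * h] = hyper.beta * (Z.T @ r)
        grad[-1] = hyper.beta * r.sum()
    E_D = 0.5 * float(r @ r)
    E_W = 0.5 * alpha_vec * w**2
    E = hyper.beta * E_D + float(E_W.sum())
    grad = grad + alpha_vec * w
    return E, grad


def data_and_prior_terms(
    arch: NetworkArchitecture, w: np.ndarray, X: np.ndarray, y: np.ndarray
) -> tuple[float, np.ndarray]:
    """(E_D, per-group E_W) at ``w``."""
    r = forward(arch, w, X) - y
    E_D = 0.5 * float(r @ r)
    E_W = np.array([0.5 * float(w[idx] @ w[idx]) for _, idx in weight_groups(arch)])
    return E_D, E_W


def train_map(
    arch: NetworkArchitecture,
    w0: np.ndarray,
    X: np.ndarray,
    y: np.ndarray,
    hyper: HyperParams,
    max_iter: int = 100,
    gtol: float = 1e-6,
) -> tuple[np.ndarray, list[float]]:
    """Deterministic conjugate-gradient MAP training at fixed hyperparameters.

    Returns the optimized weights and the error trace at accepted iterates
    (nonincreasing by the line-search contract).  Aborts if the error goes
    non-finite.
    """
    hyper.validate()
    trace: list[float] = [total_error(arch, w0, X, y, hyper)[0]]

    if arch.linear_mode:
        # the MAP problem is an exact quadratic: solve it in closed form
        Phi = _jacobian(arch, np.asarray(w0, dtype=float), np.asarray(X, dtype=float))
        A = hyper.beta * (Phi.T @ Phi) + np.diag(hyper.alpha_vector(arch))
        w = hyper.beta * np.linalg.solve(A, Phi.T @ np.asarray(y, dtype=float))
        trace.append(total_error(arch, w, X, y, hyper)[0])
        if trace[-1] > trace[0]:
            return np.asarray(w0, dtype=float), trace
        return w, trace

    def fun(w):
        E, g = total_error(arch, w, X, y, hyper)
        if not np.isfinite(E):
            raise FloatingPointError("non-finite error during MAP training")
        return E, g

    def cb(wk):
        trace.append(total_error(arch, wk, X, y, hyper)[0])

    res = optimize.minimize(
        fun, np.asarray(w0, dtype=float), jac=True, method="CG",
        options={"maxiter": max_iter, "gtol": gtol}, callback=cb,
    )
    w = res.x
    if trace[-1] > trace[0]:
        w = np.asarray(w0, dtype=float)  # never accept an uphill result
    return w, trace


def gauss_newton_matrix(
    arch: NetworkArchitecture,
    w: np.ndarray,
    X: np.ndarray,
    hyper: HyperParams,
) -> np.ndarray:
    """A = beta J^T J + diag(alpha): Gauss-Newton posterior curvature."""
    J = _jacobian(arch, np.asarray(w, dtype=float), np.asarray(X, dtype=float))
    return hyper.beta * (J.T @ J) + np.diag(hyper.alpha_vector(arch))


def _floored_eigh(A: np.ndarray) -> tuple[np.ndarray, np.ndarray, bool]:
    vals, vecs = np.linalg.eigh(A)
    floored = bool(np.any(vals < EIG_FLOOR))
    return np.maximum(vals, EIG_FLOOR), vecs, floored


def reestimate_hyperparameters(
    arch: NetworkArchitecture,
    w: np.ndarray,
    X: np.ndarray,
    y: np.ndarray,
    hyper: HyperParams,
) -> tuple[HyperParams, np.ndarray, dict]:
    """Evidence-framework update of (alpha_g, beta) at a MAP point.

    gamma_g = |g| - alpha_g * trace_g(A^-1) counts the well-determined
    parameters in group g; then alpha_g <- gamma_g / 2 E_W(g) and
    beta <- (N - sum gamma) / 2 E_D.  All updates are clamped to
    [1e-8, 1e8] so they stay positive and finite.
    """
    groups = weight_groups(arch)
    A = gauss_newton_matrix(arch, w, X, hyper)
    vals, vecs, floored = _floored_eigh(A)
    Ainv_diag = np.sum(vecs**2 / vals, axis=1)
    E_D, E_W = data_and_prior_terms(arch, w, X, y)
    N = len(y)
    gamma = np.empty(len(groups))
    new_alphas = np.empty(len(groups))
    for g, (_, idx) in enumerate(groups):
        tr = float(np.sum(Ainv_diag[idx]))
        gamma[g] = np.clip(len(idx) - hyper.alphas[g] * tr, 0.0, len(idx))
        new_alphas[g] = np.clip(gamma[g] / max(2.0 * E_W[g], 1e-300), ALPHA_FLOOR, ALPHA_CAP)
    new_beta = float(np.clip((N - gamma.sum()) / max(2.0 * E_D, 1e-300), BETA_FLOOR, ALPHA_CAP))
    info = {"eig_floored": floored, "E_D": E_D, "E_W": E_W, "gamma": gamma.copy()}
    if floored:
        logger.debug("curvature eigenvalues floored at %.1e during re-estimation", EIG_FLOOR)
    return HyperParams(alphas=new_alphas, beta=new_beta), gamma, info


def log_evidence(
    arch: NetworkArchitecture,
    w: np.ndarray,
    X: np.ndarray,
    y: np.ndarray,
    hyper: HyperParams,
) -> float:
    """Gaussian-approximation log marginal likelihood of the trained network."""
    groups = weight_groups(arch)
    E_D, E_W = data_and_prior_terms(arch, w, X, y)
    A = gauss_newton_matrix(arch, w, X, hyper)
    vals, _, _ = _floored_eigh(A)
    N = len(y)
    return float(
        -hyper.beta * E_D
        - float(hyper.alphas @ E_W)
        - 0.5 * float(np.sum(np.log(vals)))
        + 0.5 * sum(len(idx) * np.log(hyper.alphas[g]) for g, (_, idx) in enumerate(groups))
        + 0.5 * N * np.log(hyper.beta)
        - 0.5 * N * np.log(2.0 * np.pi)
    )


def train_one(
    X,
    y,
    architecture: NetworkArchitecture,
    seed,
    outer_loops: int = 8,
    inner_iters: int = 100,
    gtol: float = 1e-6,
    alpha_init: float = 0.01,
    beta_init: Optional[float] = None,
    input_names: Sequence[str] | None = None,
) -> BayesAnnModel:
    """Full evidence-framework training of one network.

    An initial MAP fit at the starting hyperparameters is followed by
    ``outer_loops`` alternations of hyperparameter re-estimation and MAP
    retraining (``outer_loops=0`` therefore yields the plain MAP fit).
    Inputs are expected standardized and targets centered by the caller.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    rng = np.random.default_rng(seed)
    groups = weight_groups(architecture)
    if beta_init is None:
        v = float(np.var(y))
        beta_init = 1.0 / v if v > 0 else 1.0
    hyper = HyperParams(alphas=np.full(len(groups), float(alpha_init)), beta=float(beta_init))
    w = init_weights(architecture, rng)

    trace: list[dict] = []
    w, err_trace = train_map(architecture, w, X, y, hyper, inner_iters, gtol)
    gamma = np.zeros(len(groups))
    for outer in range(outer_loops):
        hyper, gamma, info = reestimate_hyperparameters(architecture, w, X, y, hyper)
        w, err_trace = train_map(architecture, w, X, y, hyper, inner_iters, gtol)
        E_D, E_W = data_and_prior_terms(architecture, w, X, y)
        trace.append(
            {
                "outer": outer + 1,
                "E_D": E_D,
                "E_W_total": float(E_W.sum()),
                "gamma": gamma.copy(),
                "gamma_total": float(gamma.sum()),
                "alphas": hyper.alphas.copy(),
                "beta": hyper.beta,
                "eig_floored": info["eig_floored"],
            }
        )
    ev = log_evidence(architecture, w, X, y, hyper)
    # report gamma at the final (w, alpha, beta) without touching the model
    _, gamma, _ = reestimate_hyperparameters(architecture, w, X, y, hyper)
    return BayesAnnModel(
        architecture=architecture,
        w=w,
        hyper=hyper,
        log_evidence=ev,
        gamma=gamma,
        input_names=list(input_names or []),
        trace=trace,
    )


@dataclass
class Committee:
    """Trained replicas differing only by initialization seed; the top-k by
    log evidence are averaged for prediction."""

    members: list[BayesAnnModel]
    selected: list[int]
    k: int
    y_mean: float = 0.0
    standardizer: object = None  # optional preprocess.Standardizer

    @property
    def selected_members(self) -> list[BayesAnnModel]:
        return [self.members[i] for i in self.selected]

    def predict(self, X) -> np.ndarray:
        return predict_committee(self, X)

    def predict_from_raw(self, X_raw) -> np.ndarray:
        if self.standardizer is None:
            raise ValueError("committee has no stored standardizer")
        return self.predict(self.standardizer.transform(np.asarray(X_raw, dtype=float)))


def train_committee(
    X,
    y,
    architecture: NetworkArchitecture,
    n_networks: int,
    k: int,
    seed,
    **train_kwargs,
) -> Committee:
    """Train ``n_networks`` independently seeded replicas, keep the best ``k``.

    Members failing to train (non-finite error) are logged and excluded;
    an error is raised only if fewer than ``k`` survive.  Evidence ties
    break by seed order.
    """
    if k > n_networks:
        raise ValueError("committee size k cannot exceed n_networks")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = ss.spawn(n_networks)
    members: list[BayesAnnModel] = []
    for i, child in enumerate(children):
        try:
            members.append(train_one(X, y, architecture, child, **train_kwargs))
        except FloatingPointError as exc:  # pragma: no cover - rare path
            logger.warning("committee member %d failed to train: %s", i, exc)
    if len(members) < k:
        raise RuntimeError(f"only {len(members)} of {n_networks} members trained; need {k}")
    order = sorted(range(len(members)), key=lambda i: (-members[i].log_evidence, i))
    return Committee(members=members, selected=order[:k], k=k)


def predict_committee(committee: Committee, X, return_spread: bool = False):
    """Arithmetic mean of the selected members' predictions.

    With ``return_spread=True`` also returns the per-point (min, max) over
    members.
    """
    if not committee.selected:
        raise ValueError("empty committee")
    preds = np.stack([m.predict(X) for m in committee.selected_members])
    mean = preds.mean(axis=0) + committee.y_mean
    if return_spread:
        return mean, preds.min(axis=0) + committee.y_mean, preds.max(axis=0) + committee.y_mean
    return mean


def ard_ranking(committee: Committee, names: Sequence[str] | None = None) -> list[str]:
    """Descriptor relevance: rank inputs by ascending ARD precision within
    each selected member, then order by mean rank (ties by name)."""
    members = committee.selected_members
    if not members:
        raise ValueError("empty committee")
    d = members[0].architecture.n_inputs
    if names is None:
        names = members[0].input_names or [f"x{i}" for i in range(d)]
    names = list(names)
    if len(names) != d:
        raise ValueError("name list does not match input count")
    rank_sum = np.zeros(d)
    for m in members:
        if m.architecture.n_inputs != d:
            raise ValueError("committee members disagree on input count")
        alphas = m.input_alphas
        order = sorted(range(d), key=lambda i: (alphas[i], names[i]))
        for r, i in enumerate(order):
            rank_sum[i] += r + 1
    mean_rank = rank_sum / len(members)
    final = sorted(range(d), key=lambda i: (mean_rank[i], names[i]))
    return [names[i] for i in final]
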