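"""Descriptor-matrix reduction: CV filter, unsupervised forward selection.

Variable reduction is unsupervised — it never looks at the response — and
therefore leakage-safe when fitted on a training split.  The coefficient-
of-variation filter drops near-constant descriptors; unsupervised forward
selection (UFS) then builds a subset with minimal multiple correlation:
start from the two variables with the smallest absolute pairwise
correlation and repeatedly add the candidate whose squared multiple
correlation (R^2) with the already-selected set is smallest, while that
R^2 stays below a cut-off.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .datatypes import DescriptorTable

__all__ = [
    "ReductionReport",
    "Standardizer",
    "cv_filter",
    "ufs_select",
    "reduce_descriptors",
    "fit_standardizer",
    "apply_standardizer",
]

_MEAN_TOL = 1e-12


class StopReason(str, enum.Enum):
    R2_MAX_REACHED = "r2_max_reached"
    EXHAUSTED = "exhausted"


@dataclass
class ReductionReport:
    removed_by_cv: list[str]
    ufs_order: list[str]
    ufs_r2_at_selection: list[float]
    stop_reason: StopReason

    def __post_init__(self) -> None:
        overlap = set(self.removed_by_cv) & set(self.ufs_order)
        if overlap:
            raise ValueError(f"columns both CV-removed and UFS-selected: {overlap}")


def cv_filter(table: DescriptorTable, threshold: float = 0.05) -> tuple[DescriptorTable, list[str]]:
    """Drop descriptors whose coefficient of variation |sd/mean| is below threshold.

    Columns with mean indistinguishable from zero are kept (their CV is
    effectively infinite) unless their sd is also ~0, i.e. the column is
    constant, in which case they are removed.
    """
    if len(table) == 0:
        raise ValueError("table is empty")
    X = table.values
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=1) if len(table) > 1 else np.zeros(X.shape[1])
    removed = []
    for name, m, s in zip(table.descriptor_names, means, sds):
        if abs(m) < _MEAN_TOL:
            if s < _MEAN_TOL:
                removed.append(name)  # constant ~0 column
        elif s / abs(m) < threshold:
            removed.append(name)
    kept = [n for n in table.descriptor_names if n not in removed]
    return table.with_descriptors(kept), removed


def _multiple_r2(candidate: np.ndarray, selected: np.ndarray) -> float:
    """R^2 of the least-squares regression of candidate on selected (with intercept)."""
    y = candidate - candidate.mean()
    sst = float(y @ y)
    if sst <= 0:
        return 1.0  # constant candidate is perfectly 'explained'
    Xc = selected - selected.mean(axis=0)
    coef, *_ = np.linalg.lstsq(Xc, y, rcond=None)
    resid = y - Xc @ coef
    r2 = 1.0 - float(resid @ resid) / sst
    return min(max(r2, 0.0), 1.0)


def ufs_select(
    X: np.ndarray,
    names: Sequence[str] | None = None,
    r2_max: float = 0.99,
) -> ReductionReport:
    """Unsupervised forward selection on the columns of ``X``.

    Ties in the selection criteria are broken toward the smallest column
    index, so the procedure is deterministic.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("UFS needs a matrix with at least two columns")
    p = X.shape[1]
    if names is None:
        names = [f"x{i}" for i in range(p)]
    names = list(names)
    sds = X.std(axis=0, ddof=1)
    if np.any(sds <= 0):
        bad = [names[i] for i in np.flatnonzero(sds <= 0)]
        raise ValueError(f"zero-variance column(s) {bad}; apply cv_filter first")

    corr = np.corrcoef(X, rowvar=False)
    abs_corr = np.abs(corr)
    # initial pair: smallest |corr|, lexicographically smallest (i, j) on ties
    best = (np.inf, -1, -1)
    for i in range(p):
        for j in range(i + 1, p):
            if abs_corr[i, j] < best[0]:
                best = (abs_corr[i, j], i, j)
    _, i0, j0 = best
    selected = [i0, j0]
    r2_trace = [0.0, float(abs_corr[i0, j0] ** 2)]
    remaining = [k for k in range(p) if k not in selected]
    stop = StopReason.EXHAUSTED
    while remaining:
        S = X[:, selected]
        r2s = np.array([_multiple_r2(X[:, k], S) for k in remaining])
        pick = int(np.argmin(r2s))  # argmin takes the first minimum: smallest index
        if r2s[pick] >= r2_max:
            stop = StopReason.R2_MAX_REACHED
            break
        selected.append(remaining[pick])
        r2_trace.append(float(r2s[pick]))
        remaining.pop(pick)
    return ReductionReport(
        removed_by_cv=[],
        ufs_order=[names[i] for i in selected],
        ufs_r2_at_selection=r2_trace,
        stop_reason=stop,
    )


def reduce_descriptors(
    table: DescriptorTable,
    cv_threshold: float = 0.05,
    ufs_r2_max: float = 0.99,
) -> tuple[DescriptorTable, ReductionReport]:
    """CV filter followed by UFS; the standard reduction pipeline."""
    filtered, removed = cv_filter(table, cv_threshold)
    report = ufs_select(filtered.values, filtered.descriptor_names, ufs_r2_max)
    report.removed_by_cv = removed
    return table.with_descriptors(report.ufs_order), report


@dataclass
class Standardizer:
    """Column means/sds learned on training data only."""

    means: np.ndarray
    sds: np.ndarray
    names: list[str] = field(default_factory=list)

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return (X - self.means) / self.sds

    def inverse(self, Z: np.ndarray) -> np.ndarray:
        return np.asarray(Z, dtype=float) * self.sds + self.means


def fit_standardizer(X_train: np.ndarray, names: Sequence[str] | None = None) -> Standardizer:
    X = np.asarray(X_train, dtype=float)
    sds = X.std(axis=0, ddof=1)
    if np.any(sds <= 0):
        idx = np.flatnonzero(sds <= 0)
        label = [names[i] for i in idx] if names is not None else list(idx)
        raise ValueError(f"zero-variance column(s) {label}; run cv_filter before standardizing")
    return Standardizer(means=X.mean(axis=0), sds=sds, names=list(names or []))


def apply_standardizer(s: Standardizer, X: np.ndarray) -> np.ndarray:
    return s.transform(X)
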