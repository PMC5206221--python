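"""Experiment orchestration: the study protocols end to end.

The protocols mirrored here: per-charge-class univariate log K_d ~
log K_ow models with leverage screening; five independent random
train/test (237/60) divisions of the pooled measurements; per-split
variable reduction, PLS with LOO-selected component count, and
evidence-framework ANN committees; and production models refit on the
full dataset once generalization error has been estimated.

Within each split everything that learns from data — CV filter, UFS,
standardization, component selection, hyperparameter re-estimation — sees
training rows only.  A ``global_reduction`` option reduces variables once
on the full table instead, reproducing the simpler historical protocol at
the cost of (mild, unsupervised) information sharing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import ann as annmod
from .datatypes import ChargeClass, DescriptorTable, RunConfig, substream
from .io import stage_log
from .linear import (
    LeverageReport,
    UnivariateModel,
    fit_metrics,
    fit_univariate,
    leverage_filter_refit,
)
from .pls import PLSModel, fit_pls, select_ncomp_loo
from .preprocess import fit_standardizer, reduce_descriptors

__all__ = [
    "SplitPlan",
    "ExperimentReport",
    "make_splits",
    "run_univariate_experiment",
    "run_pls_experiment",
    "run_ann_experiment",
    "train_production_models",
]


@dataclass
class SplitPlan:
    n_total: int
    n_test: int
    n_splits: int
    test_sets: list[np.ndarray]
    level: str = "measurement"
    seed: int = 0
    exact_size: bool = True  # False when compound-level grouping forced a nearby size

    def train_index(self, s: int) -> np.ndarray:
        return np.setdiff1d(np.arange(self.n_total), self.test_sets[s])

    def test_index(self, s: int) -> np.ndarray:
        return self.test_sets[s]


@dataclass
class ExperimentReport:
    """Per-split rows plus mean/sd aggregate, Table-style."""

    rows: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    _STAT_COLS = ("components", "hidden_nodes", "variance", "mue_train", "mue_test",
                  "r2_train", "r2_cv", "r2_test")

    def aggregate(self) -> pd.DataFrame:
        stat_cols = [c for c in self.rows.columns if c in self._STAT_COLS]
        group_cols = [c for c in ("hidden_nodes",) if c in self.rows.columns]
        if group_cols:
            g = self.rows.groupby(group_cols)[[c for c in stat_cols if c not in group_cols]]
            out = pd.concat({"mean": g.mean(), "sd": g.std(ddof=1)}, names=["stat"])
            return out.reset_index()
        agg = self.rows[stat_cols].agg(["mean", "std"])
        agg.index = ["mean", "sd"]
        return agg

    def to_csv(self, path) -> None:
        self.rows.to_csv(path, index=False)


def make_splits(
    n_total: int,
    n_test: int,
    n_splits: int,
    level: str = "measurement",
    seed: int = 0,
    compound_ids: Optional[Sequence[str]] = None,
) -> SplitPlan:
    """Independent uniform train/test divisions (no stratification).

    ``level="compound"`` keeps all measurements of a compound on one side;
    the test set then gets as close to ``n_test`` measurements as the
    compound grouping allows, flagged via ``exact_size``.
    """
    if not (0 < n_test < n_total):
        raise ValueError("need 0 < n_test < n_total")
    rng = np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=(2,)))
    test_sets = []
    exact = True
    if level == "measurement":
        for _ in range(n_splits):
            test_sets.append(np.sort(rng.choice(n_total, size=n_test, replace=False)))
    elif level == "compound":
        if compound_ids is None:
            raise ValueError("compound-level splits need compound_ids")
        ids = np.asarray(compound_ids)
        if ids.size != n_total:
            raise ValueError("compound_ids length must equal n_total")
        unique = pd.unique(ids)
        for _ in range(n_splits):
            order = rng.permutation(len(unique))
            chosen: list[str] = []
            size = 0
            for ui in order:
                cnt = int(np.sum(ids == unique[ui]))
                if abs(size + cnt - n_test) <= abs(size - n_test):
                    chosen.append(unique[ui])
                    size += cnt
                if size >= n_test:
                    break
            idx = np.flatnonzero(np.isin(ids, chosen))
            if idx.size != n_test:
                exact = False
            test_sets.append(np.sort(idx))
    else:
        raise ValueError(f"unknown split level {level!r}")
    if not exact:
        stage_log("split", note="compound-level split sizes approximate", n_test=n_test)
    return SplitPlan(n_total, n_test, n_splits, test_sets, level, seed, exact)


def run_univariate_experiment(
    table: DescriptorTable,
    predictor: str = "log_kow",
    leverage_multiplier: float = 3.0,
) -> dict[str, dict]:
    """Per-class and pooled univariate models with leverage screening.

    Returns a mapping class-name -> {"model": UnivariateModel,
    "leverage": LeverageReport} including the key ``"combined"``.
    Classes with fewer than 3 measurements are skipped with a warning.
    """
    if predictor not in table.meta.columns:
        raise ValueError(f"predictor {predictor!r} not in table metadata")
    out: dict[str, dict] = {}

    def one(name: str, sub: DescriptorTable):
        x = sub.meta[predictor].to_numpy(dtype=float)
        y = sub.y
        model = fit_univariate(x, y, predictor, name)
        lev: Optional[LeverageReport] = None
        if len(sub) > 2:
            try:
                lev = leverage_filter_refit(x[:, None], y, leverage_multiplier, [predictor])
            except ValueError:
                lev = None
        out[name] = {"model": model, "leverage": lev}

    for cls in ChargeClass:
        sub = table.subset(table.meta["charge_class"] == cls.value)
        if len(sub) < 3:
            if len(sub):
                stage_log("univariate", skipped_class=cls.value, n=len(sub))
            continue
        one(cls.value, sub)
    one("combined", table)
    return out


def _prepare_split(table: DescriptorTable, train_idx, test_idx, config: RunConfig):
    """Reduce + standardize using training rows only (or globally if asked)."""
    if config.global_reduction:
        reduced, _ = reduce_descriptors(table, config.cv_threshold, config.ufs_r2_max)
        names = reduced.descriptor_names
    else:
        train_tab = table.subset(train_idx)
        reduced_train, _ = reduce_descriptors(train_tab, config.cv_threshold, config.ufs_r2_max)
        names = reduced_train.descriptor_names
    X = table.with_descriptors(names).values
    y = table.y
    Xtr, ytr = X[train_idx], y[train_idx]
    Xte, yte = X[test_idx], y[test_idx]
    std = fit_standardizer(Xtr, names)
    return std.transform(Xtr), ytr, std.transform(Xte), yte, names, std


def run_pls_experiment(
    table: DescriptorTable,
    splits: SplitPlan,
    config: RunConfig,
) -> tuple[ExperimentReport, list[PLSModel]]:
    """Five-split PLS protocol: per split, reduce on train, pick the
    component count by LOO R^2_cv, fit, and report train/test MUE and R^2."""
    rows = []
    models = []
    for s in range(splits.n_splits):
        tr, te = splits.train_index(s), splits.test_index(s)
        Ztr, ytr, Zte, yte, names, _ = _prepare_split(table, tr, te, config)
        ncomp, r2_cv = select_ncomp_loo(Ztr, ytr, config.max_pls_components)
        model = fit_pls(Ztr, ytr, ncomp, names)
        mtr = fit_metrics(ytr, model.predict(Ztr), n_params=ncomp)
        mte = fit_metrics(yte, model.predict(Zte), n_params=ncomp)
        rows.append(
            {
                "split": s + 1,
                "components": ncomp,
                "variance": model.cumulative_x_variance,
                "mue_train": mtr.mue,
                "mue_test": mte.mue,
                "r2_train": mtr.r2,
                "r2_cv": r2_cv,
                "r2_test": mte.r2,
            }
        )
        models.append(model)
        stage_log("pls_split", split=s + 1, ncomp=ncomp, r2_test=round(mte.r2, 3))
    report = ExperimentReport(pd.DataFrame(rows), {"method": "pls", "seed": splits.seed})
    return report, models


def run_ann_experiment(
    table: DescriptorTable,
    splits: SplitPlan,
    config: RunConfig,
    hidden_range: Optional[Sequence[int]] = None,
) -> tuple[ExperimentReport, dict[tuple[int, int], annmod.Committee]]:
    """Five-split ANN committee protocol, one report block per hidden-node
    count.  Targets are centered on the training mean; committee means are
    un-centered before scoring."""
    hidden_range = tuple(hidden_range) if hidden_range is not None else config.hidden_nodes
    rows = []
    committees: dict[tuple[int, int], annmod.Committee] = {}
    for s in range(splits.n_splits):
        tr, te = splits.train_index(s), splits.test_index(s)
        Ztr, ytr, Zte, yte, names, std = _prepare_split(table, tr, te, config)
        y_mean = float(ytr.mean())
        for h in hidden_range:
            arch = annmod.NetworkArchitecture(n_inputs=Ztr.shape[1], n_hidden=h)
            seed_seq = np.random.SeedSequence(
                entropy=int(config.master_seed), spawn_key=(3, s, h)
            )
            committee = annmod.train_committee(
                Ztr, ytr - y_mean, arch, config.n_networks, config.committee_size,
                seed_seq, outer_loops=config.outer_loops, input_names=names,
            )
            committee.y_mean = y_mean
            committee.standardizer = std
            mtr = fit_metrics(ytr, committee.predict(Ztr), n_params=h)
            mte = fit_metrics(yte, committee.predict(Zte), n_params=h)
            rows.append(
                {
                    "split": s + 1,
                    "hidden_nodes": h,
                    "mue_train": mtr.mue,
                    "mue_test": mte.mue,
                    "r2_train": mtr.r2,
                    "r2_test": mte.r2,
                }
            )
            committees[(s, h)] = committee
            stage_log("ann_split", split=s + 1, hidden=h, r2_test=round(mte.r2, 3))
    report = ExperimentReport(pd.DataFrame(rows), {"method": "ann", "seed": splits.seed})
    return report, committees


def train_production_models(
    table: DescriptorTable,
    config: RunConfig,
    hidden_nodes: int = 2,
) -> dict:
    """Final models refit on the entire dataset, same protocols.

    No data is held out, so the reported R^2/MUE are *fit* statistics, not
    predictive estimates — generalization error is what the split
    experiments measured.
    """
    reduced, report = reduce_descriptors(table, config.cv_threshold, config.ufs_r2_max)
    names = reduced.descriptor_names
    X, y = reduced.values, table.y
    std = fit_standardizer(X, names)
    Z = std.transform(X)

    ncomp, r2_cv = select_ncomp_loo(Z, y, config.max_pls_components)
    pls_model = fit_pls(Z, y, ncomp, names)
    pls_fit = fit_metrics(y, pls_model.predict(Z), n_params=ncomp)

    y_mean = float(y.mean())
    arch = annmod.NetworkArchitecture(n_inputs=Z.shape[1], n_hidden=hidden_nodes)
    committee = annmod.train_committee(
        Z, y - y_mean, arch, config.n_networks, config.committee_size,
        np.random.SeedSequence(entropy=int(config.master_seed), spawn_key=(3, 99, hidden_nodes)),
        outer_loops=config.outer_loops, input_names=names,
    )
    committee.y_mean = y_mean
    committee.standardizer = std
    ann_fit = fit_metrics(y, committee.predict(Z), n_params=hidden_nodes)

    stage_log("production", ncomp=ncomp, pls_r2=round(pls_fit.r2, 3), ann_r2=round(ann_fit.r2, 3))
    return {
        "pls": pls_model,
        "pls_fit": pls_fit,
        "pls_ncomp": ncomp,
        "pls_r2_cv": r2_cv,
        "committee": committee,
        "ann_fit": ann_fit,
        "standardizer": std,
        "reduction": report,
        "names": names,
    }
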