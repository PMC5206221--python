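"""Reading/writing the package's file formats.

Descriptor tables travel as plain CSV (UTF-8, header row mandatory):
reserved metadata columns plus any number of numeric descriptor columns.
Models are serialized to JSON through a small kind-tagged registry so a
round trip reproduces predictions exactly.
"""

from __future__ import annotations

import json
import logging
import sys
from typing import Optional

import numpy as np
import pandas as pd

from .ann import BayesAnnModel, Committee, HyperParams, NetworkArchitecture
from .datatypes import RESERVED_COLUMNS, REQUIRED_COLUMNS, DescriptorTable, FormatError
from .linear import LinearModel, UnivariateModel
from .pls import PLSModel
from .preprocess import Standardizer

logger = logging.getLogger("sludgeqspr")

__all__ = [
    "read_descriptor_table",
    "write_descriptor_table",
    "read_model",
    "write_model",
    "SerializationError",
    "configure_logging",
    "stage_log",
]


class SerializationError(ValueError):
    pass


def configure_logging(level: str = "INFO", logfile: Optional[str] = None) -> None:
    handlers: list[logging.Handler] = [logging.StreamHandler(sys.stderr)]
    if logfile:
        handlers.append(logging.FileHandler(logfile))
    fmt = logging.Formatter("%(asctime)s %(levelname)s %(message)s")
    logger.setLevel(level.upper())
    logger.handlers.clear()
    for h in handlers:
        h.setFormatter(fmt)
        logger.addHandler(h)


def stage_log(stage: str, **info) -> None:
    """One structured line per pipeline stage."""
    payload = " ".join(f"{k}={v}" for k, v in info.items())
    logger.info("stage=%s %s", stage, payload)


def read_descriptor_table(path, missing_policy: str = "error") -> DescriptorTable:
    """Load a descriptor-table CSV.

    Rows with missing log_kd are always dropped (and counted in the log).
    Missing or non-numeric descriptor cells are handled per
    ``missing_policy``: ``"drop-row"``, ``"drop-column"`` or ``"error"``.
    """
    if missing_policy not in ("drop-row", "drop-column", "error"):
        raise ValueError(f"unknown missing_policy {missing_policy!r}")
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"missing required column(s): {', '.join(missing)}")

    n0 = len(df)
    df = df[pd.to_numeric(df["log_kd"], errors="coerce").notna()].reset_index(drop=True)
    if len(df) < n0:
        stage_log("load", dropped_missing_log_kd=n0 - len(df), path=str(path))

    desc_cols = [c for c in df.columns if c not in RESERVED_COLUMNS]
    desc = df[desc_cols].apply(pd.to_numeric, errors="coerce") if desc_cols else df[[]]
    if desc_cols:
        bad_mask = desc.isna()
        if bad_mask.to_numpy().any():
            if missing_policy == "error":
                r, c = np.argwhere(bad_mask.to_numpy())[0]
                raise FormatError(
                    f"non-numeric or missing descriptor cell at row {int(r)}, "
                    f"column {desc_cols[int(c)]!r}"
                )
            if missing_policy == "drop-column":
                keep = [c for c in desc_cols if not bad_mask[c].any()]
                stage_log("load", dropped_columns=len(desc_cols) - len(keep), path=str(path))
                desc = desc[keep]
            else:  # drop-row
                keep_rows = ~bad_mask.any(axis=1)
                stage_log("load", dropped_rows=int((~keep_rows).sum()), path=str(path))
                df = df[keep_rows.to_numpy()].reset_index(drop=True)
                desc = desc[keep_rows.to_numpy()].reset_index(drop=True)

    meta_cols = [c for c in df.columns if c in RESERVED_COLUMNS]
    table = DescriptorTable(df[meta_cols], desc, provenance=str(path))
    stage_log("load", rows=len(table), descriptors=len(table.descriptor_names), path=str(path))
    return table


def write_descriptor_table(table: DescriptorTable, path) -> None:
    table.to_frame().to_csv(path, index=False)


# --------------------------------------------------------------------------
# model (de)serialization registry
# --------------------------------------------------------------------------

def _arr(x) -> list:
    return np.asarray(x, dtype=float).tolist()


def _univariate_to_dict(m: UnivariateModel) -> dict:
    return {
        "slope": m.slope, "intercept": m.intercept, "r2": m.r2, "n": m.n,
        "predictor_name": m.predictor_name, "charge_class": m.charge_class,
    }


def _linear_to_dict(m: LinearModel) -> dict:
    return {"coef": _arr(m.coef), "intercept": m.intercept, "names": m.names,
            "r2": m.r2, "n": m.n}


def _pls_to_dict(m: PLSModel) -> dict:
    return {
        "n_components": m.n_components,
        "x_weights": _arr(m.x_weights), "x_loadings": _arr(m.x_loadings),
        "y_loadings": _arr(m.y_loadings),
        "x_mean": _arr(m.x_mean), "x_sd": _arr(m.x_sd), "y_mean": m.y_mean,
        "coef": _arr(m.coef), "intercept": m.intercept,
        "names": m.names, "x_variance": _arr(m.x_variance),
    }


def _pls_from_dict(d: dict) -> PLSModel:
    return PLSModel(
        n_components=d["n_components"],
        x_weights=np.array(d["x_weights"]), x_loadings=np.array(d["x_loadings"]),
        y_loadings=np.array(d["y_loadings"]),
        x_mean=np.array(d["x_mean"]), x_sd=np.array(d["x_sd"]), y_mean=d["y_mean"],
        coef=np.array(d["coef"]), intercept=d["intercept"],
        names=list(d["names"]), x_variance=np.array(d["x_variance"]),
    )


def _ann_to_dict(m: BayesAnnModel) -> dict:
    return {
        "architecture": {
            "n_inputs": m.architecture.n_inputs,
            "n_hidden": m.architecture.n_hidden,
            "linear_mode": m.architecture.linear_mode,
        },
        "w": _arr(m.w),
        "alphas": _arr(m.hyper.alphas), "beta": m.hyper.beta,
        "log_evidence": m.log_evidence, "gamma": _arr(m.gamma),
        "input_names": m.input_names,
    }


def _ann_from_dict(d: dict) -> BayesAnnModel:
    return BayesAnnModel(
        architecture=NetworkArchitecture(**d["architecture"]),
        w=np.array(d["w"]),
        hyper=HyperParams(alphas=np.array(d["alphas"]), beta=d["beta"]),
        log_evidence=d["log_evidence"],
        gamma=np.array(d["gamma"]),
        input_names=list(d["input_names"]),
    )


def _standardizer_to_dict(s: Standardizer) -> dict:
    return {"means": _arr(s.means), "sds": _arr(s.sds), "names": s.names}


def _committee_to_dict(c: Committee) -> dict:
    return {
        "members": [_ann_to_dict(m) for m in c.members],
        "selected": list(c.selected), "k": c.k, "y_mean": c.y_mean,
        "standardizer": None if c.standardizer is None else _standardizer_to_dict(c.standardizer),
    }


def _committee_from_dict(d: dict) -> Committee:
    st = d.get("standardizer")
    return Committee(
        members=[_ann_from_dict(md) for md in d["members"]],
        selected=list(d["selected"]), k=d["k"], y_mean=d["y_mean"],
        standardizer=None if st is None else Standardizer(
            means=np.array(st["means"]), sds=np.array(st["sds"]), names=list(st["names"])
        ),
    )


_REGISTRY = {
    "univariate": (UnivariateModel, _univariate_to_dict, lambda d: UnivariateModel(**d)),
    "linear": (LinearModel, _linear_to_dict,
               lambda d: LinearModel(coef=np.array(d["coef"]), intercept=d["intercept"],
                                     names=list(d["names"]), r2=d["r2"], n=d["n"])),
    "pls": (PLSModel, _pls_to_dict, _pls_from_dict),
    "bayes_ann": (BayesAnnModel, _ann_to_dict, _ann_from_dict),
    "committee": (Committee, _committee_to_dict, _committee_from_dict),
    "standardizer": (Standardizer, _standardizer_to_dict,
                     lambda d: Standardizer(means=np.array(d["means"]), sds=np.array(d["sds"]),
                                            names=list(d["names"]))),
}


def write_model(model, path) -> None:
    for kind, (cls, to_dict, _) in _REGISTRY.items():
        if isinstance(model, cls):
            with open(path, "w") as fh:
                json.dump({"kind": kind, "payload": to_dict(model)}, fh)
            return
    raise SerializationError(f"don't know how to serialize {type(model).__name__}")


def read_model(path):
    try:
        with open(path) as fh:
            blob = json.load(fh)
        kind = blob["kind"]
        payload = blob["payload"]
    except (json.JSONDecodeError, KeyError, UnicodeDecodeError) as exc:
        raise SerializationError(f"cannot read model file {path}: {exc}") from exc
    if kind not in _REGISTRY:
        raise SerializationError(f"unknown model kind {kind!r}")
    return _REGISTRY[kind][2](payload)
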