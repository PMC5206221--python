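"""Core data containers for sludge/water partitioning QSPR work.

The unit of observation is a single literature measurement of the
sludge/water partition coefficient K_d (reported as log10 of L kg^-1) for
one pharmaceutical.  A compound may contribute several measurements, made
in different studies, sludges and at different pH; the charge class of the
dominant species near pH 7.4 is an *input* (it comes with the curated
dataset, it is never computed here).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, fields
from typing import Iterator, Optional, Sequence

import numpy as np
import pandas as pd


class ChargeClass(str, enum.Enum):
    """Dominant protomer charge at ~pH 7.4."""

    UNCHARGED = "uncharged"
    POSITIVE = "positive"
    NEGATIVE = "negative"
    ZWITTERION = "zwitterion"


#: meta columns recognised in descriptor-table CSV files; everything else
#: in the header is treated as a numeric molecular descriptor.
RESERVED_COLUMNS: tuple[str, ...] = (
    "compound_id",
    "smiles",
    "charge_class",
    "log_kow",
    "log_dow_74",
    "log_kd",
    "experimental_ph",
    "study_id",
)

REQUIRED_COLUMNS: tuple[str, ...] = ("compound_id", "charge_class", "log_kow", "log_kd")


class FormatError(ValueError):
    """A file does not conform to the descriptor-table contract."""


class ConfigError(ValueError):
    """A configuration object violates one of its invariants."""


@dataclass(frozen=True)
class MeasurementRecord:
    """One literature K_d measurement tied to a compound."""

    compound_id: str
    charge_class: ChargeClass
    log_kow: float
    log_kd: float
    smiles: Optional[str] = None
    log_dow_74: Optional[float] = None
    experimental_ph: Optional[float] = None
    study_id: Optional[str] = None

    def __post_init__(self) -> None:
        if not isinstance(self.charge_class, ChargeClass):
            object.__setattr__(self, "charge_class", ChargeClass(self.charge_class))
        if not math.isfinite(self.log_kd):
            raise ValueError(f"log_kd must be finite, got {self.log_kd!r}")


class DescriptorTable:
    """Aligned measurement metadata and numeric descriptor matrix.

    Parameters
    ----------
    meta:
        One row per measurement; must contain the :data:`REQUIRED_COLUMNS`.
    descriptors:
        Numeric descriptor block aligned row-for-row with ``meta``.
    provenance:
        Free-text tag recording where the descriptors came from
        (e.g. ``"synthetic"`` or ``"MOE"``).
    """

    def __init__(
        self,
        meta: pd.DataFrame,
        descriptors: pd.DataFrame,
        provenance: str = "unknown",
    ) -> None:
        if len(meta) != len(descriptors):
            raise FormatError(
                f"meta has {len(meta)} rows but descriptor block has {len(descriptors)}"
            )
        missing = [c for c in REQUIRED_COLUMNS if c not in meta.columns]
        if missing:
            raise FormatError(f"missing required column(s): {', '.join(missing)}")
        if len(set(descriptors.columns)) != len(descriptors.columns):
            raise FormatError("descriptor names must be unique")
        bad = [c for c in descriptors.columns if c in RESERVED_COLUMNS]
        if bad:
            raise FormatError(f"reserved column(s) in descriptor block: {bad}")
        values = descriptors.to_numpy(dtype=float)
        if values.size and not np.all(np.isfinite(values)):
            raise FormatError("descriptor matrix contains non-finite values")
        if not np.all(np.isfinite(meta["log_kd"].to_numpy(dtype=float))):
            raise FormatError("log_kd column contains non-finite values")
        # normalise the charge-class column to the enum's string values
        meta = meta.reset_index(drop=True).copy()
        meta["charge_class"] = [ChargeClass(c).value for c in meta["charge_class"]]
        self.meta = meta
        self.descriptors = descriptors.reset_index(drop=True).copy()
        self.provenance = provenance

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self.meta)

    @property
    def descriptor_names(self) -> list[str]:
        return list(self.descriptors.columns)

    @property
    def values(self) -> np.ndarray:
        """Measurements x descriptors matrix (float64 copy)."""
        return self.descriptors.to_numpy(dtype=float)

    @property
    def y(self) -> np.ndarray:
        """Response vector: measured log K_d."""
        return self.meta["log_kd"].to_numpy(dtype=float)

    @property
    def records(self) -> list[MeasurementRecord]:
        out = []
        for row in self.meta.itertuples(index=False):
            d = row._asdict()
            kwargs = {
                k: (None if (isinstance(v, float) and math.isnan(v)) or v is None else v)
                for k, v in d.items()
                if k in {f.name for f in fields(MeasurementRecord)}
            }
            out.append(MeasurementRecord(**kwargs))
        return out

    def iter_classes(self) -> Iterator[tuple[ChargeClass, "DescriptorTable"]]:
        for cls in ChargeClass:
            sub = self.subset(self.meta["charge_class"] == cls.value)
            if len(sub):
                yield cls, sub

    def subset(self, mask_or_index) -> "DescriptorTable":
        """Row subset by boolean mask or integer index array."""
        idx = np.asarray(mask_or_index)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return DescriptorTable(
            self.meta.iloc[idx],
            self.descriptors.iloc[idx],
            provenance=self.provenance,
        )

    def with_descriptors(self, names: Sequence[str]) -> "DescriptorTable":
        """Column subset of the descriptor block, order preserved."""
        return DescriptorTable(self.meta, self.descriptors[list(names)], self.provenance)

    def to_frame(self) -> pd.DataFrame:
        """Single flat frame: meta columns first, descriptors after."""
        return pd.concat([self.meta, self.descriptors], axis=1)


@dataclass
class RunConfig:
    """Knobs for a full modelling run.

    Defaults mirror the study protocol this package implements: CV filter at
    0.05, five random 237/60 train/test divisions of 297 measurements,
    committees of the best 10 (by log evidence) out of 100 trained networks
    with 2-5 hidden nodes.
    """

    cv_threshold: float = 0.05
    ufs_r2_max: float = 0.99
    n_test: int = 60
    n_splits: int = 5
    hidden_nodes: tuple[int, ...] = (2, 3, 4, 5)
    n_networks: int = 100
    committee_size: int = 10
    alpha_enter: float = 0.15
    alpha_remove: float = 0.15
    leverage_multiplier: float = 3.0
    max_pls_components: int = 8
    outer_loops: int = 8
    master_seed: int = 0
    global_reduction: bool = False

    def __post_init__(self) -> None:
        if isinstance(self.hidden_nodes, (list, tuple)):
            self.hidden_nodes = tuple(int(h) for h in self.hidden_nodes)
        checks = [
            (self.cv_threshold > 0, "cv_threshold must be > 0"),
            (0 < self.ufs_r2_max < 1, "ufs_r2_max must be in (0, 1)"),
            (self.n_test > 0, "n_test must be positive"),
            (self.n_splits > 0, "n_splits must be positive"),
            (self.n_networks > 0, "n_networks must be positive"),
            (
                0 < self.committee_size <= self.n_networks,
                "committee_size must be in 1..n_networks",
            ),
            (0 < self.alpha_enter < 1, "alpha_enter must be in (0, 1)"),
            (0 < self.alpha_remove < 1, "alpha_remove must be in (0, 1)"),
            (self.alpha_remove >= self.alpha_enter, "alpha_remove must be >= alpha_enter"),
            (self.leverage_multiplier > 0, "leverage_multiplier must be positive"),
            (all(h > 0 for h in self.hidden_nodes), "hidden node counts must be positive"),
            (self.max_pls_components > 0, "max_pls_components must be positive"),
            (self.outer_loops >= 0, "outer_loops must be >= 0"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ConfigError(msg)


def substream(master_seed: int, name: str) -> np.random.SeedSequence:
    """Named, independent random substream derived from the master seed.

    Every source of randomness in the package draws from one of these so a
    single master seed reproduces a whole run.
    """
    _STREAMS = {
        "generator": 1,
        "split": 2,
        "init": 3,
        "stepwise": 4,
        "misc": 5,
    }
    if name not in _STREAMS:
        raise KeyError(f"unknown substream {name!r}; known: {sorted(_STREAMS)}")
    return np.random.SeedSequence(entropy=int(master_seed), spawn_key=(_STREAMS[name],))
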