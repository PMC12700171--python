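"""Descriptor construction and tabular I/O for sensitizer/reaction datasets.

Two rate-constant descriptor sets are supported: ``RC`` (the five excited
state rate constants, log10-transformed by default because they span more
than ten decades) and ``s_RC`` (each rate divided by the sum of all five,
so the components are branching-like ratios in [0, 1] summing to one).
Seven auxiliary electronic descriptors (frontier-orbital energies, vertical
excitation energies, the singlet-triplet gap, the S1 oscillator strength
and the ground/excited dipole-moment difference) and a one-hot reaction
encoding complete the feature matrix; the regression target is the product
yield in percent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .kinetics import (
    OBSERVABLE_COLUMNS,
    RATE_NAMES,
    PhotophysicsObservables,
    RateConstantSet,
)

__all__ = [
    "ELECTRONIC_COLUMNS",
    "SCALED_RATE_NAMES",
    "ElectronicDescriptors",
    "ScaledRates",
    "SensitizerRecord",
    "ReactionDataset",
    "FeatureSpec",
    "DescriptorMatrix",
    "scale_rates",
    "assemble_features",
    "read_dataset",
    "write_dataset",
]

#: Canonical file/matrix column names of the seven electronic descriptors.
ELECTRONIC_COLUMNS = (
    "E_HOMO_eV",
    "E_LUMO_eV",
    "E_S1_eV",
    "E_T1_eV",
    "dEST_eV",
    "f_S1",
    "dDM_debye",
)

SCALED_RATE_NAMES = tuple("s_" + n for n in RATE_NAMES)

#: Floor applied to rates before the log10 transform of RC columns; TVCF-style
#: reverse-ISC rates can underflow far below 1 s^-1.
RATE_FLOOR = 1e-12

BASE_SETS = ("RC", "s_RC", "none", "lifetime")


@dataclass(frozen=True)
class ElectronicDescriptors:
    """Seven ground/excited-state electronic descriptors of one sensitizer.

    Energies in eV, ``f_S1`` dimensionless, ``dDM_debye`` in Debye.
    """

    E_HOMO_eV: float
    E_LUMO_eV: float
    E_S1_eV: float
    E_T1_eV: float
    dEST_eV: float = math.nan
    f_S1: float = 0.0
    dDM_debye: float = 0.0

    def __post_init__(self) -> None:
        if not self.E_HOMO_eV < self.E_LUMO_eV:
            raise ValueError("E_HOMO_eV must be below E_LUMO_eV")
        if not self.E_T1_eV <= self.E_S1_eV:
            raise ValueError("E_T1_eV must not exceed E_S1_eV")
        gap = self.E_S1_eV - self.E_T1_eV
        if math.isnan(self.dEST_eV):
            object.__setattr__(self, "dEST_eV", gap)
        elif abs(self.dEST_eV - gap) > 1e-6:
            raise ValueError("dEST_eV must equal E_S1_eV - E_T1_eV")
        if self.f_S1 < 0:
            raise ValueError("f_S1 must be >= 0")
        if self.dDM_debye < 0:
            raise ValueError("dDM_debye must be >= 0")

    def as_dict(self) -> dict[str, float]:
        return {c: getattr(self, c) for c in ELECTRONIC_COLUMNS}


@dataclass(frozen=True)
class ScaledRates:
    """The s_RC descriptor vector: each rate over the sum of all five."""

    s_k_r_S1S0: float
    s_k_ic_S1S0: float
    s_k_isc_S1T1: float
    s_k_risc_T1S1: float
    s_k_isc_T1S0: float

    def __post_init__(self) -> None:
        vals = self.as_tuple()
        if any(v < 0 or v > 1 for v in vals):
            raise ValueError("scaled rates must lie in [0, 1]")
        if abs(sum(vals) - 1.0) > 1e-9:
            raise ValueError("scaled rates must sum to 1")

    def as_tuple(self) -> tuple[float, ...]:
        return tuple(getattr(self, n) for n in SCALED_RATE_NAMES)

    def as_dict(self) -> dict[str, float]:
        return {n: getattr(self, n) for n in SCALED_RATE_NAMES}


def scale_rates(rates: RateConstantSet) -> ScaledRates:
    """Sum-normalize the five rate constants into the s_RC descriptors."""
    total = rates.total
    if total <= 0:
        raise ValueError("cannot scale an all-zero rate set")
    return ScaledRates(*(k / total for k in rates.as_tuple()))


@dataclass(frozen=True)
class SensitizerRecord:
    """Rate constants, electronic descriptors and optional measured data."""

    sensitizer_id: str
    rates: RateConstantSet
    electronic: ElectronicDescriptors
    observables: PhotophysicsObservables | None = None
    lifetime_columns: Mapping[str, float] = field(default_factory=dict)


class ReactionDataset:
    """Rows of (sensitizer_id, reaction_id, yield_percent)."""

    COLUMNS = ["sensitizer_id", "reaction_id", "yield_percent"]

    def __init__(self, frame: pd.DataFrame):
        missing = [c for c in self.COLUMNS if c not in frame.columns]
        if missing:
            raise ValueError(f"reaction table missing columns: {missing}")
        frame = frame.reset_index(drop=True)
        y = pd.to_numeric(frame["yield_percent"], errors="coerce")
        bad = frame.index[y.isna() | (y < 0) | (y > 100)].tolist()
        if bad:
            raise ValueError(
                f"yield_percent outside [0, 100] or non-numeric at rows {bad}"
            )
        dup = frame.duplicated(subset=["sensitizer_id", "reaction_id"])
        if dup.any():
            raise ValueError(
                "duplicate (sensitizer_id, reaction_id) pairs at rows "
                f"{frame.index[dup].tolist()}"
            )
        frame = frame.copy()
        frame["yield_percent"] = y.astype(float)
        self.frame = frame

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def reaction_ids(self) -> list[str]:
        return sorted(self.frame["reaction_id"].astype(str).unique())

    @property
    def sensitizer_ids(self) -> list[str]:
        return sorted(self.frame["sensitizer_id"].astype(str).unique())


@dataclass(frozen=True)
class FeatureSpec:
    """Which descriptor columns enter the feature matrix.

    ``base_set`` selects the rate-derived block (RC, s_RC, none, or
    pass-through measured lifetime columns); ``auxiliary`` is any subset of
    the seven electronic descriptors; ``extra_columns`` passes through named
    per-sensitizer columns (e.g. decoys or measured lifetimes) verbatim.
    ``rate_transform`` applies only to raw RC columns — the s_RC ratios are
    never log-transformed.
    """

    base_set: str = "s_RC"
    auxiliary: tuple[str, ...] = ()
    include_reaction_onehot: bool = True
    rate_transform: str = "log10"
    extra_columns: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.base_set not in BASE_SETS:
            raise ValueError(f"base_set must be one of {BASE_SETS}")
        if self.rate_transform not in ("raw", "log10"):
            raise ValueError("rate_transform must be 'raw' or 'log10'")
        object.__setattr__(self, "auxiliary", tuple(self.auxiliary))
        object.__setattr__(self, "extra_columns", tuple(self.extra_columns))
        unknown = [a for a in self.auxiliary if a not in ELECTRONIC_COLUMNS]
        if unknown:
            raise ValueError(
                f"unknown auxiliary descriptor(s) {unknown}; "
                f"valid names: {list(ELECTRONIC_COLUMNS)}"
            )

    @property
    def label(self) -> str:
        """Human-readable descriptor-set label (Table-style)."""
        parts = [] if self.base_set == "none" else [self.base_set]
        if self.auxiliary:
            parts.append("+".join(self.auxiliary))
        if self.extra_columns:
            parts.append("+".join(self.extra_columns))
        return " + ".join(parts) if parts else "(empty)"

    def to_dict(self) -> dict:
        return {
            "base_set": self.base_set,
            "auxiliary": list(self.auxiliary),
            "include_reaction_onehot": self.include_reaction_onehot,
            "rate_transform": self.rate_transform,
            "extra_columns": list(self.extra_columns),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "FeatureSpec":
        return cls(
            base_set=d.get("base_set", "s_RC"),
            auxiliary=tuple(d.get("auxiliary", ())),
            include_reaction_onehot=bool(d.get("include_reaction_onehot", True)),
            rate_transform=d.get("rate_transform", "log10"),
            extra_columns=tuple(d.get("extra_columns", ())),
        )


@dataclass
class DescriptorMatrix:
    """Assembled feature matrix and yield target.

    ``X`` is indexed by (sensitizer_id, reaction_id); ``y`` is the yield in
    percent on the same index.
    """

    X: pd.DataFrame
    y: pd.Series
    spec: FeatureSpec

    def __post_init__(self) -> None:
        if self.X.isna().any().any():
            bad = self.X.columns[self.X.isna().any()].tolist()
            raise ValueError(f"feature matrix has missing values in {bad}")
        onehot = [c for c in self.X.columns if c.startswith("reaction_")]
        if onehot:
            sums = self.X[onehot].sum(axis=1)
            if not np.allclose(sums, 1.0):
                raise ValueError("one-hot reaction columns must sum to 1 per row")

    @property
    def feature_names(self) -> list[str]:
        return list(self.X.columns)

    def __len__(self) -> int:
        return len(self.X)


def _base_block(record: SensitizerRecord, spec: FeatureSpec) -> dict[str, float]:
    if spec.base_set == "none":
        return {}
    if spec.base_set == "RC":
        vals = record.rates.as_dict()
        if spec.rate_transform == "log10":
            return {
                f"log10_{k}": math.log10(max(v, RATE_FLOOR)) for k, v in vals.items()
            }
        return vals
    if spec.base_set == "s_RC":
        return scale_rates(record.rates).as_dict()
    # lifetime: pass-through measured lifetime columns
    if not record.lifetime_columns:
        raise ValueError(
            f"base_set 'lifetime' but sensitizer {record.sensitizer_id!r} "
            "has no lifetime_columns"
        )
    return dict(record.lifetime_columns)


def assemble_features(
    dataset: ReactionDataset,
    sensitizers: Sequence[SensitizerRecord],
    spec: FeatureSpec,
) -> DescriptorMatrix:
    """Join per-sensitizer descriptors onto reaction rows per ``spec``.

    Column order is deterministic: rate-derived block in canonical rate
    order, auxiliary descriptors in canonical order, extra columns as
    listed, then one-hot ``reaction_<id>`` columns sorted by id (all
    reaction levels kept).
    """
    by_id = {s.sensitizer_id: s for s in sensitizers}
    unknown = sorted(set(dataset.frame["sensitizer_id"].astype(str)) - set(by_id))
    if unknown:
        raise KeyError(f"reaction rows reference unknown sensitizer ids: {unknown}")

    sens_rows: dict[str, dict[str, float]] = {}
    for sid in dataset.sensitizer_ids:
        rec = by_id[sid]
        row = _base_block(rec, spec)
        elec = rec.electronic.as_dict()
        for a in spec.auxiliary:
            row[a] = elec[a]
        for c in spec.extra_columns:
            if c not in rec.lifetime_columns:
                raise KeyError(
                    f"sensitizer {sid!r} is missing extra column {c!r}"
                )
            row[c] = rec.lifetime_columns[c]
        sens_rows[sid] = row

    reaction_ids = dataset.reaction_ids
    records = []
    index = []
    for _, r in dataset.frame.iterrows():
        sid, rid = str(r["sensitizer_id"]), str(r["reaction_id"])
        row = dict(sens_rows[sid])
        if spec.include_reaction_onehot:
            for other in reaction_ids:
                row[f"reaction_{other}"] = 1.0 if other == rid else 0.0
        records.append(row)
        index.append((sid, rid))

    idx = pd.MultiIndex.from_tuples(index, names=["sensitizer_id", "reaction_id"])
    X = pd.DataFrame(records, index=idx)
    y = pd.Series(
        dataset.frame["yield_percent"].to_numpy(), index=idx, name="yield_percent"
    )
    return DescriptorMatrix(X=X, y=y, spec=spec)


# ---------------------------------------------------------------------------
# Delimited-text dataset I/O

MANDATORY_SENSITIZER_COLUMNS = ["sensitizer_id", *RATE_NAMES, *ELECTRONIC_COLUMNS]


def _records_to_frames(
    sensitizers: Sequence[SensitizerRecord],
) -> pd.DataFrame:
    rows = []
    extra_cols: list[str] = []
    for rec in sensitizers:
        row: dict = {"sensitizer_id": rec.sensitizer_id}
        row.update(rec.rates.as_dict())
        row.update(rec.electronic.as_dict())
        if rec.observables is not None:
            row.update(
                {c: rec.observables.as_dict()[c] for c in OBSERVABLE_COLUMNS}
            )
        for k, v in rec.lifetime_columns.items():
            row[k] = v
            if k not in extra_cols:
                extra_cols.append(k)
        rows.append(row)
    cols = MANDATORY_SENSITIZER_COLUMNS + [
        c
        for c in (OBSERVABLE_COLUMNS + extra_cols)
        if any(c in r for r in rows)
    ]
    return pd.DataFrame(rows, columns=cols)


def write_dataset(
    sensitizers: Sequence[SensitizerRecord],
    dataset: ReactionDataset,
    sensitizer_path: str | Path,
    reactions_path: str | Path,
) -> None:
    """Write the sensitizer and reaction tables as UTF-8 CSV files.

    Floats are written with full round-trip precision so that
    ``write_dataset`` followed by :func:`read_dataset` is exact.
    """
    _records_to_frames(sensitizers).to_csv(
        sensitizer_path, index=False, float_format="%.17g"
    )
    dataset.frame.to_csv(reactions_path, index=False, float_format="%.17g")


def read_dataset(
    sensitizer_path: str | Path, reactions_path: str | Path
) -> tuple[ReactionDataset, list[SensitizerRecord]]:
    """Read the two CSV tables written by :func:`write_dataset`.

    Unknown extra columns of the sensitizer table are preserved verbatim in
    ``lifetime_columns`` (this is how measured LT-style lifetimes travel
    through the pipeline).
    """
    sens = pd.read_csv(sensitizer_path, float_precision="round_trip")
    missing = [c for c in MANDATORY_SENSITIZER_COLUMNS if c not in sens.columns]
    if missing:
        raise ValueError(f"sensitizer table missing columns: {missing}")
    dup = sens.duplicated(subset=["sensitizer_id"])
    if dup.any():
        raise ValueError(
            f"duplicate sensitizer_id at rows {sens.index[dup].tolist()}"
        )
    known = set(MANDATORY_SENSITIZER_COLUMNS) | set(OBSERVABLE_COLUMNS)
    extra = [c for c in sens.columns if c not in known]

    records = []
    for i, row in sens.iterrows():
        try:
            rates = RateConstantSet.from_dict(
                {c: float(row[c]) for c in RATE_NAMES}
            )
            electronic = ElectronicDescriptors(
                **{c: float(row[c]) for c in ELECTRONIC_COLUMNS}
            )
        except (TypeError, ValueError) as exc:
            raise ValueError(f"sensitizer table row {i}: {exc}") from exc
        obs = None
        if "tau_prompt_s" in sens.columns and np.isfinite(row.get("tau_prompt_s", np.nan)):
            obs = PhotophysicsObservables(
                **{
                    c: float(row[c])
                    for c in OBSERVABLE_COLUMNS
                    if c in sens.columns
                }
            )
        lifetimes = {
            c: float(row[c]) for c in extra if pd.notna(row[c])
        }
        records.append(
            SensitizerRecord(
                sensitizer_id=str(row["sensitizer_id"]),
                rates=rates,
                electronic=electronic,
                observables=obs,
                lifetime_columns=lifetimes,
            )
        )

    reactions = pd.read_csv(reactions_path, float_precision="round_trip")
    return ReactionDataset(reactions), records
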