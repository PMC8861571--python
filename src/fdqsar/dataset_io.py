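"""Compound-table I/O, split management, and descriptor normalization.

The on-disk format is one CSV dialect: UTF-8, comma-delimited, header row,
'.' decimal separator.  Required columns are ``id`` and ``smiles``; the six
response columns are named exactly ``AvgBScore,1BMQ,1FM6,1GPB,1H5U,1US0``;
any other numeric column is treated as a descriptor.  Missing descriptor
cells stay explicitly missing (NaN) — models that reference them fail fast;
there is no imputation.

Splits follow the four-way partition used for correlation-weight training
(active / passive / calibration / validation); the first three merge into
the network training set, validation is the external test set.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

RESPONSE_COLUMNS = ("AvgBScore", "1BMQ", "1FM6", "1GPB", "1H5U", "1US0")
SPLIT_LABELS = ("active", "passive", "calibration", "validation")
TRAIN_SPLITS = ("active", "passive", "calibration")


@dataclass
class CompoundRecord:
    """One compound: identifier, structure, descriptors, responses, split."""

    id: str
    smiles: str
    descriptors: dict[str, float] = field(default_factory=dict)
    responses: dict[str, float] = field(default_factory=dict)
    split: str | None = None


@dataclass
class SplitAssignment:
    """Mapping id → split label with derived train/test groups."""

    mapping: dict[str, str]

    @property
    def train_ids(self) -> list[str]:
        return [i for i, s in self.mapping.items() if s in TRAIN_SPLITS]

    @property
    def test_ids(self) -> list[str]:
        return [i for i, s in self.mapping.items() if s == "validation"]

    def group(self, label: str) -> list[str]:
        return [i for i, s in self.mapping.items() if s == label]


@dataclass
class NormalizationParams:
    """Per-column affine normalization ``(x - offset) / scale``."""

    method: str  # 'minmax' or 'zscore'
    columns: list[str]
    offset: np.ndarray  # min (minmax) or mean (zscore)
    scale: np.ndarray  # max-min (minmax) or sd (zscore)

    def apply(self, frame: pd.DataFrame) -> pd.DataFrame:
        out = frame[self.columns].astype(float).copy()
        out = (out - self.offset) / self.scale
        return out

    def invert(self, frame: pd.DataFrame) -> pd.DataFrame:
        out = frame[self.columns].astype(float).copy()
        out = out * self.scale + self.offset
        return out


def read_compounds(
    path: str | Path, schema: dict[str, str] | None = None
) -> list[CompoundRecord]:
    """Read a compound CSV into records, preserving file order.

    ``schema`` maps roles to column names: ``{'id': ..., 'smiles': ...}``;
    by default the columns are named ``id`` and ``smiles``.  Columns named
    as in :data:`RESPONSE_COLUMNS` are responses; every other column is a
    descriptor.  Missing descriptor cells become NaN, never zero.
    """
    schema = schema or {}
    id_col = schema.get("id", "id")
    smiles_col = schema.get("smiles", "smiles")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    frame = pd.read_csv(
        path, dtype={id_col: str}, keep_default_na=True,
        float_precision="round_trip",
    )

    for col in (id_col, smiles_col):
        if col not in frame.columns:
            raise ValueError(f"missing mandatory column {col!r}")
    dup = frame[id_col][frame[id_col].duplicated()]
    if len(dup):
        raise ValueError(f"duplicate compound ID {dup.iloc[0]!r}")

    response_cols = [c for c in RESPONSE_COLUMNS if c in frame.columns]
    for col in response_cols:
        numeric = pd.to_numeric(frame[col], errors="coerce")
        bad = frame.index[numeric.isna() & frame[col].notna()]
        if len(bad):
            raise ValueError(
                f"non-numeric response in column {col!r}, row {int(bad[0]) + 2}"
            )
        frame[col] = numeric
    descriptor_cols = [
        c
        for c in frame.columns
        if c not in (id_col, smiles_col, "split") and c not in RESPONSE_COLUMNS
    ]

    records = []
    for _, row in frame.iterrows():
        smiles = row[smiles_col]
        if not isinstance(smiles, str) or not smiles:
            raise ValueError(f"empty SMILES for compound {row[id_col]!r}")
        responses = {
            c: float(row[c]) for c in response_cols if not pd.isna(row[c])
        }
        descriptors = {c: float(row[c]) for c in descriptor_cols}
        split = row["split"] if "split" in frame.columns else None
        if pd.isna(split):
            split = None
        records.append(
            CompoundRecord(
                id=str(row[id_col]),
                smiles=smiles,
                descriptors=descriptors,
                responses=responses,
                split=split,
            )
        )
    return records


def write_compounds(records: list[CompoundRecord], path: str | Path) -> None:
    """Write records to CSV at full float precision (lossless round-trip)."""
    desc_cols: list[str] = []
    for rec in records:
        for name in rec.descriptors:
            if name not in desc_cols:
                desc_cols.append(name)
    resp_cols = [
        c
        for c in RESPONSE_COLUMNS
        if any(c in rec.responses for rec in records)
    ]
    has_split = any(rec.split is not None for rec in records)
    header = ["id", "smiles", *desc_cols, *resp_cols] + (
        ["split"] if has_split else []
    )
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(header)
        for rec in records:
            row: list[str] = [rec.id, rec.smiles]
            for c in desc_cols:
                v = rec.descriptors.get(c)
                row.append("" if v is None or np.isnan(v) else repr(float(v)))
            for c in resp_cols:
                v = rec.responses.get(c)
                row.append("" if v is None else repr(float(v)))
            if has_split:
                row.append(rec.split or "")
            writer.writerow(row)


def records_to_frame(records: list[CompoundRecord]) -> pd.DataFrame:
    """Tabular view of records, indexed by compound id (order preserved)."""
    rows = []
    for rec in records:
        row: dict[str, object] = {"id": rec.id, "smiles": rec.smiles}
        row.update(rec.descriptors)
        row.update(rec.responses)
        if rec.split is not None:
            row["split"] = rec.split
        rows.append(row)
    return pd.DataFrame(rows).set_index("id")


def assign_splits(
    ids: list[str], scheme: str = "round_robin", seed: int = 0
) -> SplitAssignment:
    """Partition ids into active/passive/calibration/validation quarters.

    ``round_robin`` assigns position k to group k mod 4 in input order;
    ``seeded_random`` shuffles with the given seed first.  Group sizes
    differ by at most one.
    """
    if not ids:
        raise ValueError("cannot split an empty id list")
    if len(set(ids)) != len(ids):
        raise ValueError("ids must be unique")
    order = list(ids)
    if scheme == "seeded_random":
        rng = np.random.default_rng(seed)
        order = [order[i] for i in rng.permutation(len(order))]
    elif scheme != "round_robin":
        raise ValueError(f"unknown split scheme {scheme!r}")
    mapping = {cid: SPLIT_LABELS[k % 4] for k, cid in enumerate(order)}
    # preserve original id order in the mapping
    return SplitAssignment(mapping={cid: mapping[cid] for cid in ids})


def normalize(
    frame: pd.DataFrame,
    fit_rows: list[str] | None = None,
    method: str = "minmax",
    columns: list[str] | None = None,
) -> tuple[pd.DataFrame, NormalizationParams]:
    """Column-wise normalization with parameters learned on ``fit_rows``.

    minmax maps the fitting group into [0, 1] (rows outside the group may
    fall outside — no clipping); zscore centers and scales.  A constant
    fitted column is an error naming the column.  ``params.invert`` undoes
    the transform exactly (to floating-point precision).
    """
    columns = list(columns) if columns is not None else list(frame.columns)
    fit = frame.loc[fit_rows, columns] if fit_rows is not None else frame[columns]
    fit = fit.astype(float)
    if fit.empty:
        raise ValueError("fitting group is empty")
    if method == "minmax":
        offset = fit.min(axis=0).to_numpy()
        scale = fit.max(axis=0).to_numpy() - offset
    elif method == "zscore":
        offset = fit.mean(axis=0).to_numpy()
        scale = fit.std(axis=0, ddof=1).to_numpy()
    else:
        raise ValueError(f"unknown normalization method {method!r}")
    bad = np.flatnonzero(scale <= 0)
    if bad.size:
        raise ValueError(f"constant column {columns[bad[0]]!r} cannot be normalized")
    params = NormalizationParams(
        method=method, columns=columns, offset=offset, scale=scale
    )
    return params.apply(frame), params
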