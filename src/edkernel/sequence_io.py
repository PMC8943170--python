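"""Readers and writers: event tables, peptide tables, matrices, datasets.

Event tables are long-format delimited text, one row per clinical event
with subject id, event date and event code columns (names and date format
configurable through :class:`EventTableDialect`).  Rows are grouped by
subject and date-sorted into one symbol sequence per subject; equal-date
ties keep file order, so the reader is deterministic and permutation
invariant up to equal-date ordering.

Peptide tables are one row per sequence: an amino-acid string plus a class
name, mapped one-vs-all onto ±1.

Distance and kernel matrices round-trip through delimited text with a JSON
provenance header line, value-exact at full double precision.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from datetime import datetime
from typing import Callable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .edit_distance import DEFAULT_COSTS, DistanceMatrix, EditCostScheme
from .errors import ConfigurationError, FormatError, ParameterError, RecordError
from .kernel_builder import KernelMatrix
from .sequences import LabeledDataset, SymbolSequence

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# event tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EventTableDialect:
    """Column names, delimiter and date format of an event table.

    ``date_format`` follows ``strptime``; the special value ``"index"``
    reads dates as plain integers (used by the synthetic writer, where
    dates are event indices).  ``label_col`` optionally names a per-row
    ±1 label column (constant within a subject).
    """

    id_col: str = "patient_id"
    date_col: str = "event_date"
    code_col: str = "read_code"
    delimiter: str = ","
    date_format: str = "%Y%m%d"
    label_col: Optional[str] = None
    value_cols: tuple = ()  # extra numeric columns kept for per-event accessors


def _parse_dates(raw: pd.Series, dialect: EventTableDialect, skip_bad: bool) -> pd.Series:
    if dialect.date_format == "index":
        parsed = pd.to_numeric(raw, errors="coerce")
    else:
        parsed = pd.to_datetime(raw.astype(str), format=dialect.date_format, errors="coerce")
    bad = parsed.isna()
    if bad.any():
        rows = [int(i) + 2 for i in np.flatnonzero(bad.to_numpy())]  # 1-based + header
        if not skip_bad:
            raise RecordError(
                f"unparseable date {raw.iloc[int(np.flatnonzero(bad.to_numpy())[0])]!r} "
                f"under format {dialect.date_format!r}",
                row=rows[0],
            )
        logger.warning("read_event_table: skipping %d rows with unparseable dates (rows %s...)",
                       len(rows), rows[:5])
    return parsed


def read_event_table(
    path,
    dialect: EventTableDialect = EventTableDialect(),
    skip_bad_dates: bool = False,
    name: str = "",
) -> LabeledDataset:
    """One :class:`SymbolSequence` per distinct subject, date-sorted.

    Symbols are whole event codes ordered by event date ascending; rows
    with equal dates keep file order (stable sort).  Labels are unset
    unless the dialect names a label column.
    """
    df = pd.read_csv(path, sep=dialect.delimiter, dtype=str, keep_default_na=False)
    for colname in (dialect.id_col, dialect.date_col, dialect.code_col):
        if colname not in df.columns:
            raise ConfigurationError(
                f"column {colname!r} not found in {path}; available: {list(df.columns)}"
            )
    label_col = dialect.label_col if dialect.label_col in df.columns else None
    dates = _parse_dates(df[dialect.date_col], dialect, skip_bad_dates)
    df = df.assign(_date=dates).loc[dates.notna()]

    sequences = []
    for sid, grp in df.groupby(dialect.id_col, sort=True):
        grp = grp.sort_values("_date", kind="stable")  # stable: equal dates keep file order
        raw_label = grp[label_col].iloc[0] if label_col else ""
        label = int(float(raw_label)) if raw_label != "" else None
        values = None
        if dialect.value_cols:
            values = tuple(
                tuple(pd.to_numeric(grp[c], errors="coerce")) for c in dialect.value_cols
            )
        seq = SymbolSequence(
            id=str(sid),
            symbols=tuple(grp[dialect.code_col]),
            timestamps=tuple(grp["_date"]),
            label=label,
        )
        if values is not None:
            # attach raw numeric columns for per-event accessors without
            # widening the core type (frozen dataclass, so go via __dict__)
            seq.__dict__["event_values"] = dict(zip(dialect.value_cols, values))
        sequences.append(seq)
    return LabeledDataset(tuple(sequences), name=name or str(path))


def derive_bp_label(
    ds: LabeledDataset,
    diabetes_code: str = "C10..00",
    sbp_threshold: float = 130.0,
    dbp_threshold: float = 80.0,
    bp_reader: Callable[[SymbolSequence, int], Optional[tuple]] = None,
) -> LabeledDataset:
    """Label subjects by elevated blood pressure before first diagnosis.

    A subject is positive (+1) iff some event strictly before the first
    occurrence of ``diabetes_code`` (by timestamp) yields a blood-pressure
    reading with systolic >= ``sbp_threshold`` AND diastolic >=
    ``dbp_threshold`` — thresholds inclusive.  ``bp_reader(seq, i)``
    returns ``(systolic, diastolic)`` for event ``i`` or ``None`` if the
    event carries no reading; readings with missing numerics are skipped
    with a log message.  Subjects lacking the diagnosis code are dropped
    (count logged).
    """
    if bp_reader is None:
        raise ParameterError("derive_bp_label requires a per-event bp_reader accessor")
    labelled, dropped = [], 0
    for seq in ds:
        if diabetes_code not in seq.symbols:
            dropped += 1
            continue
        first = seq.symbols.index(diabetes_code)
        if seq.timestamps is not None:
            cutoff = seq.timestamps[first]
            before = [i for i, t in enumerate(seq.timestamps) if t < cutoff]
        else:
            before = list(range(first))
        label = -1
        for i in before:
            reading = bp_reader(seq, i)
            if reading is None:
                continue
            sbp, dbp = reading
            if sbp is None or dbp is None or not (np.isfinite(sbp) and np.isfinite(dbp)):
                logger.info("derive_bp_label: %s event %d has missing numerics, skipped", seq.id, i)
                continue
            if sbp >= sbp_threshold and dbp >= dbp_threshold:
                label = 1
                break
        labelled.append(seq.with_label(label))
    if dropped:
        logger.info("derive_bp_label: dropped %d sequences lacking code %r", dropped, diabetes_code)
    return LabeledDataset(tuple(labelled), name=ds.name)


# ---------------------------------------------------------------------------
# peptide tables
# ---------------------------------------------------------------------------

def _canon(name: str) -> str:
    return re.sub(r"[^a-z0-9]", "", name.lower())


def read_peptide_table(
    path,
    sequence_col: str = "sequence",
    class_col: str = "class",
    positive_class: str = "inactive-virtual",
    known_classes: Sequence[str] = ("inactive-exp", "inactive-virtual", "mod. active", "very active"),
    delimiter: str = ",",
    balanced: bool = False,
    seed: int = 0,
    name: str = "",
) -> LabeledDataset:
    """One character-tokenized sequence per row; one-vs-all ±1 labels.

    The positive class (default ``inactive-virtual``) maps to +1, every
    other known class to −1; class names are matched case- and
    punctuation-insensitively (so ``"inactive - virtual"`` works).  With
    ``balanced=True`` the majority side is down-sampled (without
    replacement, seeded) to an equal class split.
    """
    df = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)
    for colname in (sequence_col, class_col):
        if colname not in df.columns:
            raise ConfigurationError(
                f"column {colname!r} not found in {path}; available: {list(df.columns)}"
            )
    canon_known = {_canon(c): c for c in known_classes}
    pos_key = _canon(positive_class)
    if pos_key not in canon_known:
        raise ConfigurationError(f"positive class {positive_class!r} not among {list(known_classes)}")

    sequences = []
    for row_i, rec in enumerate(df.itertuples(index=False), start=2):
        seq_str = rec[df.columns.get_loc(sequence_col)]
        cls = rec[df.columns.get_loc(class_col)]
        if not seq_str:
            raise RecordError("empty sequence string", row=row_i)
        key = _canon(cls)
        if key not in canon_known:
            raise RecordError(
                f"unknown class {cls!r}; known classes: {list(known_classes)}", row=row_i
            )
        label = 1 if key == pos_key else -1
        sequences.append(
            SymbolSequence(id=f"r{row_i - 2:04d}", symbols=tuple(seq_str), label=label)
        )
    if balanced:
        rng = np.random.default_rng(seed)
        pos = [s for s in sequences if s.label == 1]
        neg = [s for s in sequences if s.label == -1]
        k = min(len(pos), len(neg))
        keep_pos = [pos[i] for i in sorted(rng.choice(len(pos), size=k, replace=False))]
        keep_neg = [neg[i] for i in sorted(rng.choice(len(neg), size=k, replace=False))]
        kept_ids = {s.id for s in keep_pos} | {s.id for s in keep_neg}
        sequences = [s for s in sequences if s.id in kept_ids]
    return LabeledDataset(tuple(sequences), name=name or str(path))


# ---------------------------------------------------------------------------
# matrix store: TSV payload + JSON provenance header
# ---------------------------------------------------------------------------

_MAGIC = "#edkernel-matrix "


def write_matrix(M: Union[DistanceMatrix, KernelMatrix], path) -> None:
    """Serialize a matrix as delimited text with a provenance header.

    Values are written with ``repr``-exact precision (17 significant
    digits) so a read-back is value-identical.
    """
    if isinstance(M, DistanceMatrix):
        header = {
            "kind": "distance",
            "ids": list(M.ids),
            "variant": M.variant,
            "costs": [M.costs.insert_cost, M.costs.delete_cost, M.costs.substitute_cost],
        }
    elif isinstance(M, KernelMatrix):
        header = {"kind": "kernel", "ids": list(M.ids), "provenance": M.provenance}
    else:
        raise ParameterError(f"cannot serialize object of type {type(M).__name__}")
    with open(path, "w") as fh:
        fh.write(_MAGIC + json.dumps(header) + "\n")
        for row in M.values:
            fh.write("\t".join(format(v, ".17g") for v in row) + "\n")


def read_matrix(path) -> Union[DistanceMatrix, KernelMatrix]:
    """Inverse of :func:`write_matrix`; validates shape against the header."""
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith(_MAGIC):
            raise FormatError(f"{path}: missing matrix header line")
        header = json.loads(first[len(_MAGIC):])
        values = np.loadtxt(fh, delimiter="\t", ndmin=2)
    ids = tuple(header["ids"])
    if values.shape != (len(ids), len(ids)):
        raise FormatError(
            f"{path}: payload shape {values.shape} does not match {len(ids)} header ids"
        )
    if header.get("kind") == "distance":
        costs = EditCostScheme(*header.get("costs", (1, 1, 2)))
        return DistanceMatrix(values, ids, header["variant"], costs)
    if header.get("kind") == "kernel":
        return KernelMatrix(values, ids, header.get("provenance", {}))
    raise FormatError(f"{path}: unknown matrix kind {header.get('kind')!r}")


# ---------------------------------------------------------------------------
# dataset writer (the dialect read_event_table consumes) and label files
# ---------------------------------------------------------------------------

def write_event_table(ds: LabeledDataset, path, dialect: EventTableDialect = None) -> None:
    """Write a dataset as a long-format event table.

    Timestamps default to integer event indices when absent, matching the
    ``"index"`` date format.  Labels are included when every sequence is
    labelled and the dialect names a label column.
    """
    if dialect is None:
        dialect = EventTableDialect(date_format="index", label_col="label")
    rows = []
    for seq in ds:
        ts = seq.timestamps if seq.timestamps is not None else tuple(range(len(seq)))
        for t, tok in zip(ts, seq.symbols):
            row = {dialect.id_col: seq.id, dialect.date_col: t, dialect.code_col: tok}
            if dialect.label_col and seq.label is not None:
                row[dialect.label_col] = seq.label
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep=dialect.delimiter, index=False)


def write_labels(ds: LabeledDataset, path) -> None:
    pd.DataFrame({"id": list(ds.ids), "label": list(ds.labels())}).to_csv(path, index=False)


def read_labels(path) -> pd.Series:
    df = pd.read_csv(path)
    if not {"id", "label"} <= set(df.columns):
        raise FormatError(f"{path}: label file needs 'id' and 'label' columns")
    return pd.Series(df["label"].astype(int).to_numpy(), index=df["id"].astype(str))
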