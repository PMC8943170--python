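"""Containers for uneven-length symbolic sequences.

A subject (a patient history, a peptide) is represented in its native form:
an ordered sequence of discrete symbols drawn from an alphabet Σ, optionally
time-stamped, optionally carrying a binary class label encoded as +1 / −1.
No featurization happens here — downstream code consumes the sequences
directly via elastic dissimilarity measures.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Hashable, Iterator, Optional, Sequence

import numpy as np

from .errors import ParameterError

#: characters that would break the delimited on-disk representations
_FORBIDDEN_CHARS = set(",\t\n\r")

POSITIVE, NEGATIVE = 1, -1


@dataclass(frozen=True)
class SymbolSequence:
    """One subject's ordered symbol sequence.

    Parameters
    ----------
    id:
        Unique text identifier within a dataset.
    symbols:
        Ordered tokens; length >= 1.  Tokens are non-empty strings free of
        delimiter characters (comma, tab, newline).
    timestamps:
        Optional per-symbol timestamps (any totally ordered values, e.g.
        ``datetime.date`` or integer event indices); must be non-decreasing
        and aligned with ``symbols``.
    label:
        Optional binary class in {+1, -1}.
    source_table:
        Optional provenance tag naming the table the events came from
        (e.g. ``"Clinical"`` or ``"All"``).
    """

    id: str
    symbols: tuple
    timestamps: Optional[tuple] = None
    label: Optional[int] = None
    source_table: Optional[str] = None

    def __post_init__(self):
        object.__setattr__(self, "symbols", tuple(self.symbols))
        if len(self.symbols) < 1:
            raise ParameterError(f"sequence {self.id!r}: must contain at least one symbol")
        for tok in self.symbols:
            if not isinstance(tok, str) or not tok:
                raise ParameterError(f"sequence {self.id!r}: empty or non-string token {tok!r}")
            if _FORBIDDEN_CHARS & set(tok):
                raise ParameterError(
                    f"sequence {self.id!r}: token {tok!r} contains a delimiter character"
                )
        if self.timestamps is not None:
            ts = tuple(self.timestamps)
            object.__setattr__(self, "timestamps", ts)
            if len(ts) != len(self.symbols):
                raise ParameterError(
                    f"sequence {self.id!r}: {len(ts)} timestamps for {len(self.symbols)} symbols"
                )
            if any(a > b for a, b in zip(ts, ts[1:])):
                raise ParameterError(f"sequence {self.id!r}: timestamps must be non-decreasing")
        if self.label is not None and self.label not in (POSITIVE, NEGATIVE):
            raise ParameterError(f"sequence {self.id!r}: label must be +1 or -1, got {self.label!r}")

    def __len__(self) -> int:
        return len(self.symbols)

    def __iter__(self) -> Iterator[str]:
        return iter(self.symbols)

    def distinct_symbols(self) -> frozenset:
        return frozenset(self.symbols)

    def with_label(self, label: Optional[int]) -> "SymbolSequence":
        return SymbolSequence(self.id, self.symbols, self.timestamps, label, self.source_table)


@dataclass(frozen=True)
class LabeledDataset:
    """An ordered collection of :class:`SymbolSequence` with unique ids."""

    sequences: tuple
    name: str = ""

    def __post_init__(self):
        object.__setattr__(self, "sequences", tuple(self.sequences))
        ids = [s.id for s in self.sequences]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ParameterError(f"dataset {self.name!r}: duplicate sequence ids {dup}")

    # -- basic container protocol ------------------------------------
    def __len__(self) -> int:
        return len(self.sequences)

    def __iter__(self) -> Iterator[SymbolSequence]:
        return iter(self.sequences)

    def __getitem__(self, i: int) -> SymbolSequence:
        return self.sequences[i]

    # -- views --------------------------------------------------------
    @property
    def ids(self) -> tuple:
        return tuple(s.id for s in self.sequences)

    @property
    def alphabet(self) -> frozenset:
        """Union of distinct tokens over all member sequences."""
        out: set = set()
        for s in self.sequences:
            out.update(s.symbols)
        return frozenset(out)

    def labels(self) -> np.ndarray:
        """Label vector aligned with ``sequences``; raises if any is unset."""
        labs = [s.label for s in self.sequences]
        if any(l is None for l in labs):
            raise ParameterError(f"dataset {self.name!r}: not all sequences are labelled")
        return np.asarray(labs, dtype=int)

    def get(self, seq_id: str) -> SymbolSequence:
        for s in self.sequences:
            if s.id == seq_id:
                return s
        raise KeyError(seq_id)

    def drop(self, seq_id: str) -> "LabeledDataset":
        """Dataset without the named sequence (used by the in-turn x0 search)."""
        kept = tuple(s for s in self.sequences if s.id != seq_id)
        if len(kept) == len(self.sequences):
            raise KeyError(seq_id)
        return LabeledDataset(kept, name=self.name)

    def subset(self, seq_ids: Sequence[str]) -> "LabeledDataset":
        by_id = {s.id: s for s in self.sequences}
        return LabeledDataset(tuple(by_id[i] for i in seq_ids), name=self.name)
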