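"""Edit distance between symbol sequences and its normalized variants.

The base dissimilarity is the classic Levenshtein recurrence with
configurable operation costs — by default insertion and deletion cost 1 and
substitution costs 2 (a substitution is then never cheaper than a
delete+insert, which makes the default distance equal to
``|x| + |y| - 2*LCS(x, y)``).

Four variants are exposed, named as in the kernel construction they feed:

``k_ed1``
    the raw edit distance;
``k_ed2``
    length-normalized: divided by the length of the longer sequence;
``k_ed3``
    divided by the number of common (distinct) symbols of the pair;
``k_ed4``
    divided by ``2**|common symbols|`` (computed as a floating exponent so
    large intersections underflow smoothly instead of overflowing).

The pairwise driver computes the raw distance matrix once and derives the
normalized variants from it, since every normalizer depends only on the two
sequences' lengths and symbol sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence, Union

import numpy as np

from .errors import ParameterError
from .sequences import LabeledDataset, SymbolSequence

VARIANTS = ("k_ed1", "k_ed2", "k_ed3", "k_ed4")


@dataclass(frozen=True)
class EditCostScheme:
    """Operation costs for the edit recurrence; a match always costs 0."""

    insert_cost: float = 1.0
    delete_cost: float = 1.0
    substitute_cost: float = 2.0

    def __post_init__(self):
        for name in ("insert_cost", "delete_cost", "substitute_cost"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be non-negative, got {getattr(self, name)}")


DEFAULT_COSTS = EditCostScheme()

TokenSeq = Union[SymbolSequence, Sequence]


def _tokens(x: TokenSeq) -> tuple:
    if isinstance(x, SymbolSequence):
        return x.symbols
    return tuple(x)


def _encode_pair(xs: tuple, ys: tuple):
    """Map tokens of both sequences onto small ints for vectorized compare."""
    vocab: dict = {}
    enc = lambda seq: np.array([vocab.setdefault(t, len(vocab)) for t in seq], dtype=np.int64)
    return enc(xs), enc(ys)


def edit_distance(x: TokenSeq, y: TokenSeq, costs: EditCostScheme = DEFAULT_COSTS) -> float:
    """Minimal total cost of an edit script transforming ``x`` into ``y``.

    Dynamic programming over a two-row rolling table.  The within-row
    dependency introduced by insertions is resolved in closed form:
    ``cur[j] = min_{k<=j} t[k] + (j-k)*ins`` where ``t`` holds the
    delete/substitute candidates, evaluated with a running minimum of
    ``t[k] - k*ins``.
    """
    xs, ys = _tokens(x), _tokens(y)
    ins, dele, sub = float(costs.insert_cost), float(costs.delete_cost), float(costs.substitute_cost)
    if not xs:
        return ins * len(ys)
    if not ys:
        return dele * len(xs)
    a, b = _encode_pair(xs, ys)
    m = len(b)
    jidx = np.arange(m + 1, dtype=float)
    prev = ins * jidx  # d[0][j]: build y[:j] from nothing
    t = np.empty(m + 1)
    for i in range(1, len(a) + 1):
        subcost = np.where(b == a[i - 1], 0.0, sub)
        t[0] = i * dele
        np.minimum(prev[1:] + dele, prev[:-1] + subcost, out=t[1:])
        prev = np.minimum.accumulate(t - ins * jidx) + ins * jidx
    return float(prev[m])


def length_normalized_distance(x: TokenSeq, y: TokenSeq, costs: EditCostScheme = DEFAULT_COSTS) -> float:
    """k_ed2: edit distance divided by the length of the longer sequence."""
    xs, ys = _tokens(x), _tokens(y)
    n = max(len(xs), len(ys))
    if n == 0:
        raise ParameterError("length normalization undefined for two empty sequences")
    return edit_distance(xs, ys, costs) / n


def common_item_count(x: TokenSeq, y: TokenSeq) -> int:
    """Number of distinct symbols the two sequences share."""
    return len(frozenset(_tokens(x)) & frozenset(_tokens(y)))


def common_normalized_distance(x: TokenSeq, y: TokenSeq, costs: EditCostScheme = DEFAULT_COSTS) -> float:
    """k_ed3: edit distance divided by the shared-symbol count.

    Disjoint pairs would divide by zero; the denominator is guarded with
    ``max(1, |common|)`` so they fall back to the raw distance.
    """
    return edit_distance(x, y, costs) / max(1, common_item_count(x, y))


def exp_common_normalized_distance(x: TokenSeq, y: TokenSeq, costs: EditCostScheme = DEFAULT_COSTS) -> float:
    """k_ed4: edit distance scaled by ``2**-|common|`` (floating exponent)."""
    return edit_distance(x, y, costs) * float(np.exp2(-float(common_item_count(x, y))))


_SCALAR_VARIANTS = {
    "k_ed1": edit_distance,
    "k_ed2": length_normalized_distance,
    "k_ed3": common_normalized_distance,
    "k_ed4": exp_common_normalized_distance,
}


def variant_distance(x: TokenSeq, y: TokenSeq, variant: str, costs: EditCostScheme = DEFAULT_COSTS) -> float:
    """Dispatch a single pair through the named distance variant."""
    try:
        fn = _SCALAR_VARIANTS[variant]
    except KeyError:
        raise ParameterError(f"unknown variant {variant!r}; expected one of {VARIANTS}") from None
    return fn(x, y, costs)


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric pairwise dissimilarities under one edit-distance variant."""

    values: np.ndarray
    ids: tuple
    variant: str
    costs: EditCostScheme = DEFAULT_COSTS

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "ids", tuple(self.ids))
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ParameterError(f"distance matrix must be square, got shape {v.shape}")
        if v.shape[0] != len(self.ids):
            raise ParameterError("distance matrix shape does not match id count")
        if self.variant not in VARIANTS:
            raise ParameterError(f"unknown variant {self.variant!r}; expected one of {VARIANTS}")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ParameterError("distance matrix is not symmetric")
        if np.any(v < -1e-12):
            raise ParameterError("distance matrix has negative entries")
        if np.any(np.abs(np.diag(v)) > 1e-12):
            raise ParameterError("distance matrix diagonal must be zero")

    @property
    def n(self) -> int:
        return len(self.ids)


def _raw_pairwise(seqs: Sequence[tuple], costs: EditCostScheme) -> np.ndarray:
    n = len(seqs)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = edit_distance(seqs[i], seqs[j], costs)
    return d


def _normalize_matrix(d1: np.ndarray, seqs: Sequence[tuple], variant: str) -> np.ndarray:
    """Derive a variant matrix from the raw distance matrix."""
    if variant == "k_ed1":
        return d1
    n = len(seqs)
    if variant == "k_ed2":
        lens = np.array([len(s) for s in seqs], dtype=float)
        return d1 / np.maximum(lens[:, None], lens[None, :])
    sets = [frozenset(s) for s in seqs]
    common = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            common[i, j] = common[j, i] = len(sets[i] & sets[j])
    if variant == "k_ed3":
        return d1 / np.maximum(1.0, common)
    if variant == "k_ed4":
        return d1 * np.exp2(-common)
    raise ParameterError(f"unknown variant {variant!r}; expected one of {VARIANTS}")


def pairwise_distances(
    ds: LabeledDataset, variant: str = "k_ed1", costs: EditCostScheme = DEFAULT_COSTS
) -> DistanceMatrix:
    """All-pairs distance matrix of a dataset under the named variant.

    Only the upper triangle of the raw edit distance is computed and
    mirrored; normalizers are applied to the full matrix afterwards.
    """
    if len(ds) < 2:
        raise ParameterError("pairwise distances need at least 2 sequences")
    if variant not in VARIANTS:
        raise ParameterError(f"unknown variant {variant!r}; expected one of {VARIANTS}")
    seqs = [s.symbols for s in ds]
    d1 = _raw_pairwise(seqs, costs)
    return DistanceMatrix(_normalize_matrix(d1, seqs, variant), ds.ids, variant, costs)


def distances_to_reference(
    ds: LabeledDataset,
    x0: SymbolSequence,
    variant: str = "k_ed1",
    costs: EditCostScheme = DEFAULT_COSTS,
) -> np.ndarray:
    """Variant distance from every dataset member to a reference sequence."""
    return np.array([variant_distance(s, x0, variant, costs) for s in ds])
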