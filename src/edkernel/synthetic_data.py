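"""Synthetic uneven-length symbolic datasets with an order-only class signal.

The generator emulates the regime the edit kernels target: subjects are
variable-length token sequences (uniform lengths, wide range) whose class
is encoded *only in symbol order*.  Both classes receive copies of a motif
with the same symbol multiset — class +1 gets ``motif_a``, class −1 gets
``motif_b`` (by default the reversal of ``motif_a``) — spliced into random
background.  Because the multisets match, Bag-of-Words features of the two
classes are identically distributed and count-based classifiers sit at
chance, while an order-sensitive edit distance separates the classes.
Per-symbol replacement noise controls the difficulty.

Also provides the fixed worked micro-fixture shared by unit tests across
modules.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np

from .errors import ConfigurationError, ParameterError
from .sequences import LabeledDataset, SymbolSequence


def _default_motifs(alphabet: tuple) -> tuple:
    m = tuple(alphabet[: min(6, max(2, len(alphabet) // 2))])
    return m, tuple(reversed(m))


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator settings.

    ``length_law`` bounds the uniform integer background length; motif
    copies are spliced in on top, so total lengths exceed the bounds by
    ``motif_copies * len(motif)``.  ``motif_a`` and ``motif_b`` must share
    one symbol multiset — the generator refuses configurations where a
    count-based featurization could separate the classes by construction.
    """

    n_per_class: int = 30
    alphabet_size: int = 12
    length_law: Tuple[int, int] = (20, 120)
    motif_a: Optional[tuple] = None
    motif_b: Optional[tuple] = None
    motif_copies: int = 6
    noise_rate: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.alphabet_size < 4:
            raise ConfigurationError("alphabet_size must be >= 4")
        if self.n_per_class < 1:
            raise ConfigurationError("n_per_class must be >= 1")
        lo, hi = self.length_law
        if not (1 <= lo <= hi):
            raise ConfigurationError(f"invalid length law {self.length_law}")
        if not 0.0 <= self.noise_rate <= 1.0:
            raise ConfigurationError(f"noise_rate must be in [0, 1], got {self.noise_rate}")
        if self.motif_copies < 0:
            raise ConfigurationError("motif_copies must be >= 0")
        a, b = self.motif_a, self.motif_b
        if (a is None) != (b is None):
            raise ConfigurationError("provide both motifs or neither")
        if a is None:
            a, b = _default_motifs(self.alphabet)
        a, b = tuple(a), tuple(b)
        if Counter(a) != Counter(b):
            raise ConfigurationError(
                "motif_a and motif_b must share the same symbol multiset "
                "(otherwise the class contrast is not order-only)"
            )
        if a == b:
            raise ConfigurationError("motifs must differ in order")
        object.__setattr__(self, "motif_a", a)
        object.__setattr__(self, "motif_b", b)

    @property
    def alphabet(self) -> tuple:
        return tuple(f"s{i:02d}" for i in range(self.alphabet_size))


def _make_sequence(rng: np.random.Generator, cfg: SyntheticConfig, motif: tuple) -> tuple:
    alpha = cfg.alphabet
    lo, hi = cfg.length_law
    L = int(rng.integers(lo, hi + 1))
    seq = [alpha[k] for k in rng.integers(0, len(alpha), size=L)]
    # splice motif copies at random positions, later positions first so
    # earlier insertion points stay valid
    points = sorted((int(p) for p in rng.integers(0, L + 1, size=cfg.motif_copies)), reverse=True)
    for p in points:
        seq[p:p] = list(motif)
    if cfg.noise_rate > 0:
        flip = rng.random(len(seq)) < cfg.noise_rate
        repl = rng.integers(0, len(alpha), size=len(seq))
        seq = [alpha[repl[i]] if flip[i] else t for i, t in enumerate(seq)]
    return tuple(seq)


def generate(config: SyntheticConfig) -> LabeledDataset:
    """Generate a balanced, labelled dataset; deterministic under the seed.

    Classes are interleaved in the output ordering (+1, −1, +1, ...), ids
    are ``p0000, p0001, ...`` and timestamps are integer event indices.
    """
    rng = np.random.default_rng(config.seed)
    seqs = []
    for k in range(config.n_per_class):
        for label, motif in ((1, config.motif_a), (-1, config.motif_b)):
            symbols = _make_sequence(rng, config, motif)
            seqs.append(
                SymbolSequence(
                    id=f"p{len(seqs):04d}",
                    symbols=symbols,
                    timestamps=tuple(range(len(symbols))),
                    label=label,
                    source_table="All",
                )
            )
    return LabeledDataset(tuple(seqs), name=f"synthetic(seed={config.seed})")


def generate_with_pool(config: SyntheticConfig, pool_size: int) -> tuple:
    """Generate a dataset plus a disjoint pool of zero-vector candidates.

    The pool sequences come from the same generative law (classes
    alternating) but carry distinct ids and are not dataset members, the
    held-out arrangement used when the origin must not be an evaluated
    subject.  Returns ``(dataset, pool)``.
    """
    if pool_size < 1:
        raise ParameterError("pool_size must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x9E37]))
    pool = []
    for k in range(pool_size):
        motif = config.motif_a if k % 2 == 0 else config.motif_b
        symbols = _make_sequence(rng, config, motif)
        pool.append(
            SymbolSequence(
                id=f"x0_{k:02d}",
                symbols=symbols,
                timestamps=tuple(range(len(symbols))),
                label=None,
                source_table="All",
            )
        )
    return generate(config), tuple(pool)


def worked_pair() -> tuple:
    """Fixed micro-fixture: ``(x, x', x0, expected)``.

    ``x = (A, B, C)``, ``x' = (B, C, D)``, ``x0 = (B,)``.  With default
    costs (indel 1, substitution 2) every pairwise distance equals
    ``|x| + |y| - 2*LCS``:

    * d(x, x') = 3 + 3 − 2·2 = 2   (LCS "B C")
    * d(x, x0) = 3 + 1 − 2·1 = 2
    * d(x0, x') = 1 + 3 − 2·1 = 2

    and the substitution kernel value is K1 = ½(2 + 2 − 2) = 1.
    """
    x = SymbolSequence("wx", ("A", "B", "C"))
    xp = SymbolSequence("wy", ("B", "C", "D"))
    x0 = SymbolSequence("w0", ("B",))
    expected = {"d_x_xp": 2.0, "d_x_x0": 2.0, "d_x0_xp": 2.0, "k1": 1.0}
    return x, xp, x0, expected
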