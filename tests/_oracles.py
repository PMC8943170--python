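"""Independent reference implementations used only as test oracles.

These deliberately avoid the package's dynamic-programming code path: the
edit distance is a naive memoized recursion straight off the recurrence,
and the LCS is its own classic DP table.
"""

import sys
from functools import lru_cache


def naive_edit_distance(x, y, ins=1.0, dele=1.0, sub=2.0):
    x, y = tuple(x), tuple(y)
    sys.setrecursionlimit(10000)

    @lru_cache(maxsize=None)
    def d(i, j):
        if i == 0:
            return j * ins
        if j == 0:
            return i * dele
        return min(
            d(i - 1, j) + dele,
            d(i, j - 1) + ins,
            d(i - 1, j - 1) + (0.0 if x[i - 1] == y[j - 1] else sub),
        )

    return d(len(x), len(y))


def lcs_length(x, y):
    x, y = tuple(x), tuple(y)
    prev = [0] * (len(y) + 1)
    for xi in x:
        cur = [0] * (len(y) + 1)
        for j, yj in enumerate(y, start=1):
            cur[j] = prev[j - 1] + 1 if xi == yj else max(prev[j], cur[j - 1])
        prev = cur
    return prev[-1]


def random_token_pair(rng, alphabet_size, max_len=12, min_len=0):
    alpha = [f"t{k}" for k in range(alphabet_size)]
    lx, ly = rng.integers(min_len, max_len + 1, size=2)
    x = tuple(alpha[k] for k in rng.integers(0, alphabet_size, size=lx))
    y = tuple(alpha[k] for k in rng.integers(0, alphabet_size, size=ly))
    return x, y
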