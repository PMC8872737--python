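import itertools

import numpy as np
import pytest

from beadmap.seq_align import ScoringScheme


@pytest.fixture
def scoring():
    return ScoringScheme()


def brute_force_best_score(a: str, b: str, scoring: ScoringScheme) -> float:
    """Independent alignment oracle: memoized recursion over the three moves."""
    from functools import lru_cache

    @lru_cache(maxsize=None)
    def rec(i: int, j: int) -> float:
        if i == len(a) and j == len(b):
            return 0.0
        best = -np.inf
        if i < len(a) and j < len(b):
            step = scoring.match if a[i] == b[j] else scoring.mismatch
            best = max(best, rec(i + 1, j + 1) + step)
        if i < len(a):
            best = max(best, rec(i + 1, j) + scoring.gap)
        if j < len(b):
            best = max(best, rec(i, j + 1) + scoring.gap)
        return best

    return rec(0, 0)


def enumerate_alignment_scores(a: str, b: str, scoring: ScoringScheme) -> float:
    """Pure exhaustive enumeration of every global alignment (tiny inputs)."""
    best = [-np.inf]

    def walk(i, j, score):
        if i == len(a) and j == len(b):
            best[0] = max(best[0], score)
            return
        if i < len(a) and j < len(b):
            walk(i + 1, j + 1, score + (scoring.match if a[i] == b[j] else scoring.mismatch))
        if i < len(a):
            walk(i + 1, j, score + scoring.gap)
        if j < len(b):
            walk(i, j + 1, score + scoring.gap)

    walk(0, 0, 0.0)
    return best[0]


def all_sequences(max_len: int, alphabet: str = "ATC"):
    for n in range(max_len + 1):
        for tup in itertools.product(alphabet, repeat=n):
            yield "".join(tup)
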