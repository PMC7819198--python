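"""Longest common subsequence: length, and exhaustive backtracking of all
optimal strings.

The classic dynamic program fills C[i, j] = LCS length of the prefixes
x[:i], y[:j] (0 on the borders, diagonal + 1 on a symbol match, max of left
and up otherwise). Backtracking starts at the lower-right corner and follows
every optimal route, so the full set of distinct LCS strings is recovered;
the number of solutions can grow exponentially, so a guard cap bounds the
set size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, LcsOverflowError

#: Default cap on the number of distinct LCS strings collected.
DEFAULT_MAX_SOLUTIONS = 10_000


@dataclass
class LcsResult:
    length: int
    all_lcs: frozenset[str]
    C: np.ndarray


def _table(x: str, y: str) -> np.ndarray:
    m, n = len(x), len(y)
    C = np.zeros((m + 1, n + 1), dtype=np.int64)
    for i in range(1, m + 1):
        xi = x[i - 1]
        for j in range(1, n + 1):
            if xi == y[j - 1]:
                C[i, j] = C[i - 1, j - 1] + 1
            else:
                C[i, j] = C[i, j - 1] if C[i, j - 1] >= C[i - 1, j] else C[i - 1, j]
    return C


def lcs_length(x: str, y: str) -> int:
    """Length of the longest common subsequence of ``x`` and ``y``."""
    return int(_table(x, y)[len(x), len(y)])


def lcs_all(x: str, y: str, max_solutions: int = DEFAULT_MAX_SOLUTIONS) -> frozenset[str]:
    """The set of *all* distinct LCS strings of ``x`` and ``y``.

    Memoized backtracking over the DP table; both the left and up moves are
    taken whenever they are tied, so no optimal route is missed. Raises
    :class:`LcsOverflowError` if more than ``max_solutions`` strings arise.
    """
    return lcs_result(x, y, max_solutions=max_solutions).all_lcs


def lcs_result(x: str, y: str, max_solutions: int = DEFAULT_MAX_SOLUTIONS) -> LcsResult:
    C = _table(x, y)
    memo: dict[tuple[int, int], frozenset[str]] = {}

    def back(i: int, j: int) -> frozenset[str]:
        if i == 0 or j == 0:
            return frozenset({""})
        key = (i, j)
        if key in memo:
            return memo[key]
        if x[i - 1] == y[j - 1]:
            out = frozenset(s + x[i - 1] for s in back(i - 1, j - 1))
        else:
            parts: set[str] = set()
            if C[i, j - 1] == C[i, j]:
                parts |= back(i, j - 1)
            if C[i - 1, j] == C[i, j]:
                parts |= back(i - 1, j)
            out = frozenset(parts)
        if len(out) > max_solutions:
            raise LcsOverflowError(
                f"more than {max_solutions} distinct longest common subsequences")
        memo[key] = out
        return out

    # iterative deepening is unnecessary: recursion depth is at most m + n
    import sys
    depth = len(x) + len(y) + 50
    if depth > sys.getrecursionlimit():
        old = sys.getrecursionlimit()
        sys.setrecursionlimit(depth)
        try:
            all_lcs = back(len(x), len(y))
        finally:
            sys.setrecursionlimit(old)
    else:
        all_lcs = back(len(x), len(y))
    return LcsResult(length=int(C[len(x), len(y)]), all_lcs=all_lcs, C=C)


def lcs_ratio(x: str, y: str) -> float:
    """LCS length normalized by the shorter input's length; in [0, 1]."""
    if not x and not y:
        raise ConfigurationError("lcs_ratio undefined for two empty strings")
    if not x or not y:
        return 0.0
    return lcs_length(x, y) / min(len(x), len(y))
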