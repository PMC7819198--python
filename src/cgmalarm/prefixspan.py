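"""Frequent-subsequence mining by prefix projection (PrefixSpan).

Patterns are grown one symbol at a time: at each node the locally frequent
symbols of the projection database (the suffixes of all supporting sequences
after the prefix's leftmost embedding) extend the prefix, and the projection
shrinks. Support is the fraction of corpus sequences containing the pattern
as a not-necessarily-contiguous subsequence, counted at most once per
sequence. The anti-monotonicity of support prunes the search exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Union

from .errors import ConfigurationError
from .symbolize import SymbolSequence

Corpus = Sequence[Union[str, SymbolSequence]]


@dataclass(frozen=True)
class Pattern:
    """A mined subsequence with its exact support fraction."""

    symbols: str
    sup: float

    def __len__(self) -> int:
        return len(self.symbols)


def _as_strings(corpus: Corpus) -> list[str]:
    return [s.symbols if isinstance(s, SymbolSequence) else s for s in corpus]


def contains_subsequence(haystack: Union[str, SymbolSequence], needle: str) -> bool:
    """True iff ``needle``'s symbols occur in ``haystack`` in order.

    Greedy left-to-right matching; an empty needle is always contained.
    """
    hay = haystack.symbols if isinstance(haystack, SymbolSequence) else haystack
    it = iter(hay)
    return all(ch in it for ch in needle)


def support(corpus: Corpus, pattern: str) -> float:
    """Fraction of corpus sequences containing ``pattern`` as a subsequence."""
    seqs = _as_strings(corpus)
    if not seqs:
        raise ConfigurationError("support is undefined on an empty corpus")
    return sum(contains_subsequence(s, pattern) for s in seqs) / len(seqs)


def mine(corpus: Corpus, minsup: float) -> list[Pattern]:
    """All patterns with support >= ``minsup``, sorted lexicographically.

    The projection database is held as (sequence index, suffix offset) pairs;
    extending by a symbol advances each offset past that symbol's leftmost
    occurrence, which is sufficient for once-per-sequence support counting
    and keeps suffixes as short as possible.
    """
    seqs = _as_strings(corpus)
    if not seqs:
        raise ConfigurationError("cannot mine an empty corpus")
    if not (0.0 < minsup <= 1.0):
        raise ConfigurationError(f"minsup must be in (0, 1], got {minsup}")
    n = len(seqs)
    results: list[Pattern] = []
    # stack of (prefix, projection as list of (seq index, offset))
    stack: list[tuple[str, list[tuple[int, int]]]] = [
        ("", [(i, 0) for i in range(n)])]
    while stack:
        prefix, proj = stack.pop()
        # locally frequent symbols: count supporting sequences per symbol
        counts: dict[str, int] = {}
        for i, off in proj:
            for ch in set(seqs[i][off:]):
                counts[ch] = counts.get(ch, 0) + 1
        # descending order on the stack yields ascending DFS; final sort below
        for ch in sorted(counts, reverse=True):
            cnt = counts[ch]
            if cnt / n >= minsup:
                new_proj = []
                for i, off in proj:
                    pos = seqs[i].find(ch, off)
                    if pos != -1:
                        new_proj.append((i, pos + 1))
                stack.append((prefix + ch, new_proj))
                results.append(Pattern(symbols=prefix + ch, sup=cnt / n))
    results.sort(key=lambda p: p.symbols)
    return results
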