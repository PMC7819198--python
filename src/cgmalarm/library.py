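"""Construction and refinement of per-level alarm pattern libraries.

For one alarm level the pipeline is: symbolize the training traces, detect
below-threshold events, cut early-alarm and non-alarm windows, mine both
corpora for frequent subsequences, then refine the alarm set in three
passes — drop patterns outside the [L_min, L_e] length band, drop patterns
carried by the non-alarm corpus (they hold no discriminative alarm
information), and drop redundant patterns.

Redundancy is judged under the containment match rule: a pattern fires on
any window that contains it as a subsequence, so a pattern that is a proper
supersequence of another retained pattern can never fire where the shorter
one does not — it is the supersequence that is redundant. The refined
library is therefore the *minimal* antichain: no retained pattern is a
subsequence of another, and every dropped pattern is a supersequence of a
retained one. The shortest-length bound L_min, not absorption into longer
patterns, is the lever that trades missed alarms against false positives.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

from .errors import ConfigurationError, EmptyLibraryError
from .events import (LEVEL_THRESHOLDS, SequenceCorpus, WindowParams, build_corpus)
from .lcs import lcs_length
from .prefixspan import Pattern, contains_subsequence, mine
from .symbolize import DEFAULT_SYMBOL_MAP, GlucoseSeries, SymbolMap

logger = logging.getLogger(__name__)

DEFAULT_MINSUP_ALARM = 0.2
DEFAULT_MINSUP_NON_ALARM = 0.15


@dataclass
class PatternLibrary:
    """A level's refined set of frequent early-alarm patterns."""

    level: str
    threshold_mmol_l: float
    patterns: list[Pattern]
    L_e: int = 12
    L_min: int = 6
    minsup_alarm: float = DEFAULT_MINSUP_ALARM
    minsup_non_alarm: float = DEFAULT_MINSUP_NON_ALARM
    corpus_sizes: dict = field(default_factory=dict)
    built_at: str | None = None  # omitted by default so builds are byte-stable

    def to_json(self) -> str:
        payload = {
            "level": self.level,
            "threshold_mmol_l": self.threshold_mmol_l,
            "L_e": self.L_e,
            "L_min": self.L_min,
            "minsup_alarm": self.minsup_alarm,
            "minsup_non_alarm": self.minsup_non_alarm,
            "patterns": [{"symbols": p.symbols, "support": p.sup} for p in self.patterns],
            "corpus_sizes": self.corpus_sizes,
            "built_at": self.built_at,
        }
        return json.dumps(payload, indent=2, sort_keys=False)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_json() + "\n")

    @classmethod
    def load(cls, path) -> "PatternLibrary":
        with open(path) as fh:
            d = json.load(fh)
        return cls(level=d["level"], threshold_mmol_l=d["threshold_mmol_l"],
                   patterns=[Pattern(p["symbols"], p["support"]) for p in d["patterns"]],
                   L_e=d["L_e"], L_min=d["L_min"], minsup_alarm=d["minsup_alarm"],
                   minsup_non_alarm=d["minsup_non_alarm"],
                   corpus_sizes=d.get("corpus_sizes", {}), built_at=d.get("built_at"))


def _is_subsequence(p: str, q: str) -> bool:
    """p subsequence of q (equivalently, lcs_length(p, q) == len(p))."""
    return len(p) <= len(q) and contains_subsequence(q, p)


def prune_by_length(patterns: list[Pattern], L_min: int, L_e: int) -> list[Pattern]:
    """Keep patterns with L_min <= length <= L_e."""
    if not (0 < L_min <= L_e):
        raise ConfigurationError("require 0 < L_min <= L_e")
    kept = [p for p in patterns if L_min <= len(p) <= L_e]
    if patterns and not kept:
        logger.warning("length pruning removed every pattern (L_min=%d)", L_min)
    return kept


def remove_common(alarm: list[Pattern], non_alarm: list[Pattern],
                  overlap_ratio: float = 1.0) -> list[Pattern]:
    """Drop alarm patterns explained by the non-alarm frequent set.

    An alarm pattern P goes if some non-alarm pattern Q has
    ``lcs_length(P, Q) >= overlap_ratio * len(P)``; at the default ratio 1.0
    that is exactly "P is a subsequence of (or equals) Q".
    """
    full = overlap_ratio >= 1.0
    kept = []
    for p in alarm:
        cut = overlap_ratio * len(p.symbols)
        if full:
            drop = any(_is_subsequence(p.symbols, q.symbols) for q in non_alarm)
        else:
            drop = any(lcs_length(p.symbols, q.symbols) >= cut for q in non_alarm)
        if not drop:
            kept.append(p)
    return kept


def remove_redundant(patterns: list[Pattern]) -> list[Pattern]:
    """Reduce to the minimal antichain under subsequence containment.

    Exact duplicates collapse to a single entry; any pattern that is a proper
    supersequence of another retained pattern is dropped (it can never match
    a window the shorter pattern misses).
    """
    # collapse duplicates, keeping the recorded support of the first
    seen: dict[str, Pattern] = {}
    for p in patterns:
        seen.setdefault(p.symbols, p)
    uniq = sorted(seen.values(), key=lambda p: (len(p.symbols), p.symbols))
    kept: list[Pattern] = []
    for p in uniq:  # ascending length: retained patterns are never subsumed later
        if not any(_is_subsequence(q.symbols, p.symbols) for q in kept):
            kept.append(p)
    return kept


def refine(alarm_patterns: list[Pattern], non_alarm_patterns: list[Pattern],
           params: WindowParams, overlap_ratio: float = 1.0) -> list[Pattern]:
    """Length prune -> cross-library removal -> redundancy removal."""
    pruned = prune_by_length(alarm_patterns, params.L_min, params.L_e)
    logger.info("length pruning: %d -> %d alarm patterns", len(alarm_patterns), len(pruned))
    uncommon = remove_common(pruned, non_alarm_patterns, overlap_ratio)
    logger.info("non-alarm removal: %d -> %d alarm patterns", len(pruned), len(uncommon))
    final = remove_redundant(uncommon)
    logger.info("redundancy removal: %d -> %d alarm patterns", len(uncommon), len(final))
    return final


def build_library_from_corpus(corpus: SequenceCorpus, params: WindowParams,
                              minsup_alarm: float = DEFAULT_MINSUP_ALARM,
                              minsup_non_alarm: float = DEFAULT_MINSUP_NON_ALARM,
                              overlap_ratio: float = 1.0) -> PatternLibrary:
    level = corpus.level or "II"
    if not corpus.early_alarm_seqs:
        raise EmptyLibraryError(level)
    alarm_patterns = mine(corpus.early_alarm_seqs, minsup_alarm)
    non_alarm_patterns = (mine(corpus.non_alarm_seqs, minsup_non_alarm)
                          if corpus.non_alarm_seqs else [])
    final = refine(alarm_patterns, non_alarm_patterns, params, overlap_ratio)
    return PatternLibrary(
        level=level, threshold_mmol_l=LEVEL_THRESHOLDS[level], patterns=final,
        L_e=params.L_e, L_min=params.L_min,
        minsup_alarm=minsup_alarm, minsup_non_alarm=minsup_non_alarm,
        corpus_sizes={"early_alarm": len(corpus.early_alarm_seqs),
                      "non_alarm": len(corpus.non_alarm_seqs),
                      "events": corpus.n_events,
                      "unextractable_events": corpus.n_unextractable})


def build_level_library(cgm: list[GlucoseSeries], level: str,
                        params: WindowParams | None = None,
                        minsup_alarm: float = DEFAULT_MINSUP_ALARM,
                        minsup_non_alarm: float = DEFAULT_MINSUP_NON_ALARM,
                        overlap_ratio: float = 1.0,
                        symbol_map: SymbolMap = DEFAULT_SYMBOL_MAP) -> PatternLibrary:
    """Full pipeline from raw traces to one level's refined pattern library."""
    params = params or WindowParams()
    corpus = build_corpus(cgm, level, params, symbol_map)
    return build_library_from_corpus(corpus, params, minsup_alarm,
                                     minsup_non_alarm, overlap_ratio)
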