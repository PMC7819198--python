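"""Real-time alarm engine: slide a window over symbolized CGM, match each
window against the per-level pattern libraries, and emit the highest-level
alert.

A window matches a pattern P when lcs_length(window, P) / len(P) reaches the
match-ratio threshold; at the default ratio 1.0 that is full containment of
P in the window, the strictest reading and the one that minimizes false
positives. Levels are tested in priority order I > II > III and only the
highest matching level fires at a position; a per-level refractory span
suppresses repeat alerts for the same episode.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .errors import ConfigurationError
from .events import LEVEL_COLORS, LEVEL_ORDER
from .lcs import lcs_length
from .library import PatternLibrary
from .prefixspan import Pattern, contains_subsequence
from .symbolize import SymbolSequence


@dataclass
class Alert:
    level: str
    T_end: pd.Timestamp | None
    end_index: int  # index of the window's last sample in the source sequence
    window: str
    matched_pattern: Pattern
    match_ratio: float

    @property
    def color(self) -> str:
        return LEVEL_COLORS[self.level]


def match_window(window: SymbolSequence | str, lib: PatternLibrary,
                 match_ratio_min: float = 1.0) -> tuple[Pattern, float] | None:
    """Best matching library pattern for one window, or None.

    Among patterns reaching the match ratio, the longest wins; ties break by
    higher support, then lexicographic order.
    """
    w = window.symbols if isinstance(window, SymbolSequence) else window
    if len(w) != lib.L_e:
        raise ConfigurationError(f"window length {len(w)} != library L_e {lib.L_e}")
    best: tuple[Pattern, float] | None = None

    def key(p: Pattern):
        return (len(p.symbols), p.sup, _inv_lex(p.symbols))

    full_containment = match_ratio_min >= 1.0
    for p in lib.patterns:
        if full_containment:
            # containment is the LCS criterion at ratio 1.0; test it directly
            if not contains_subsequence(w, p.symbols):
                continue
            ratio = 1.0
        else:
            ratio = lcs_length(w, p.symbols) / len(p.symbols)
            if ratio < match_ratio_min:
                continue
        if best is None or key(p) > key(best[0]):
            best = (p, ratio)
    return best


def _inv_lex(s: str) -> tuple[int, ...]:
    # larger is lexicographically *smaller*: negate code points
    return tuple(-ord(c) for c in s)


def stream_alarms(seq: SymbolSequence, libraries: dict[str, PatternLibrary],
                  match_ratio_min: float = 1.0,
                  refractory: int | None = None) -> list[Alert]:
    """Run the sliding-window matcher over a full symbol sequence.

    The window advances one sample (5 min) at a time. ``libraries`` maps
    level name to library; levels may be absent. ``refractory`` is the
    number of samples during which a level stays silent after firing
    (default: one window length).
    """
    libs = [(lvl, libraries[lvl]) for lvl in LEVEL_ORDER if libraries.get(lvl) is not None]
    if not libs:
        return []
    Le = libs[0][1].L_e
    if any(lib.L_e != Le for _, lib in libs):
        raise ConfigurationError("all libraries must share the window length L_e")
    if refractory is None:
        refractory = Le
    last_fired = {lvl: None for lvl, _ in libs}
    alerts: list[Alert] = []
    for end in range(Le - 1, len(seq)):
        window = seq.symbols[end - Le + 1:end + 1]
        for lvl, lib in libs:
            hit = match_window(window, lib, match_ratio_min)
            if hit is None:
                continue
            # highest matching level claims the position, fired or suppressed
            if last_fired[lvl] is None or end - last_fired[lvl] >= refractory:
                pattern, ratio = hit
                t_end = seq.times[end] if seq.times is not None else None
                alerts.append(Alert(level=lvl, T_end=t_end, end_index=end,
                                    window=window, matched_pattern=pattern,
                                    match_ratio=ratio))
                last_fired[lvl] = end
            break
    return alerts
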