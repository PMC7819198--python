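"""Symbolization of CGM glucose values.

Real-valued glucose traces are mapped onto a 15-letter alphabet over fixed,
left-open/right-closed concentration bins. Bins near the hypoglycemia
thresholds are narrower so that fluctuations close to an alarm boundary are
resolved, and every alarm threshold (3.0, 3.9, 4.4 mmol/L) coincides with a
bin boundary, so one map serves all three alarm levels.
"""

from __future__ import annotations

import bisect
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError, InvalidMeasurementError

logger = logging.getLogger(__name__)

#: mmol/L per mg/dL, offered for I/O conversion only; bins are defined in mmol/L.
MGDL_PER_MMOLL = 18.0182


@dataclass(frozen=True)
class SymbolMap:
    """An ordered partition of (2.2, 22.2] mmol/L into symbol bins.

    ``bins`` is an ascending list of ``(lower_exclusive, upper_inclusive,
    symbol)`` triples. Values at or below the lowest bound clamp to the lowest
    symbol, values above the highest bound clamp to the highest symbol (CGM
    sensors saturate near these limits); both clamps log a warning.
    """

    bins: tuple[tuple[float, float, str], ...]
    #: upper bounds that must be present so alarm rules align with bins
    required_boundaries: tuple[float, ...] = (3.0, 3.9, 4.4)

    def __post_init__(self) -> None:
        if len(self.bins) != len({s for _, _, s in self.bins}):
            raise ConfigurationError("symbol map symbols must be unique")
        uppers = [hi for _, hi, _ in self.bins]
        lowers = [lo for lo, _, _ in self.bins]
        if any(hi <= lo for lo, hi, _ in self.bins):
            raise ConfigurationError("each bin needs lower < upper")
        # bins must tile the range: each upper bound is the next lower bound
        for prev_hi, next_lo in zip(uppers[:-1], lowers[1:]):
            if not math.isclose(prev_hi, next_lo, abs_tol=1e-12):
                raise ConfigurationError("symbol map bins must tile with no gaps or overlaps")
        for b in self.required_boundaries:
            if not any(math.isclose(b, hi, abs_tol=1e-12) for hi in uppers):
                raise ConfigurationError(f"alarm threshold {b} must lie on a bin boundary")

    @property
    def alphabet(self) -> str:
        """Symbols in ascending glucose order."""
        return "".join(s for _, _, s in self.bins)

    @property
    def lower_limit(self) -> float:
        return self.bins[0][0]

    @property
    def upper_limit(self) -> float:
        return self.bins[-1][1]

    def midpoint(self, symbol: str) -> float:
        """Midpoint glucose of a symbol's bin (used by the trace simulator)."""
        for lo, hi, s in self.bins:
            if s == symbol:
                return (lo + hi) / 2.0
        raise ConfigurationError(f"unknown symbol {symbol!r}")

    def to_file(self, path) -> None:
        """Serialize as a plain key-value file: ``symbol: [lower, upper]``."""
        data = {s: [lo, hi] for lo, hi, s in self.bins}
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    @classmethod
    def from_file(cls, path) -> "SymbolMap":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        bins = sorted(((float(lo), float(hi), str(s)) for s, (lo, hi) in data.items()),
                      key=lambda t: t[0])
        return cls(bins=tuple(bins))


#: The default clinical map: narrow 0.5 mmol/L bins around the hypoglycemia
#: thresholds, wider bins in the hyperglycemic range.
DEFAULT_SYMBOL_MAP = SymbolMap(bins=(
    (2.2, 3.0, "y"),
    (3.0, 3.9, "z"),
    (3.9, 4.4, "a"),
    (4.4, 4.9, "b"),
    (4.9, 5.4, "c"),
    (5.4, 5.9, "d"),
    (5.9, 6.4, "e"),
    (6.4, 7.9, "f"),
    (7.9, 9.2, "g"),
    (9.2, 10.5, "h"),
    (10.5, 11.8, "i"),
    (11.8, 13.3, "j"),
    (13.3, 14.8, "k"),
    (14.8, 16.3, "l"),
    (16.3, 22.2, "m"),
))


@dataclass
class GlucoseSeries:
    """A timestamped CGM record in mmol/L for one subject."""

    times: pd.DatetimeIndex
    values: np.ndarray
    subject_id: str = "subject"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.times) != len(self.values):
            raise ConfigurationError("times and values must have equal length")

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class SymbolSequence:
    """A symbol string plus, per symbol, its index in the source series."""

    symbols: str
    source_indices: np.ndarray = field(default=None)  # type: ignore[assignment]
    times: pd.DatetimeIndex | None = None

    def __post_init__(self) -> None:
        if self.source_indices is None:
            self.source_indices = np.arange(len(self.symbols))
        self.source_indices = np.asarray(self.source_indices, dtype=int)
        if len(self.symbols) != len(self.source_indices):
            raise ConfigurationError("symbols and source_indices must have equal length")
        if len(self.source_indices) > 1 and not np.all(np.diff(self.source_indices) > 0):
            raise ConfigurationError("source_indices must be strictly increasing")

    def __len__(self) -> int:
        return len(self.symbols)


def symbolize_value(g: float, symbol_map: SymbolMap = DEFAULT_SYMBOL_MAP) -> str:
    """Map one glucose value (mmol/L) to its symbol.

    The unique bin with ``lower < g <= upper`` wins; out-of-range values clamp
    to the extreme symbols with a logged warning.
    """
    if not (isinstance(g, (int, float, np.floating, np.integer)) and math.isfinite(g)) or g <= 0:
        raise InvalidMeasurementError(f"invalid glucose measurement: {g!r}")
    if g <= symbol_map.lower_limit:
        logger.warning("glucose %.2f mmol/L at or below sensor floor %.1f; clamping to %r",
                       g, symbol_map.lower_limit, symbol_map.bins[0][2])
        return symbol_map.bins[0][2]
    if g > symbol_map.upper_limit:
        logger.warning("glucose %.2f mmol/L above sensor ceiling %.1f; clamping to %r",
                       g, symbol_map.upper_limit, symbol_map.bins[-1][2])
        return symbol_map.bins[-1][2]
    uppers = [hi for _, hi, _ in symbol_map.bins]
    idx = bisect.bisect_left(uppers, g)
    return symbol_map.bins[idx][2]


def symbolize_series(series: GlucoseSeries,
                     symbol_map: SymbolMap = DEFAULT_SYMBOL_MAP) -> SymbolSequence:
    """Symbolize a whole series, one symbol per sample, order preserved."""
    if len(series) == 0:
        return SymbolSequence(symbols="", source_indices=np.array([], dtype=int),
                              times=series.times)
    symbols = "".join(symbolize_value(v, symbol_map) for v in series.values)
    return SymbolSequence(symbols=symbols,
                          source_indices=np.arange(len(series)),
                          times=series.times)


def symbols_at_or_below(threshold: float,
                        symbol_map: SymbolMap = DEFAULT_SYMBOL_MAP) -> frozenset[str]:
    """Symbols whose entire bin lies at or below ``threshold`` mmol/L.

    The threshold must coincide with a bin upper boundary (the alarm rule
    "glucose <= threshold" is then exactly expressible on symbols).
    """
    uppers = [hi for _, hi, _ in symbol_map.bins]
    if not any(math.isclose(threshold, hi, abs_tol=1e-12) for hi in uppers):
        raise ConfigurationError(
            f"threshold {threshold} mmol/L is not a bin boundary of the symbol map")
    return frozenset(s for _, hi, s in symbol_map.bins if hi <= threshold + 1e-12)


def mgdl_to_mmoll(values: Iterable[float] | float):
    """Units converter for I/O convenience (mmol/L = mg/dL / 18.0182)."""
    return np.asarray(values, dtype=float) / MGDL_PER_MMOLL
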