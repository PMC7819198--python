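"""Alarm-event detection and training-sequence extraction.

An alarm event is a maximal run of consecutive samples at or below a level's
glucose threshold. The fixed-length window immediately preceding an event is
an early-alarm sequence (the mining unit for alarm patterns); stretches
between events are chopped into equally long non-alarm sequences so both
corpora are mined at the same sequence length.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .symbolize import (DEFAULT_SYMBOL_MAP, GlucoseSeries, SymbolMap,
                        SymbolSequence, symbolize_series, symbols_at_or_below)

logger = logging.getLogger(__name__)

#: Alarm levels, their glucose thresholds (mmol/L) and alert colors.
#: Level I (red) is severe hypoglycemia, level II (orange) the diagnostic
#: threshold, level III (yellow) an early warning band.
LEVEL_THRESHOLDS: dict[str, float] = {"I": 3.0, "II": 3.9, "III": 4.4}
LEVEL_COLORS: dict[str, str] = {"I": "red", "II": "orange", "III": "yellow"}
LEVEL_ORDER: tuple[str, ...] = ("I", "II", "III")  # highest priority first


def level_for_threshold(threshold: float) -> str | None:
    for lvl, thr in LEVEL_THRESHOLDS.items():
        if abs(thr - threshold) < 1e-9:
            return lvl
    return None


@dataclass
class AlarmEvent:
    """A maximal below-threshold run: start index S_i, length L_w samples."""

    S_i: int
    L_w: int
    level: str | None = None
    T_h: pd.Timestamp | None = None

    @property
    def end(self) -> int:
        """One past the last below-threshold sample."""
        return self.S_i + self.L_w


@dataclass
class WindowParams:
    """Windowing configuration shared across the pipeline.

    L_e is the early-alarm window length in samples (12 samples = 1 h at
    5-min sampling); L_min the shortest retained pattern length (half of
    L_e); lookback for non-alarm windows extends to the previous event's
    end.
    """

    L_e: int = 12
    L_min: int = 6
    sampling_interval: float = 5.0  # minutes per sample

    def __post_init__(self) -> None:
        if not (0 < self.L_min <= self.L_e):
            raise ConfigurationError("require 0 < L_min <= L_e")


@dataclass
class SequenceCorpus:
    """Pooled fixed-length training windows for one alarm level."""

    early_alarm_seqs: list[SymbolSequence] = field(default_factory=list)
    non_alarm_seqs: list[SymbolSequence] = field(default_factory=list)
    level: str | None = None
    n_events: int = 0
    n_unextractable: int = 0


def _slice(seq: SymbolSequence, start: int, stop: int) -> SymbolSequence:
    times = seq.times[start:stop] if seq.times is not None else None
    return SymbolSequence(symbols=seq.symbols[start:stop],
                          source_indices=seq.source_indices[start:stop],
                          times=times)


def detect_alarm_events(seq: SymbolSequence, threshold: float,
                        symbol_map: SymbolMap = DEFAULT_SYMBOL_MAP) -> list[AlarmEvent]:
    """Find maximal runs of at-or-below-threshold symbols.

    The threshold must sit on a bin boundary so the glucose rule is exact on
    symbols.
    """
    below = symbols_at_or_below(threshold, symbol_map)
    level = level_for_threshold(threshold)
    events: list[AlarmEvent] = []
    i, n = 0, len(seq)
    while i < n:
        if seq.symbols[i] in below:
            j = i
            while j < n and seq.symbols[j] in below:
                j += 1
            t_h = seq.times[i] if seq.times is not None else None
            events.append(AlarmEvent(S_i=i, L_w=j - i, level=level, T_h=t_h))
            i = j
        else:
            i += 1
    return events


def extract_early_alarm_sequences(seq: SymbolSequence, events: list[AlarmEvent],
                                  params: WindowParams) -> list[SymbolSequence]:
    """The L_e-sample window ending exactly at each event's start.

    Events too close to the series start (S_i < L_e), or whose window would
    overlap the preceding event's below-threshold run, are skipped and
    counted — those alarms cannot be anticipated from a full-length history.
    """
    out: list[SymbolSequence] = []
    prev_end = 0
    for ev in events:
        start = ev.S_i - params.L_e
        if start < 0 or start < prev_end:
            logger.info("event at index %d skipped: no full %d-sample history", ev.S_i, params.L_e)
        else:
            out.append(_slice(seq, start, ev.S_i))
        prev_end = ev.end
    return out


def extract_non_alarm_sequences(seq: SymbolSequence, events: list[AlarmEvent],
                                params: WindowParams) -> list[SymbolSequence]:
    """Chop between-event stretches into non-overlapping L_e windows.

    Eligible stretches run from one event's end (or the series start) to the
    next event's early-alarm window start (or the series end); each is cut
    left-aligned into length-L_e pieces and any shorter remainder dropped, so
    both corpora share one sequence length.
    """
    Le = params.L_e
    regions: list[tuple[int, int]] = []
    prev_end = 0
    for ev in events:
        regions.append((prev_end, ev.S_i - Le))
        prev_end = ev.end
    regions.append((prev_end, len(seq)))
    out: list[SymbolSequence] = []
    for lo, hi in regions:
        pos = lo
        while pos + Le <= hi:
            out.append(_slice(seq, pos, pos + Le))
            pos += Le
    return out


def segment_series(series: GlucoseSeries, sampling_interval: float = 5.0,
                   max_gap_factor: float = 2.0,
                   interpolate_single: bool = False) -> list[GlucoseSeries]:
    """Split a series at sensor gaps longer than ``max_gap_factor`` intervals.

    With ``interpolate_single`` a gap of exactly one missing sample is filled
    by linear interpolation instead of splitting.
    """
    if len(series) < 2:
        return [series]
    step = pd.Timedelta(minutes=sampling_interval)
    if interpolate_single:
        times = [series.times[0]]
        values = [series.values[0]]
        for t, v in zip(series.times[1:], series.values[1:]):
            dt = t - times[-1]
            if abs(dt / step - 2.0) < 1e-9:
                times.append(times[-1] + step)
                values.append((values[-1] + v) / 2.0)
            times.append(t)
            values.append(v)
        series = GlucoseSeries(times=pd.DatetimeIndex(times), values=np.array(values),
                               subject_id=series.subject_id)
    gaps = np.flatnonzero(np.diff(series.times.values) > max_gap_factor * step.to_numpy())
    if len(gaps) == 0:
        return [series]
    out, start = [], 0
    for g in gaps:
        out.append(GlucoseSeries(times=series.times[start:g + 1],
                                 values=series.values[start:g + 1],
                                 subject_id=series.subject_id))
        start = g + 1
    out.append(GlucoseSeries(times=series.times[start:], values=series.values[start:],
                             subject_id=series.subject_id))
    logger.info("series %s split into %d segments at sensor gaps", series.subject_id, len(out))
    return out


def build_corpus(series_list: list[GlucoseSeries], level: str, params: WindowParams,
                 symbol_map: SymbolMap = DEFAULT_SYMBOL_MAP) -> SequenceCorpus:
    """Pool early-alarm and non-alarm windows for one level across subjects."""
    if level not in LEVEL_THRESHOLDS:
        raise ConfigurationError(f"unknown alarm level {level!r}")
    threshold = LEVEL_THRESHOLDS[level]
    corpus = SequenceCorpus(level=level)
    for series in series_list:
        for segment in segment_series(series, sampling_interval=params.sampling_interval):
            seq = symbolize_series(segment, symbol_map)
            events = detect_alarm_events(seq, threshold, symbol_map)
            early = extract_early_alarm_sequences(seq, events, params)
            corpus.early_alarm_seqs.extend(early)
            corpus.non_alarm_seqs.extend(extract_non_alarm_sequences(seq, events, params))
            corpus.n_events += len(events)
            corpus.n_unextractable += len(events) - len(early)
    return corpus
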