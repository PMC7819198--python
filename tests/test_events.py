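"""Event detection and training-window extraction."""

import numpy as np
import pandas as pd
import pytest

from cgmalarm import (GlucoseSeries, SymbolSequence, WindowParams,
                      detect_alarm_events, extract_early_alarm_sequences,
                      extract_non_alarm_sequences, segment_series,
                      symbolize_series, symbols_at_or_below)
from cgmalarm.errors import ConfigurationError


def seq(symbols: str) -> SymbolSequence:
    return SymbolSequence(symbols=symbols)


def test_detect_single_run():
    events = detect_alarm_events(seq("ffzzf"), 3.9)
    assert [(e.S_i, e.L_w) for e in events] == [(2, 2)]
    assert events[0].level == "II"


def test_detect_no_events():
    assert detect_alarm_events(seq("fffff"), 3.9) == []


def test_detect_threshold_three_excludes_z():
    events = detect_alarm_events(seq("yzfzy"), 3.0)
    assert [(e.S_i, e.L_w) for e in events] == [(0, 1), (4, 1)]


def test_detect_run_to_series_end():
    events = detect_alarm_events(seq("ffzz"), 3.9)
    assert [(e.S_i, e.L_w) for e in events] == [(2, 2)]


def _with_events(length: int, runs: list[tuple[int, int]]) -> SymbolSequence:
    symbols = ["f"] * length
    for start, lw in runs:
        for i in range(start, start + lw):
            symbols[i] = "z"
    return seq("".join(symbols))


def test_early_window_arithmetic():
    s = _with_events(30, [(20, 2)])
    events = detect_alarm_events(s, 3.9)
    windows = extract_early_alarm_sequences(s, events, WindowParams())
    assert len(windows) == 1
    assert list(windows[0].source_indices) == list(range(8, 20))


def test_early_window_skipped_near_series_start():
    s = _with_events(30, [(5, 2)])
    events = detect_alarm_events(s, 3.9)
    assert extract_early_alarm_sequences(s, events, WindowParams()) == []


def test_two_events_two_windows():
    s = _with_events(40, [(15, 1), (28, 1)])
    events = detect_alarm_events(s, 3.9)
    windows = extract_early_alarm_sequences(s, events, WindowParams())
    assert [list(w.source_indices[[0, -1]]) for w in windows] == [[3, 14], [16, 27]]


def test_early_window_skipped_when_overlapping_previous_run():
    # second event starts 8 samples after the first run ends
    s = _with_events(60, [(20, 3), (31, 1)])
    events = detect_alarm_events(s, 3.9)
    windows = extract_early_alarm_sequences(s, events, WindowParams())
    assert len(windows) == 1  # only the first event has a clean 12-sample history


def test_non_alarm_chopping_discards_remainder():
    # stretch between first run's end (20) and second window start (50) is 30
    s = _with_events(70, [(18, 2), (62, 1)])
    events = detect_alarm_events(s, 3.9)
    windows = extract_non_alarm_sequences(s, events, WindowParams())
    assert len(windows) == 2
    assert list(windows[0].source_indices[[0, -1]]) == [20, 31]
    assert list(windows[1].source_indices[[0, -1]]) == [32, 43]


def test_non_alarm_gap_shorter_than_window_yields_nothing():
    s = _with_events(36, [(12, 1), (35, 1)])  # stretch 13..22 is 10 < 12
    events = detect_alarm_events(s, 3.9)
    assert extract_non_alarm_sequences(s, events, WindowParams()) == []


def test_non_alarm_uses_leading_and_trailing_stretches():
    s = _with_events(60, [(30, 3)])
    events = detect_alarm_events(s, 3.9)
    windows = extract_non_alarm_sequences(s, events, WindowParams())
    # leading stretch [0, 18) -> 1 window; trailing [33, 60) -> 2 windows
    assert len(windows) == 3
    starts = [w.source_indices[0] for w in windows]
    assert starts == [0, 33, 45]


def test_windows_never_touch_event_runs_or_early_windows():
    rng = np.random.default_rng(5)
    for _ in range(50):
        n = int(rng.integers(30, 120))
        symbols = rng.choice(list("fgz"), size=n, p=[0.55, 0.3, 0.15])
        s = seq("".join(symbols))
        params = WindowParams()
        events = detect_alarm_events(s, 3.9)
        early = extract_early_alarm_sequences(s, events, params)
        non = extract_non_alarm_sequences(s, events, params)
        run_idx = {i for e in events for i in range(e.S_i, e.end)}
        early_idx = {i for w in early for i in w.source_indices}
        for w in early + non:
            assert len(w) == params.L_e
        for w in early:
            # the window ends right where the below-threshold run begins
            assert w.source_indices[-1] + 1 in {e.S_i for e in events}
            assert not run_idx & set(w.source_indices)
        for w in non:
            assert not run_idx & set(w.source_indices)
            assert not early_idx & set(w.source_indices)


def test_detection_agrees_with_raw_glucose_scan():
    """Symbol-level runs equal brute-force runs on the raw values, because
    every alarm threshold sits on a bin boundary."""
    rng = np.random.default_rng(6)
    for threshold in (3.0, 3.9, 4.4):
        values = rng.uniform(2.4, 12.0, size=400)
        series = GlucoseSeries(
            times=pd.date_range("2024-01-01", periods=400, freq="5min"),
            values=values)
        detected = detect_alarm_events(symbolize_series(series), threshold)
        below = values <= threshold
        brute = []
        i = 0
        while i < len(below):
            if below[i]:
                j = i
                while j < len(below) and below[j]:
                    j += 1
                brute.append((i, j - i))
                i = j
            else:
                i += 1
        assert [(e.S_i, e.L_w) for e in detected] == brute


def test_level_thresholds_nest_on_symbols():
    assert symbols_at_or_below(3.0) <= symbols_at_or_below(3.9) <= symbols_at_or_below(4.4)


def test_event_nesting_on_cohort(small_cohort):
    """Every severe (level-I) run lies inside some level-II run, and every
    level-II run inside a level-III run."""
    series_list, truth = small_cohort
    for sid, per_level in truth.items():
        for inner, outer in (("I", "II"), ("II", "III")):
            for ev in per_level[inner]:
                assert any(o.S_i <= ev.S_i and ev.end <= o.end
                           for o in per_level[outer])


def test_segment_series_splits_at_gaps():
    times = pd.DatetimeIndex(
        list(pd.date_range("2024-01-01 00:00", periods=5, freq="5min"))
        + list(pd.date_range("2024-01-01 01:00", periods=5, freq="5min")))
    series = GlucoseSeries(times=times, values=np.full(10, 7.0))
    parts = segment_series(series)
    assert [len(p) for p in parts] == [5, 5]


def test_segment_series_interpolates_single_gap():
    times = pd.DatetimeIndex(["2024-01-01 00:00", "2024-01-01 00:05",
                              "2024-01-01 00:15"])  # one missing sample
    series = GlucoseSeries(times=times, values=np.array([7.0, 7.0, 8.0]))
    parts = segment_series(series, interpolate_single=True)
    assert len(parts) == 1
    assert len(parts[0]) == 4
    assert parts[0].values[2] == pytest.approx(7.5)


def test_window_params_validation():
    with pytest.raises(ConfigurationError):
        WindowParams(L_e=12, L_min=13)
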