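"""Evaluation indicators and alert-to-event attribution."""

import numpy as np
import pandas as pd
import pytest

from cgmalarm import (AlarmEvent, Alert, ConfigurationError, ConfusionCounts,
                      Pattern, UndefinedMetricError, attribute_alerts,
                      early_alarm_time, evaluate, false_positive_rate,
                      missing_alarm_rate, sensitivity)


@pytest.mark.parametrize("tp,fn,fp,sens,fpr,miss", [
    (67, 11, 21, 85.90, 23.86, 14.10),
    (176, 43, 37, 80.37, 17.37, 19.63),
    (267, 75, 42, 78.07, 13.59, 21.93),
])
def test_indicator_arithmetic(tp, fn, fp, sens, fpr, miss):
    c = ConfusionCounts(TP=tp, FN=fn, FP=fp)
    assert sensitivity(c) == sens
    assert false_positive_rate(c) == fpr
    assert missing_alarm_rate(c) == miss


def test_indicator_edge_cases():
    assert sensitivity(ConfusionCounts(TP=0, FN=5)) == 0.0
    assert false_positive_rate(ConfusionCounts(TP=10, FP=0)) == 0.0
    assert missing_alarm_rate(ConfusionCounts(TP=7, FN=0)) == 0.0


def test_undefined_metrics_raise():
    with pytest.raises(UndefinedMetricError):
        sensitivity(ConfusionCounts())
    with pytest.raises(UndefinedMetricError):
        false_positive_rate(ConfusionCounts(FN=3))
    with pytest.raises(UndefinedMetricError):
        missing_alarm_rate(ConfusionCounts(FP=3))


def test_negative_counts_rejected():
    with pytest.raises(ConfigurationError):
        ConfusionCounts(TP=-1)


def test_sensitivity_and_missing_rate_are_complements():
    rng = np.random.default_rng(31)
    for _ in range(200):
        tp = int(rng.integers(0, 400))
        fn = int(rng.integers(0, 400))
        if tp + fn == 0:
            continue
        c = ConfusionCounts(TP=tp, FN=fn)
        # the two indicators are exact complements; independent 2-dp
        # rounding can split a half-cent tie, never more
        assert abs(sensitivity(c) + missing_alarm_rate(c) - 100.0) <= 0.01 + 1e-9


def test_rounding_is_half_up():
    # 176/219 = 80.3652...% -> 80.37, not the truncated 80.36
    assert sensitivity(ConfusionCounts(TP=176, FN=43)) == 80.37


def test_early_alarm_time_subtraction():
    assert early_alarm_time("2024-01-01 12:00", "2024-01-01 11:30") == 30.0
    assert early_alarm_time("2024-01-01 12:00", "2024-01-01 12:00") == 0.0
    t = pd.date_range("2024-01-01", periods=101, freq="5min")
    assert early_alarm_time(t[100], t[96]) == 20.0
    with pytest.raises(ConfigurationError):
        early_alarm_time("2024-01-01 12:00", "2024-01-01 12:05")


def _alert(level, t_end):
    return Alert(level=level, T_end=pd.Timestamp(t_end), end_index=0,
                 window="f" * 12, matched_pattern=Pattern("gfedcb", 1.0),
                 match_ratio=1.0)


def _event(level, t_h):
    return AlarmEvent(S_i=0, L_w=2, level=level, T_h=pd.Timestamp(t_h))


def test_attribution_basic_true_positive():
    counts, leads = attribute_alerts([_event("II", "2024-01-01 10:00")],
                                     [_alert("II", "2024-01-01 09:40")])
    assert (counts.TP, counts.FP, counts.FN) == (1, 0, 0)
    assert leads == [20.0]


def test_alert_without_event_is_false_positive():
    counts, leads = attribute_alerts([], [_alert("II", "2024-01-01 09:40")])
    assert (counts.TP, counts.FP, counts.FN) == (0, 1, 0)
    assert leads == []


def test_two_alerts_one_event_leads_from_earliest():
    counts, leads = attribute_alerts(
        [_event("II", "2024-01-01 10:00")],
        [_alert("II", "2024-01-01 09:50"), _alert("II", "2024-01-01 09:30")])
    assert (counts.TP, counts.FP) == (1, 0)
    assert leads == [30.0]


def test_alert_outside_horizon_is_false_positive():
    counts, _ = attribute_alerts([_event("II", "2024-01-01 10:00")],
                                 [_alert("II", "2024-01-01 08:30")], horizon=60)
    assert (counts.TP, counts.FP, counts.FN) == (0, 1, 1)


def test_alert_at_or_after_onset_is_not_early():
    counts, _ = attribute_alerts([_event("II", "2024-01-01 10:00")],
                                 [_alert("II", "2024-01-01 10:00")])
    assert (counts.TP, counts.FP, counts.FN) == (0, 1, 1)


def test_attribution_conserves_alerts():
    rng = np.random.default_rng(33)
    base = pd.Timestamp("2024-01-01")
    for _ in range(50):
        events = [_event("II", base + pd.Timedelta(minutes=int(m)))
                  for m in np.sort(rng.choice(np.arange(60, 2000, 30),
                                              size=rng.integers(0, 6), replace=False))]
        alerts = [_alert("II", base + pd.Timedelta(minutes=int(m)))
                  for m in rng.integers(0, 2000, size=rng.integers(0, 12))]
        counts, leads = attribute_alerts(events, alerts)
        assert counts.TP + counts.FN == len(events)
        assert counts.FP <= len(alerts)
        assert counts.TP <= len(alerts) - counts.FP  # >=1 alert per TP event
        assert all(lead >= 0 for lead in leads)


def test_negative_horizon_rejected():
    with pytest.raises(ConfigurationError):
        attribute_alerts([], [], horizon=-5)


def test_report_table_and_json():
    report = evaluate({"II": [_event("II", "2024-01-01 10:00")]},
                      [_alert("II", "2024-01-01 09:40")])
    d = report.as_dict()["II"]
    assert d["sensitivity_pct"] == 100.0
    assert d["missing_alarm_rate_pct"] == 0.0
    assert d["average_early_alarm_time_min"] == 20.0
    table = report.to_table()
    assert "Sensitivity (%)" in table and "Missing alarm rate (%)" in table
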