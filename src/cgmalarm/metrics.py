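"""Event-level evaluation of the alarm system.

Ground truth is a list of hypoglycemia events (onset time T_h); predictions
are alerts (window endpoint T_end). An event counts as a true positive when
at least one same-level alert lands inside the attribution horizon before
onset; alerts attributable to no event are false positives. The headline
indicators are

    sensitivity        = TP / (TP + FN) * 100%
    false-positive     = FP / (FP + TP) * 100%
    missing alarm rate = (1 - TP / (TP + FN)) * 100%
    early alarm time   = T_h - T_end   (minutes)

Percentages are reported to two decimals, round-half-up. TN (non-alarm
windows correctly unmatched) is tallied for completeness but enters none of
the three headline indicators.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

from .errors import ConfigurationError, UndefinedMetricError
from .events import AlarmEvent
from .engine import Alert


def _pct(numerator: int, denominator: int) -> float:
    """Percentage to 2 decimals, round-half-up (presentation convention)."""
    d = Decimal(numerator) * 100 / Decimal(denominator)
    return float(d.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass
class ConfusionCounts:
    TP: int = 0
    FP: int = 0
    FN: int = 0
    TN: int = 0

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.FN, self.TN) < 0:
            raise ConfigurationError("confusion counts must be non-negative")


def sensitivity(c: ConfusionCounts) -> float:
    """100 * TP / (TP + FN), the fraction of events alarmed in time."""
    if c.TP + c.FN == 0:
        raise UndefinedMetricError("sensitivity undefined with no ground-truth events")
    return _pct(c.TP, c.TP + c.FN)


def false_positive_rate(c: ConfusionCounts) -> float:
    """100 * FP / (FP + TP), the fraction of alerts that were spurious."""
    if c.FP + c.TP == 0:
        raise UndefinedMetricError("false-positive rate undefined with no alerts attributed")
    return _pct(c.FP, c.FP + c.TP)


def missing_alarm_rate(c: ConfusionCounts) -> float:
    """100 * (1 - TP / (TP + FN)); the exact complement of sensitivity."""
    if c.TP + c.FN == 0:
        raise UndefinedMetricError("missing alarm rate undefined with no ground-truth events")
    return _pct(c.FN, c.TP + c.FN)


def early_alarm_time(T_h, T_end) -> float:
    """Minutes between the alert window's endpoint and hypoglycemia onset."""
    T_h, T_end = pd.Timestamp(T_h), pd.Timestamp(T_end)
    if T_end > T_h:
        raise ConfigurationError("an alert after onset is not an early alarm")
    return (T_h - T_end).total_seconds() / 60.0


def attribute_alerts(events: list[AlarmEvent], alerts: list[Alert],
                     horizon: float = 60.0) -> tuple[ConfusionCounts, list[float]]:
    """Attribute alerts to events within ``horizon`` minutes before onset.

    Every alert is either credited to the first event whose pre-onset
    horizon contains its T_end, or counted as a false positive — never both,
    never dropped. Each hit event's lead time comes from its earliest
    attributed alert.
    """
    if horizon <= 0:
        raise ConfigurationError("attribution horizon must be positive")
    h = pd.Timedelta(minutes=horizon)
    attributed: dict[int, list[pd.Timestamp]] = {}
    fp = 0
    for alert in alerts:
        hit = None
        for k, ev in enumerate(events):
            if ev.T_h - h <= alert.T_end < ev.T_h:
                hit = k
                break
        if hit is None:
            fp += 1
        else:
            attributed.setdefault(hit, []).append(alert.T_end)
    leads = [early_alarm_time(events[k].T_h, min(t_ends))
             for k, t_ends in sorted(attributed.items())]
    counts = ConfusionCounts(TP=len(attributed), FP=fp,
                             FN=len(events) - len(attributed))
    return counts, leads


@dataclass
class LevelReport:
    level: str
    counts: ConfusionCounts
    lead_times_min: list[float] = field(default_factory=list)
    n_alerts: int = 0  # raw alert count, before event attribution

    @property
    def n_events(self) -> int:
        return self.counts.TP + self.counts.FN

    @property
    def mean_early_alarm_time(self) -> float | None:
        if not self.lead_times_min:
            return None
        return float(Decimal(sum(self.lead_times_min) / len(self.lead_times_min))
                     .quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))

    def as_dict(self) -> dict:
        c = self.counts
        return {
            "level": self.level,
            "actual_hypoglycemia": self.n_events,
            "early_alarm": c.TP,
            "false_alarm": c.FP,
            "average_early_alarm_time_min": self.mean_early_alarm_time,
            "sensitivity_pct": sensitivity(c) if self.n_events else None,
            "false_positive_pct": false_positive_rate(c) if (c.TP + c.FP) else None,
            "missing_alarm_rate_pct": missing_alarm_rate(c) if self.n_events else None,
        }


@dataclass
class EvalReport:
    """Per-level confusion counts and indicators for one evaluation run."""

    levels: dict[str, LevelReport]

    def as_dict(self) -> dict:
        return {lvl: rep.as_dict() for lvl, rep in self.levels.items()}

    def to_json(self) -> str:
        return json.dumps(self.as_dict(), indent=2)

    def to_table(self) -> str:
        cols = ["Alarm level", "Actual hypoglycemia", "Early alarm", "False alarm",
                "Average early alarm time", "Sensitivity (%)", "False-positive (%)",
                "Missing alarm rate (%)"]
        rows = [cols]
        for lvl, rep in self.levels.items():
            d = rep.as_dict()
            def fmt(x):
                return "-" if x is None else str(x)
            rows.append([lvl, str(d["actual_hypoglycemia"]), str(d["early_alarm"]),
                         str(d["false_alarm"]),
                         fmt(d["average_early_alarm_time_min"]),
                         fmt(d["sensitivity_pct"]),
                         fmt(d["false_positive_pct"]),
                         fmt(d["missing_alarm_rate_pct"])])
        widths = [max(len(r[i]) for r in rows) for i in range(len(cols))]
        return "\n".join("  ".join(cell.ljust(w) for cell, w in zip(row, widths))
                         for row in rows)


def evaluate(events_by_level: dict[str, list[AlarmEvent]],
             alerts: list[Alert], horizon: float = 60.0) -> EvalReport:
    """Build the per-level report from ground-truth events and raw alerts."""
    levels = {}
    for lvl, events in events_by_level.items():
        lvl_alerts = [a for a in alerts if a.level == lvl]
        counts, leads = attribute_alerts(events, lvl_alerts, horizon)
        levels[lvl] = LevelReport(level=lvl, counts=counts, lead_times_min=leads,
                                  n_alerts=len(lvl_alerts))
    return EvalReport(levels=levels)
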