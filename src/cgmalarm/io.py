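"""CSV dialects used at the package boundary.

CGM traces: columns ``timestamp`` (ISO-8601) and ``glucose_mmol_l``, one
file per subject. Events, alerts and ground truth travel as flat CSV
tables; pattern libraries are JSON (see :mod:`cgmalarm.library`).
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .engine import Alert
from .errors import ConfigurationError
from .events import AlarmEvent
from .symbolize import GlucoseSeries

CGM_COLUMNS = ("timestamp", "glucose_mmol_l")


def read_cgm_csv(path, subject_id: str | None = None) -> GlucoseSeries:
    df = pd.read_csv(path)
    missing = [c for c in CGM_COLUMNS if c not in df.columns]
    if missing:
        raise ConfigurationError(f"{path}: missing CGM columns {missing}")
    times = pd.DatetimeIndex(pd.to_datetime(df["timestamp"]))
    return GlucoseSeries(times=times, values=df["glucose_mmol_l"].to_numpy(float),
                         subject_id=subject_id or Path(path).stem)


def write_cgm_csv(series: GlucoseSeries, path) -> None:
    df = pd.DataFrame({"timestamp": series.times.strftime("%Y-%m-%dT%H:%M:%S"),
                       "glucose_mmol_l": [f"{v:.4f}" for v in series.values]})
    df.to_csv(path, index=False)


def events_to_frame(events_by_subject: dict[str, dict[str, list[AlarmEvent]]]) -> pd.DataFrame:
    rows = []
    for sid, per_level in events_by_subject.items():
        for lvl, events in per_level.items():
            for ev in events:
                rows.append({"subject": sid, "level": lvl, "S_i": ev.S_i,
                             "L_w": ev.L_w, "T_h": ev.T_h})
    return pd.DataFrame(rows, columns=["subject", "level", "S_i", "L_w", "T_h"])


def alerts_to_frame(alerts_by_subject: dict[str, list[Alert]]) -> pd.DataFrame:
    rows = []
    for sid, alerts in alerts_by_subject.items():
        for a in alerts:
            rows.append({"subject": sid, "level": a.level, "color": a.color,
                         "T_end": a.T_end, "window": a.window,
                         "matched_pattern": a.matched_pattern.symbols,
                         "match_ratio": f"{a.match_ratio:.4f}"})
    return pd.DataFrame(rows, columns=["subject", "level", "color", "T_end",
                                       "window", "matched_pattern", "match_ratio"])
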