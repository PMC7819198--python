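"""Symbolize a synthetic CGM day and detect alarm events at the three
thresholds.

A glucose trace is discretized onto a 15-letter alphabet (narrow 0.5 mmol/L
bins near the hypoglycemia thresholds, wider bins above); an alarm event is
a maximal run of samples at or below a level's threshold (3.0 / 3.9 / 4.4
mmol/L). The printed run lengths are in 5-min samples.
"""

from cgmalarm import LEVEL_THRESHOLDS, detect_alarm_events, symbolize_series
from cgmalarm.synth import HypoEvent, SimConfig, simulate

cfg = SimConfig(days=1, seed=42, hypo_events=(HypoEvent(0, 720, 3.4),))
series = simulate(cfg)
seq = symbolize_series(series)

print(f"trace: {len(series)} samples, glucose "
      f"{series.values.min():.1f}-{series.values.max():.1f} mmol/L")
print(f"symbols around the midday episode: {seq.symbols[132:156]}")
for level, threshold in LEVEL_THRESHOLDS.items():
    events = detect_alarm_events(seq, threshold)
    for ev in events:
        print(f"level {level:>3} (<= {threshold} mmol/L): onset {ev.T_h} "
              f"(sample {ev.S_i}), below threshold for {ev.L_w} samples")
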