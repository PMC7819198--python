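"""Seeded synthetic CGM generator.

Emulates multi-day traces at 5-min sampling (288 samples/day): a
mean-reverting noisy baseline, smooth meal excursions, and scheduled
hypoglycemia episodes. Each episode descends piecewise-linearly to its
nadir and recovers; an optional fixed symbol motif is forced into the first
part of the descent (sample values pinned to the motif bins' midpoints), so
every episode is preceded by a deterministic pre-event signature. Scheduled
excursion spans are noise-free — the planted symbolic structure is exact by
construction — while free-living segments carry AR(1) sensor noise; this is
what makes planted-pattern recovery tests exact rather than approximate.

The generator is a test harness for the mining pipeline, not a
physiological glucose-insulin model.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .events import LEVEL_THRESHOLDS, AlarmEvent, detect_alarm_events
from .symbolize import (DEFAULT_SYMBOL_MAP, GlucoseSeries, SymbolMap,
                        symbolize_series)

SAMPLES_PER_DAY = 288

#: Default pre-event signature: a monotone staircase descending through the
#: bins just above the warning threshold. Six symbols = 30 min of descent.
DEFAULT_SIGNATURE = "gfedcb"


@dataclass(frozen=True)
class HypoEvent:
    """One scheduled episode: onset at ``day``/``time_min``, nadir ``depth``."""

    day: int
    time_min: float
    depth_mmol_l: float
    #: 50 min = 6 signature samples + a 4-sample approach just above threshold
    descent_minutes: float = 50.0


@dataclass
class SimConfig:
    days: int = 3
    sampling_interval: float = 5.0  # minutes
    baseline_mmol_l: float = 7.0
    reversion_rate: float = 0.3  # AR(1) noise: correlation = 1 - rate
    noise_sd: float = 0.25  # mmol/L, stationary sd of sensor noise
    #: slow glycemic variability around the baseline (dawn effect, activity,
    #: unmodelled snacks): mean-reverting with a ~2 h correlation time
    variability_sd: float = 0.8
    variability_tau_min: float = 120.0
    meal_times_min: tuple[float, ...] = (450.0, 720.0, 1110.0)  # 07:30 12:00 18:30
    meal_amplitudes: tuple[float, ...] = (2.5, 3.0, 2.0)  # mmol/L peak rise
    meal_duration_min: float = 120.0
    hypo_events: tuple[HypoEvent, ...] = ()
    nadir_minutes: float = 25.0
    recovery_minutes: float = 60.0
    signature: str | None = DEFAULT_SIGNATURE
    seed: int = 0
    start: str = "2024-03-01"
    subject_id: str = "subject"


def _meal_bump(minute_of_day: np.ndarray, center: float, amplitude: float,
               duration: float, undershoot_frac: float = 0.3) -> np.ndarray:
    """Post-meal excursion: raised-cosine rise and fall, then a shallow
    reactive undershoot below baseline (the insulin-response dip) recovering
    over the following hour — so ordinary descents through the bins below
    baseline are a routine, non-alarm feature of the trace."""
    x = (minute_of_day - center) / duration
    bump = np.where(np.abs(x) <= 0.5, 0.5 * amplitude * (1 + np.cos(2 * np.pi * x)), 0.0)
    dip = undershoot_frac * amplitude
    in_dip = (x > 0.5) & (x <= 1.1)
    bump = bump - np.where(in_dip, dip * np.sin(np.pi * (x - 0.5) / 0.6), 0.0)
    return bump


def simulate(cfg: SimConfig, symbol_map: SymbolMap = DEFAULT_SYMBOL_MAP) -> GlucoseSeries:
    """Generate one subject's trace; identical config and seed give an
    identical series."""
    step = cfg.sampling_interval
    n = int(cfg.days * SAMPLES_PER_DAY)
    minute = np.arange(n) * step
    minute_of_day = minute % (24 * 60.0)

    target = np.full(n, cfg.baseline_mmol_l, dtype=float)
    for center, amp in zip(cfg.meal_times_min, cfg.meal_amplitudes):
        target += _meal_bump(minute_of_day, center, amp, cfg.meal_duration_min)

    # scheduled episodes: [descent | nadir | recovery], deterministic values
    forced = np.zeros(n, dtype=bool)
    spans: list[tuple[int, int]] = []
    for ev in sorted(cfg.hypo_events, key=lambda e: (e.day, e.time_min)):
        onset = int(round((ev.day * 24 * 60 + ev.time_min) / step))
        n_desc = int(round(ev.descent_minutes / step))
        n_nadir = int(round(cfg.nadir_minutes / step))
        n_rec = int(round(cfg.recovery_minutes / step))
        lo, hi = onset - n_desc, onset + n_nadir + n_rec
        if lo < 0 or hi > n:
            raise ConfigurationError(f"event at day {ev.day}, {ev.time_min} min does not fit the series")
        if spans and lo < spans[-1][1]:
            raise ConfigurationError("scheduled hypoglycemia events overlap")
        spans.append((lo, hi))

        sig = cfg.signature or ""
        if len(sig) > n_desc:
            raise ConfigurationError("signature longer than the descent")
        desc = np.empty(n_desc)
        if sig:
            desc[:len(sig)] = [symbol_map.midpoint(s) for s in sig]
            ramp_from = min(symbol_map.midpoint(sig[-1]), 4.35)
        else:
            ramp_from = target[lo]
        # approach segment: hold just above the deepest threshold the nadir
        # will cross, so onset lands exactly at the scheduled sample
        ramp_to = max(3.95, ev.depth_mmol_l + 0.1)
        ramp_to = min(ramp_to, 4.35)
        n_ramp = n_desc - len(sig)
        if n_ramp > 0:
            desc[len(sig):] = np.linspace(ramp_from, ramp_to, n_ramp + 1)[1:]
        target[lo:onset] = desc
        target[onset:onset + n_nadir] = ev.depth_mmol_l
        rec_to = cfg.baseline_mmol_l
        target[onset + n_nadir:hi] = np.linspace(ev.depth_mmol_l, rec_to, n_rec + 1)[1:]
        forced[lo:hi] = True

    rng = np.random.default_rng(cfg.seed)

    def ar1(sd: float, phi: float) -> np.ndarray:
        x = np.zeros(n)
        innov = rng.standard_normal(n) * sd * np.sqrt(max(1.0 - phi ** 2, 1e-12))
        for t in range(1, n):
            x[t] = phi * x[t - 1] + innov[t]
        return x

    noise = ar1(cfg.noise_sd, 1.0 - cfg.reversion_rate)
    slow = ar1(cfg.variability_sd, float(np.exp(-step / max(cfg.variability_tau_min, 1e-9))))
    values = np.where(forced, target, target + slow + noise)
    values = np.clip(values, symbol_map.lower_limit + 0.01, symbol_map.upper_limit)

    times = pd.date_range(cfg.start, periods=n, freq=f"{int(step)}min")
    return GlucoseSeries(times=times, values=values, subject_id=cfg.subject_id)


def ground_truth_events(series: GlucoseSeries,
                        symbol_map: SymbolMap = DEFAULT_SYMBOL_MAP) -> dict[str, list[AlarmEvent]]:
    """Exact per-level events of a generated trace, by detection."""
    seq = symbolize_series(series, symbol_map)
    return {lvl: detect_alarm_events(seq, thr, symbol_map)
            for lvl, thr in LEVEL_THRESHOLDS.items()}


#: Nadir depths and cohort mix: severe (below 3.0), moderate (below 3.9) and
#: shallow (below 4.4 only) episodes in roughly the proportions a multi-level
#: clinical event census shows (severe ~23%, moderate-only ~41%, rest shallow).
DEPTH_CHOICES = (2.7, 3.4, 4.15)
DEPTH_PROBS = (0.23, 0.41, 0.36)


def make_benchmark(n_subjects: int, events_per_subject: int, seed: int,
                   days: int = 3, signature: str | None = DEFAULT_SIGNATURE,
                   depth_choices: tuple[float, ...] = DEPTH_CHOICES,
                   depth_probs: tuple[float, ...] = DEPTH_PROBS,
                   symbol_map: SymbolMap = DEFAULT_SYMBOL_MAP,
                   ) -> tuple[list[GlucoseSeries], dict[str, dict[str, list[AlarmEvent]]]]:
    """A seeded cohort with per-subject randomized schedules and exact truth.

    Returns the traces and, per subject id, the per-level ground-truth event
    lists. Baselines, meal amplitudes/times and episode times and depths are
    drawn per subject from seeded distributions.
    """
    if n_subjects < 1:
        raise ConfigurationError("need at least one subject")
    rng = np.random.default_rng(seed)
    # two quiet slots per day (small hours and mid-afternoon), away from meals
    slots = [(d, t) for d in range(days) for t in (180.0, 960.0)]
    if events_per_subject > len(slots):
        raise ConfigurationError("too many events for the number of days")
    series_list: list[GlucoseSeries] = []
    truth: dict[str, dict[str, list[AlarmEvent]]] = {}
    for k in range(n_subjects):
        sid = f"S{k:03d}"
        baseline = rng.uniform(6.5, 10.0)
        meal_amps = tuple(rng.uniform(1.2, 3.5, size=3))
        meal_times = tuple(np.array((450.0, 720.0, 1110.0)) + rng.uniform(-30, 30, size=3))
        idx = rng.permutation(len(slots))[:events_per_subject]
        events = []
        for j, i in enumerate(sorted(idx)):
            day, t0 = slots[i]
            if j == 0 and len(depth_choices) > 1:
                # subjects cycle through the severity classes for their first
                # episode, so every class is represented in any cohort
                depth = float(depth_choices[k % len(depth_choices)])
            else:
                depth = float(rng.choice(depth_choices, p=depth_probs))
            events.append(HypoEvent(day=day, time_min=t0 + float(rng.uniform(-40, 40)),
                                    depth_mmol_l=depth))
        cfg = SimConfig(days=days, baseline_mmol_l=baseline,
                        meal_amplitudes=meal_amps, meal_times_min=meal_times,
                        hypo_events=tuple(events), signature=signature,
                        seed=int(rng.integers(0, 2 ** 31 - 1)), subject_id=sid)
        series = simulate(cfg, symbol_map)
        series_list.append(series)
        truth[sid] = ground_truth_events(series, symbol_map)
    return series_list, truth
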