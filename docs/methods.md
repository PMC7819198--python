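# Methods

## Model and assumptions

The system treats hypoglycemia anticipation as a *sequential state
recognition* problem rather than a forecasting problem. The working
assumption is that episodes are preceded by recurring symbolic descent
shapes in the hour before onset, and that these shapes can be separated
from everyday glucose motion by contrasting two corpora: windows that
immediately precede below-threshold runs (early-alarm sequences) and
windows cut from the stretches between them (non-alarm sequences). Both
corpora share one window length so the mined patterns are comparable.

Symbolization uses left-open/right-closed bins read directly off the
clinical mapping table; a value on a boundary belongs to the lower bin
(3.9 mmol/L → 'z'). Values at or below 2.2 clamp to 'y' and above 22.2 to
'm', with a logged warning — CGM sensors saturate near these limits, and
the mapping does not cover the outside ranges. One symbol map serves all
three alarm levels because every threshold (3.0, 3.9, 4.4 mmol/L) is a bin
boundary; no per-level re-symbolization is needed, and event detection on
symbols is provably identical to thresholding the raw values.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `L_e` | 12 samples (60 min) | early-alarm window length; also the sliding-window length |
| `L_min` | 6 samples | shortest retained pattern, `L_e`/2 |
| `minsup_alarm` | 0.2 | minimum support in the early-alarm corpus |
| `minsup_non_alarm` | 0.15 | minimum support in the non-alarm corpus |
| thresholds | 3.0 / 3.9 / 4.4 mmol/L | levels I (red) / II (orange) / III (yellow) |
| `match_ratio_min` | 1.0 | LCS(window, P)/|P| needed for a match; 1.0 = full containment |
| `refractory` | `L_e` samples | per-level silence after an alert |
| `horizon` | 60 min | attribution window before onset for scoring |

The support pair (0.2, 0.15) follows the published system settings, with
the larger value on the (smaller, noisier) alarm corpus. `L_min = L_e/2`
is the published compromise: shorter retained patterns inflate false
positives, longer ones inflate missed alarms.

## Design choices where the design was open

**Redundancy removal keeps minimal patterns.** Under the containment match
rule, a pattern fires on any window containing it as a subsequence, so if
`P ⊑ Q` every window matched by `Q` is already matched by `P`: the
supersequence `Q` is the redundant one. Refinement therefore reduces the
alarm set to the minimal antichain (duplicates collapsed, proper
supersequences of retained patterns dropped). This preserves the library's
entire match set, and it is the reading under which the shortest-length
bound `L_min` — not absorption into longer patterns — is the lever that
trades missed alarms against false positives, which matches how the
parameter is described as having been tuned. The cost is promiscuity: the
retained patterns are the shortest, hence the most FP-prone; `L_min` and
the match ratio are the controls.

**Non-alarm lookback.** The stretch eligible for non-alarm windows runs
from one event's end to the next event's early-window start; series
boundaries count as event boundaries, so leading and trailing stretches
contribute. Windows are cut left-aligned and a short final fragment is
dropped. The alternative — a fixed lookback constant — was rejected because
no value for it is published.

**Events too close to history edges.** An event whose early window would
run off the series start, or overlap the previous event's below-threshold
run, is skipped and counted (such alarms cannot be anticipated from a
full-length history). Events are maximal below-threshold runs; `L_w` is
simply the run length.

**Matching and precedence.** "Match" is full containment by default (the
strictest LCS reading; a configurable ratio is exposed). Among matching
patterns the longest wins, ties broken by support then lexicographic
order. Levels are tested I > II > III and only the highest matching level
fires at a position; a per-level refractory span of one window keeps one
episode from emitting a burst of alerts.

**Scoring with nested thresholds.** The thresholds nest, so a red alert
(glucose heading below 3.0) logically asserts the orange and yellow
conditions too. Evaluation therefore credits alerts of level L *or higher*
to level-L events; without this, the precedence rule would structurally
zero the lower levels' sensitivity whenever the libraries overlap. Each
alert is attributed to the first event whose 60-min pre-onset horizon
contains its endpoint, or counted as a false positive — never both, never
dropped. A hit event's lead time comes from its earliest attributed alert.
Percentages are printed to two decimals, round-half-up; sensitivity and
missing-alarm rate are exact complements (independent rounding can split a
half-cent tie, never more). True negatives are tallied but enter none of
the headline indicators.

## Numerical and degenerate-input conventions

Mining output is canonicalized lexicographically, support counts once per
sequence regardless of embedding multiplicity, and projection advances
past the leftmost embedding — sufficient for containment-based support.
LCS backtracking memoizes on the table cell and explores both directions
on ties, so all optimal strings are recovered; a guard (default 10,000
strings) raises an explicit overflow on pathological inputs. An empty
series symbolizes to an empty sequence; an empty corpus is an error; a
level with no events raises an explicit empty-library error naming the
level. Library JSON has fixed key order and no wall-clock field by
default, so identical input and configuration produce byte-identical
files. Timestamps are ISO-8601; indices are 0-based half-open. Sensor gaps
longer than twice the sampling interval split a series into independently
processed segments (optional single-sample interpolation).

## The synthetic cohort: what it does and does not show

The generator emulates the study's data geometry — multi-day traces at
5-min sampling (288 samples/day), glucose in (2.2, 22.2] mmol/L, a
T2D-like cohort with per-subject baselines (6.5–10 mmol/L), three daily
meals with raised-cosine excursions and a reactive post-meal undershoot,
slow mean-reverting glycemic variability (sd 0.8 mmol/L, ~2 h correlation)
plus AR(1) sensor noise (sd 0.25 mmol/L), and scheduled hypoglycemia
episodes in three severity classes (nadirs 2.7 / 3.4 / 4.15 mmol/L, mixed
roughly as a multi-level clinical event census). Each episode descends
piecewise-linearly: a fixed six-symbol signature (`gfedcb` by default)
followed by a short approach just above threshold, then the nadir and a
linear recovery. Scheduled spans are noise-free so the planted symbolic
structure is exact — this is what makes planted-pattern recovery tests
exact rather than statistical. Subjects cycle their first episode through
the severity classes so every level is represented in any cohort.

Because every episode carries the *same* signature regardless of depth,
severity is intentionally not discriminable before onset in this
benchmark: the level-I library fires before moderate and shallow episodes
too, so level-I false-positive rates are high by construction. Together
with the minimal-antichain retention of length-6 patterns and a non-alarm
corpus far less morphologically varied than clinical data, this makes the
benchmark's false-positive percentages much higher than clinically
reported figures. What the passing pipeline demonstrates is recall and
mechanics — signature recovery through mining and refinement, early alerts
with 20–35 min leads, exact metric arithmetic, determinism — not the
clinical false-alarm operating point.

Problem sizes follow the same scaled-down logic: the standard study is 20
training and 10 held-out subjects with 2 episodes each over 3 days, which
exercises every code path with corpora of tens of alarm windows and over a
thousand non-alarm windows.

## Known limitations

- The pattern libraries are static once built; no online updating.
- Only hypoglycemia is modeled; hyperglycemia events are out of scope.
- The generator is a test harness, not a physiological glucose–insulin
  model; sensor error is AR(1), not spectrally modeled.
- The mg/dL unit system is supported only through an I/O converter; bins
  are defined in mmol/L.
- With `match_ratio_min < 1.0`, matching falls back to the full LCS
  dynamic program per pattern and is correspondingly slower.
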