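# chronoperf

Chronobiology of in-the-wild cognitive performance, from consumer-tracker
style data. `chronoperf` is for researchers who collect longitudinal
smartphone task batteries (a Psychomotor Vigilance Test, PVT, for vigilant
attention; an Addition Test, ADD, for cognitive throughput) alongside
wearable sleep, heart-rate and activity records, and who want to quantify
which sleep and physiological markers move which dimension of performance —
within persons, not across them.

## What it computes

**Performance scores.** Each task battery yields the session median reaction
time MRT (ms, false starts ignored) and the number of additions attempted
NAA. Scores are expressed relative to the participant's own baseline:

```
RRT = (1 - MRT / mean_MRT) x 100        (higher = more alert)
RAA = (NAA / mean_NAA - 1) x 100        (higher = more throughput)
```

after dropping each participant's first battery, PVT sessions with
MRT > 800 ms, sessions beyond 3 SD of the participant mean, and participants
with fewer than 42 batteries.

**Chronotype and sleep pressure.** Chronotype is the corrected mid-sleep on
free days, `MSF = MSF_uc - 0.5 (SD_f - SN)` with sleep need
`SN = (N_w SD_w + N_f SD_f) / (N_w + N_f)`; internal time is
`InT = ExT - MSF` (mod 24 h); nightly sleep debt is `1 - duration/SN` and
sleep shift is the signed misalignment of a night's mid-sleep from the MSF
instant. Weekly aggregates impute missing nights with the running mean of
all prior nights.

**Inference.** Two statsmodels-style engines:

* `RepeatedMeasuresCorrelation(x, y, subjects).fit()` — the ANCOVA
  common-slope repeated-measures correlation r_rm (subject-specific
  intercepts, one slope; df = N - k - 1), with F-test p-value and Fisher-z
  or bootstrap CIs.
* `Cosinor(t_hours, y, period=24).fit()` — fixed-period cosinor
  (mesor, amplitude, acrophase) with a delta-method acrophase CI and a
  2-df zero-amplitude test.

**Synthetic cohorts.** `simulate_cohort(SimConfig(), seed)` generates
complete datasets — schedules, staged sleep, minute heart-rate/activity
streams, task batteries — for regular workers, rotating shift workers and
graduate students, with task outcomes driven by a two-process model
(circadian component peaking 13.5 h after the chronotype; homeostatic
pressure with 18.2 h / 4.2 h buildup/decay constants) plus configurable
sleep/arousal couplings, and returns the latent ground truth for recovery
tests.

## Worked example

```python
from chronoperf import (SimConfig, simulate_cohort, score_sessions,
                        daily_relative_scores, chronotype_msf, night_metrics,
                        RepeatedMeasuresCorrelation, Cosinor)
from chronoperf.scoring import scores_frame
from chronoperf.pipeline import build_daily_frame
from chronoperf.records import clock_hours, hours_to_hhmm

cohort = simulate_cohort(SimConfig(include_streams=False), seed=1)
scores = score_sessions(cohort.tasks)
nights = {}
for pid, sch in cohort.schedules.items():
    p_sleep = [s for s in cohort.sleep if s.participant_id == pid]
    prof = chronotype_msf(p_sleep, sch)
    nights[pid] = night_metrics(p_sleep, prof)

frame = build_daily_frame(daily_relative_scores(scores), nights) \
    .dropna(subset=["prev_duration", "relative_daily_rrt"])
print(RepeatedMeasuresCorrelation(frame["prev_duration"],
                                  frame["relative_daily_rrt"],
                                  frame["participant_id"]).fit().summary())
```

prints

```
Repeated-measures correlation
=============================================
r_rm           0.5359
df            603
p-value       2.8e-46
95% CI        (0.4766, 0.5904) [fisher]
common slope   0.044178
N obs         620
N subjects    16
```

i.e. within persons, longer previous-night sleep predicts higher relative
daily alertness (the generator's default duration coupling is positive, and
the common slope says each extra minute of sleep buys ~0.044 percentage
points of relative alertness). Fitting the circadian rhythm of the
session-level scores,

```python
df = scores_frame(scores).dropna(subset=["rrt"])
df["time_of_day"] = df["timestamp"].map(clock_hours)
print(Cosinor(df["time_of_day"], df["rrt"]).fit().summary())
```

```
Cosinor fit (period 24 h)
=============================================
mesor         -0.8923
amplitude      2.6381
acrophase      15.6251 h = 15:37
acrophase CI  15:37 (14:47 to 16:27)
amplitude p   5.53e-11
residual sd    8.1264
N obs         1398
```

— alertness varies sinusoidally over the day with a significant 2.6%
amplitude peaking mid-afternoon (the cohort's mean chronotype plus the
configured 13.5 h circadian offset, minus the homeostatic decline that
pulls the combined peak earlier).

A `chronoperf` CLI wraps the same functionality
(`simulate`, `score`, `chrono`, `features`, `correlate`, `cosinor`, `run`);
`chronoperf run --config analysis.yaml` produces the full table set
(sleep-vs-daily-score correlations, momentary physiology correlations,
cosinor acrophases, descriptives) plus a manifest of row counts at every
filter stage.

## Layout

```
src/chronoperf/
  records.py    domain types and validation (tasks, sleep, streams, schedules)
  io.py         JSONL/CSV readers and writers
  scoring.py    MRT/RRT, NAA/RAA, retention filters, daily scores
  chrono.py     MSF, internal time, sleep need/debt/shift, weekly aggregates
  features.py   task-time heart-rate and activity window statistics
  stats/        repeated-measures correlation and cosinor engines
  simulate.py   two-process synthetic cohort generator
  pipeline.py   end-to-end orchestration and output tables
  cli.py        click CLI
```

See `docs/methods.md` for the model details, parameter choices and
limitations.
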