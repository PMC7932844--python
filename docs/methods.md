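# Methods

This note documents the models, conventions and numerical choices behind
`chronoperf`, and what the synthetic-data validation does and does not show.

## Performance scoring

A task battery contributes a session median reaction time MRT (over
non-false-start PVT stimuli; the median of an even-count list is the
midpoint average) and an addition count NAA. Relative scores are percentage
deviations from the participant's own baseline,

    RRT = (1 - MRT / mean_MRT) * 100,    RAA = (NAA / mean_NAA - 1) * 100,

with the baselines taken over the participant's *retained* sessions, which
makes each participant's mean RRT and RAA identically zero — an identity
the tests assert to 1e-9. Retention filters run in a fixed order:

1. the participant's chronologically first battery is dropped
   (app-unfamiliarity);
2. PVT sessions with MRT missing or strictly above 800 ms are dropped
   (exactly 800 ms is retained);
3. sessions strictly more than 3 SD from the participant mean are dropped,
   with mean and SD computed over the survivors of steps 1–2 and the SD
   the population SD (ddof=0; configurable). Exactly 3 SD is retained, and
   a zero-SD participant loses nothing.

The ADD score applies only steps 1 and 3 (no absolute threshold exists for
addition counts). The order matters only for the 3-SD step: computing the
SD before removing >800 ms sessions would let extreme sessions inflate the
SD; we filter them first. Participants with fewer than 42 completed
batteries (counted before any session-level filter) are excluded entirely.

Daily scores take the per-day median of retained MRT/NAA (calendar day =
local midnight-to-midnight) and apply the same relative forms with the
across-days mean of daily medians as baseline.

## Chronotype and sleep metrics

* **Night.** A sleep session belongs to the calendar date it ends on (its
  wake date); when several sessions share a wake date only the longest is
  the "night" (naps are excluded from chronotype, debt and linkage).
* **MSF.** `MSF = MSF_uc - 0.5 (SD_f - SN)` with
  `SN = (N_w SD_w + N_f SD_f) / (N_w + N_f)`; a night is a free-day night
  when its wake date is labelled free. `MSF_uc` is the *circular* mean of
  free-night mid-sleep clock times by default; a naive linear mean anchored
  at noon is available for comparison (`mean_method="linear"`). Since the
  weights in SN are day counts, SN equals the plain mean nightly duration
  over the observation period; summing per week would change nothing.
* **Sleep debt.** `1 - duration/SN` per night; its mean over the nights
  entering SN is exactly zero by construction (asserted to 1e-12).
* **Sleep shift.** Actual mid-sleep *instant* minus the MSF instant
  expected for the night's wake date (MSF clock times before noon anchor to
  the wake date, later ones to the previous date). This is a datetime
  difference, not a minimal circular one: a rotating-shift worker who
  sleeps through the afternoon can legitimately shift by more than 12 h,
  which a circular difference would fold back.
* **Weekly aggregates.** Means over the 7 calendar nights preceding a date;
  a missing night is imputed per metric with the running mean of all
  recorded nights strictly before it (falling back to the overall recorded
  mean for gaps preceding every record). Aggregates are missing when no
  night precedes the date at all.
* **Linkage.** A task links to the most recent night ending before it and
  within 36 h (an invented, configurable staleness bound); time since wake
  is the task timestamp minus that night's end.

All timestamps are naive local time at minute resolution; daylight-saving
transitions are not modelled.

## Momentary features

Window statistics use the half-open minute interval (t - w, t] including
the task minute, for w = 10 and 60 by default; variance is the population
variance (ddof=0, configurable). Statistics are reported only when at least
half the window's minutes carry data. "Current" heart rate is the stream
value at the task minute, else the nearest minute within 5 minutes (an
invented plumbing tolerance, configurable); resting heart rate is the day's
stored value.

## Repeated-measures correlation

r_rm is the ANCOVA common-slope correlation: fit
`y_ij = alpha_i + beta x_ij + eps_ij` by least squares and report
`sign(beta) * sqrt(SS_slope / (SS_slope + SS_error))` with
df = N - k - 1, a p-value from F(1, df), and a 95% CI from the Fisher
z-transform with SE `1/sqrt(df - 1)` (a subject-resampling bootstrap CI is
available as `ci_method="bootstrap"`). Missing pairs are deleted listwise.
Subjects with constant within-subject x carry no slope information but
still enter the error term and df, as in the ANCOVA; the model errors only
when *no* subject varies. No multiple-testing correction is applied across
the output tables — raw p-values are reported; a Benjamini–Hochberg
post-processor would be a one-line addition downstream but is deliberately
off, so the tables remain comparable row by row. All tests are two-sided.

A second implementation (`rmcorr_lstsq`) recomputes everything by explicit
design-matrix least squares with one indicator column per subject; it
exists purely as an independent oracle, and the suite checks the two agree
to 1e-10 on randomized inputs and match `pingouin.rm_corr`.

## Cosinor

The fixed-period cosinor `y = M + A cos(omega (t - phi))` is linearised to
`y = M + b1 cos(omega t) + b2 sin(omega t)` and solved by OLS;
`A = hypot(b1, b2)`, `phi = atan2(b2, b1)/omega` wrapped to [0, period).
The acrophase CI uses the delta method on (b1, b2) (gradient
`(-b2, b1)/A^2`); the zero-amplitude test is the 2-df F test against the
intercept-only model. Constant series return amplitude 0 with p = 1 and an
undefined acrophase CI. Acrophases render as hh:mm, flooring to the minute.
Degenerate designs (fewer than 3 distinct time points, or a rank-deficient
basis) raise rather than returning meaningless coefficients.

## Synthetic cohort generator

The generator emulates a ~6-week, three-group longitudinal study (6 regular
workers, 5 rotating shift workers, 5 graduate students; 42 nights each by
default) and is the package's validation substrate, since no comparable
public dataset exists.

**Sleep.** Nightly durations are truncated normals: 420 ± 80 min on work
nights, 466 ± 80 min on free nights (clipped to [181, 760]), so the pooled
mean at a ~5:2 work:free mix is ~433 min. Free-night mid-sleep centres on
the participant's true chronotype (drawn per group: regular 03:36 ± 0.7 h,
shift 04:24 ± 1.2 h, student 05:00 ± 1.0 h); work-night timing follows the
group schedule, with shift workers rotating through day/evening/night
blocks (3–6 days) separated by 1–2 free days — night blocks produce
daytime sleep and sleep shifts beyond ±12 h. Stage fractions of total
session duration are drawn around 18.2% REM, 52.9% light, 15.9% deep (SDs
5.3/7.0/5.1 percentage points), renormalised when they would exceed 98% of
the session; the remainder is awake time, and only sessions longer than 3 h
carry stages. The stage-percentage denominator is the session's total
duration, the same convention the night-metrics layer reports.

**Two-process performance model.** Each task battery's latent alertness and
throughput (in percent, the RRT/RAA scale) sum a circadian cosine peaking
13.5 h after the individual's mid-sleep point (amplitude 3% each by
default), a homeostatic pressure term for alertness (pressure rises toward
1 as a saturating exponential with an 18.2 h time constant while awake and
decays with a 4.2 h constant during sleep — classical two-process values;
"sigmoidal" buildup is implemented as this saturating exponential since no
functional constants are standard), linear couplings from the previous
night (duration, REM and light minutes to alertness; sleep shift and sleep
end to throughput, negatively) and from momentary physiology (60-min heart
rate mean and 10-min step mean, positively to both), plus Gaussian noise
(SD 7% alertness, 11% throughput). Alertness maps to MRT through a
decreasing link `MRT = m0 (1 - alert/100)` around a per-participant
baseline m0 (355 ms × lognormal spread); throughput maps to
`NAA = round(n0 (1 + thr/100))`. Per-stimulus PVT responses scatter
lognormally around the session MRT with occasional flagged false starts.
Coupling magnitudes are calibration choices in natural units (e.g. 0.02%
alertness per minute of sleep duration); the arousal couplings are larger
per unit (0.3–0.45) because they act on smoothed window means whose
within-subject spread is only a few units. They are sized so that
single-coupling recovery at study scale is comfortably powered, and the
no-coupling configuration is exactly null.

**Streams.** Minute heart rate = daily resting rate (per-participant base
66 ± 8 bpm) + a waking offset (+10) or sleep dip (−6) + a chronotype-
aligned diurnal sinusoid + activity bumps + noise; steps come from a
minute-level bout process (4% of waking minutes, ~70 steps) and are zero
during sleep; calories and distance derive from steps. Missing nights and
stream gaps are opt-in rates, default zero.

**Determinism.** All randomness flows from `SeedSequence([seed, 19])` with
one spawned child per participant, so output files are byte-identical for a
given (config, seed).

**What passing tests show — and don't.** The generator reproduces the
statistical *structure* the analysis assumes (within-person couplings,
circadian phase, stage moments), not physiological realism: there is no
light exposure, melatonin, sleep inertia, practice effect, or heart-rate
variability, sleep parameters are drawn independently across nights, and
noise is Gaussian. Recovery of a coupling here demonstrates the pipeline's
correctness, not that a real cohort of this size would show the effect.

## Validation problem sizes

The test suite pins its statistical checks at these scales, chosen to make
sampling error small relative to the asserted tolerances: rmcorr-vs-oracle
agreement on 100 randomized datasets (1e-10); type-I error of the rmcorr F
test over 2000 null replicates at 16 subjects × 30 observations (within 3
SE of 0.05); cosinor acrophase CI coverage over 500 replicates at n = 500
(within 3 SE of 0.95); coupling sign recovery over 5 seeds per coupling at
the full study scale of 16 participants × 42 days (≥80% of seeds
significant with the configured sign); and a null-safety battery of ~400
correlation tests over 12 seeds of a reduced 8-participant cohort (the F
test's null behaviour does not depend on cohort size).

## Known limitations

* Tracker "sleep efficiency" is carried as an opaque 0–100 score; its
  definition is vendor-specific and nothing downstream interprets it.
* The MSF averaging convention (circular vs linear) is not standardised in
  the field; both are provided and differ only when free-night mid-sleeps
  straddle a large arc of the clock.
* Weekly aggregates depend on the imputation rule for missing nights; the
  running-mean rule is mean-preserving but damps week-to-week variance.
* The pipeline reports raw p-values across many correlations; interpreting
  the full tables requires the reader's own multiplicity judgement.
* Subjective sleepiness (KSS) and caffeine flags are parsed and carried but
  never analysed.
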