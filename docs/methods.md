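# Methods

This note documents the models behind `audiosim`, the defaults and why they
were chosen, the numerical conventions, and what the simulations can and
cannot show.

## Listener model

Each synthetic participant carries hidden continuous thresholds
`T(ear, f)` in dB HL on the grid 250, 500, 1000, 2000, 4000, 6000, 8000 Hz,
and answers single presentations by a cumulative-normal psychometric
function

    P(heard at level L) = γ + (1 − γ − λ) Φ((L − (T + s)) / σ)

* `σ` (slope), default **3 dB** — a typical spread for pure-tone detection.
* `γ` (guess), `λ` (lapse), default **0.02** each, bounded at 0.1: false
  "I can hear" presses and missed audible tones.
* `s`, the session offset, is drawn once per exam and ear from
  `N(0, session_sd²)` with `session_sd = 2.5 dB`. It models headphone
  (re)positioning and is the reason test and retest differ for an unchanged
  listener.
* Deterministic listeners (`σ = 10⁻⁶`, `γ = λ = 0`) respond as step
  functions and are the exact oracle for staircase correctness.

Hearing-class archetypes (normal: per-cell `N(5, 5²)` truncated to
[−10, 20] dB HL, so never above 25; sensorineural: a low-frequency anchor by
severity plus 10 dB/octave above 1 kHz and interaural asymmetry;
conductive/mixed: flat 20–50 dB elevation) are deliberately coarse shapes
whose default 36/21/13-in-70 mixture reproduces the qualitative composition
of an otolaryngology-clinic cohort. Ages are `N(36, 11²)` clipped to
[18, 71] for patients and uniform 18–35 for the calibration crowd.

## Devices and the level chain

A device model has a per-frequency `true_offset ~ N(0, 5²)` dB — the extra
drive it needs to reach nominal output — and unit-to-unit spread
`instance_sd = 2 dB`; output limits are −10 to 80 dB mHL. A handset playing
raw level `x` produces `x − offset` on the hearing-level scale. The mobile
test converts a commanded level `c` (dB mHL) through

    acoustic at the ear = reference[f] + c − instance_offset[f]

so a perfectly recovered reference makes the device play at nominal level.
The clinical audiometer is modelled as perfectly calibrated (output range
−10 to 110 dB HL): pure-tone audiometry measures on the true dB HL scale.

## Measurement procedures

**Clinical bracketing staircase.** Familiarisation descent from 40 dB HL;
10 dB down after each heard tone, 5 dB up after each miss; threshold = the
lowest level heard on at least 2 ascending presentations (and at least half
of them, up to 4). For deterministic listeners this returns exactly the
smallest 5 dB grid level at or above `T`. For stochastic listeners (σ = 3)
the rule carries a small upward bias (≈ +3 dB at on-grid thresholds, SD
≈ 2.8 dB) inherent to ascending-response criteria; the self-adjustment
procedure shares a comparable bias, so the two largely cancel in paired
differences.

**Self-adjustment (mobile).** The user steps 5 dB down while hearing the
tone and 5 dB up while not, and confirms "barely audible" at a level that
was heard, whose next-lower level was missed, and missed again on one
re-check — two consistent reversals around the same boundary. Results are
snapped to the 5 dB grid; readings pinned at the device limits are flagged
`below_min`/`above_max` and excluded from statistics.

**Cross-hearing and masking.** Without masking the contralateral cochlea
receives the presented level minus a 40 dB interaural attenuation and may
detect the tone (detection is the OR of the two ears); above 40 dB a
contralateral masker removes that path entirely. No central masking or
overmasking is modelled.

**Bekesy calibration tracking.** The level falls 1 dB per tick while the
button is held (audible) and rises while released, for a fixed 250-tick
sweep; the estimate is the mean of the midpoints of the last 4 reversal
pairs after discarding the first 2 reversals, recorded at 1 dB resolution.
Two design points matter:

* The track runs its full duration and only the final reversal pairs enter
  the estimate. Stopping at the first few reversals would let attention
  lapses during the long initial descent (probability ≈ 1 − 0.98ⁿ over n
  ticks) abort tracks far above threshold and silently select against
  normal-hearing calibrators — which collapses the calibration.
* Validity is a *settle* criterion: the level range over the final 100 ticks
  must stay within 15 dB. Reversal-midpoint spread cannot detect an
  inattentive user, because adjacent reversals of even a random walk are
  locally close; a wandering track is what actually distinguishes one.

## Biological calibration

Per model: keep records of users aged 18–35 (closed interval), one record
per distinct device (most recent), require at least 15 distinct devices for
validity, then per frequency

    reference[f] = percentile_37(raw thresholds) − literature_median[f]

with the quantile computed by linear interpolation between order statistics.
Each simulated calibration record stores the two-ear mean of the Bekesy
estimates. The 37th percentile is median-consistent at the designed ~26 %
contamination (0.37 = 0.5 × 0.74); at zero contamination it sits ≈ 0.33 σ
(about 1.2 dB here) *below* the clean median — a small designed bias, not an
estimator defect — and it breaks down when contamination grows far beyond
the design point (at 60 % the estimate lands around the 92nd percentile of
the clean part; by 75 % it is many dB off).

Literature medians default to **0 dB at all frequencies** and are meant to
be user-supplied for real populations. Because the synthetic normal
population has a ~5 dB median, the default leaves a ~+5 dB constant
clinic-minus-mobile bias, deliberately emulating the reference bias that
biological calibration inherits from imperfect population norms. The
default crowd is 400 users at 26 % contamination, with 15 calibration
records per model — the minimum the validity rule accepts, which is the
regime the rule exists for.

## Study pipeline

One global seed expands into independent per-stage, per-unit streams
(devices, crowd, per-model calibration, cohort, per-subject exams), making
the full report deterministic and independent of subject ordering. The
default study: 28 device models (16 popular + 12 minor, one handset per
subject, 70 total), a 70-subject cohort, a counterbalanced 35/35 order
split (an analysis label only — no carry-over effects are simulated), one
clinical exam and a mobile test plus retest per subject with fresh session
offsets each. Statistics follow the crossover design's accounting: the unit
is the ear × frequency cell (980 before discards), cells are treated as
independent for all CIs — replicating the design's n-accounting despite
within-subject correlation, which is a faithful-replication choice, not a
statistical endorsement. Differences are oriented clinic − mobile (positive
means the mobile test reads lower/better) and test − retest. Normal (z)
quantiles are used for mean CIs, chi-square for SD CIs, the F-interval
(McGraw–Wong / Feldt) for ICC and alpha; for k = 2 the identity
α = 2·ICC/(1 + ICC) holds exactly and is verified against an independent
ANOVA implementation in the tests. Reported tables round to 0.1 dB and
whole percent only at the formatting boundary.

Screening applies the fixed rule — loss iff the threshold strictly exceeds
30 dB at any of 500/1000/2000 Hz, or strictly exceeds 25 dB at two or more
of them, or strictly exceeds 50 dB at 4 kHz — per ear (the unit of the
agreement analysis; a worse-ear subject-level variant is a config switch),
with Wald CIs clipped to [0, 100] % (Wilson available). The paired sample
size uses the two-sided normal approximation and reproduces 140 ears from
SD 8.42 dB, effect 2.0 dB, α 0.05, power 0.8.

## What the simulation does and does not show

The generator reproduces the *structure* of the validation study: hidden
thresholds, response noise, session effects, device heterogeneity, a
contaminated crowd, out-of-range censoring at device limits. Under these
defaults the simulated test–retest difference SD is ≈ 5.1 dB and the pooled
clinic-vs-mobile difference SD ≈ 5.8–6.6 dB across seeds. Real field data
show larger clinic-vs-mobile spread, dominated by *frequency-dependent*
errors in the literature medians used at calibration; the synthetic normal
archetype is frequency-independent by construction, so this component is
absent here. Passing simulation checks therefore demonstrates the internal
consistency of procedures, calibration and statistics — not that real
mobile audiometry achieves any particular accuracy. Also not modelled:
ambient noise during uncontrolled calibration, user mistakes (side
switching, accidental presses), bone conduction, pulsed/continuous tone
distinctions, retest bias from the app displaying previous results, and
longitudinal hearing change.

## Numerical conventions and degenerate inputs

* `snap_to_grid` rounds exact midpoints away from zero (symmetric for
  negative levels).
* Missing and out-of-range cells are treated identically by all statistics
  (excluded at pairing).
* Staircases cap at 200 presentations; a staircase pinned at an output
  limit twice consecutively is flagged out of range rather than erroring.
* ICC/alpha raise on zero total variance; sensitivity/specificity raise
  when truth contains no positives/negatives; the percentile of an empty
  list raises.
* Reproducibility: every stochastic function takes a numpy `Generator`;
  identical seeds give identical outputs, including byte-identical study
  reports.
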