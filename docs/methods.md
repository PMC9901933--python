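# Methods and design notes

This note documents the models, parameter choices, numerical conventions,
and known limitations of `pupephys`. It is the package's own account of its
science; nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Data model

All components of a session share one time axis in seconds. Intervals are
half-open `[start, end)` everywhere: an event exactly on a boundary belongs
to the later interval, so any set of epochs that tiles the session
partitions it unambiguously, and restricted durations sum exactly to the
session duration. The recorded extent of a session is defined by its
sampled signals and epoch annotations; spikes or event onsets outside that
extent are validation errors, not data.

Quiescence epochs are loaded and carried but excluded from all state
contrasts by default — only AS and wake enter the rate comparisons. LFP
amplitudes are treated as arbitrary, unit-agnostic values throughout; every
threshold in the pipeline is defined relative to statistics of the data
itself, never in absolute units.

## Spindle-burst detection

The LFP (nominally 1 kHz after preprocessing) is band-passed at 10–20 Hz
with a linear-phase FIR filter designed by the Kaiser-window method to a
60 dB stopband and 1 Hz transition band (≈ 3 600 taps at 1 kHz; designed
with 5 dB of margin). The symmetric filter is applied centered via FFT
convolution, so the output is zero-phase and envelope timing is unbiased.
The envelope is the magnitude of the analytic signal (Hilbert transform,
FFT length padded to a fast size).

The detection threshold is `median + k·SD` of the envelope over a baseline
segment, `k = 2` by default. The baseline defaults to the whole analyzed
record; for pre/post-injection experiments it must be the pre-injection
period, passed as an epoch set (the anesthetized record violates the
stationarity the whole-record default assumes). Bursts are maximal runs
*strictly above* threshold lasting ≥ 100 ms. Strictness matters for the
degenerate case: a constant envelope has SD 0, the threshold collapses onto
the median, and a non-strict rule would declare the entire record one
burst.

**Onset refinement.** A hard threshold clips the rising flank of a
gradually waxing oscillation: for a Hann-enveloped burst at 5× the
background SD, the first crossing of `median + 2·SD` lags the true onset by
roughly 15% of the burst duration (tens of milliseconds). Reported onsets
are therefore refined by a dual-threshold rule: walk back from the
detection crossing to the last sample at or below a lower threshold
(`median + k/2·SD`), then linearly extrapolate the flank between the two
crossings down to the baseline median (capped at 100 ms of extrapolation).
On the synthetic fixture (50 bursts, 150–400 ms, 5× SD) this brings the
mean absolute onset error to ≈ 20 ms; the raw first-crossing convention is
available via `refine_onset=False`. The residual error is set by the
envelope's own temporal resolution — a 10 Hz-wide band gives the background
envelope a correlation time of ~100 ms, so individual onsets cannot be
localized much more precisely by any envelope-domain rule.

A related physical limit: the band-pass smears a strong oscillation whose
duration is below ~100 ms (its spectrum is wider than the passband), so the
minimum-duration rule discriminates 80 ms from 150 ms events exactly at the
envelope level, where it is defined, but a sufficiently high-amplitude
80 ms burst in the raw LFP can still produce > 100 ms of supra-threshold
envelope. Adjacent bursts separated by any sub-threshold gap remain
distinct; no merge window is applied.

## Movement periods

Movement periods are maximal runs of the whole-body pixel-change trace
strictly above 3× a baseline level lasting ≥ 250 ms; the period ends at the
first sample back below threshold. The complement is labeled
`no_movement`, so the two labels exactly partition the analyzed span. When
no baseline level is supplied it is estimated as the median of the samples
at or below the trace's 10th percentile — a robust proxy for the mode of
the quiet-floor distribution.

## Rate tables

Per-unit rates are spike counts over pooled interval durations; the 2×2
state × movement table uses interval intersections, so the
duration-weighted mean of the four condition rates reconstructs the pooled
AS+wake rate as an exact identity (a standing regression test). A spindle
burst is assigned to the state containing its *onset*; bursts may straddle
state boundaries, and onset-based assignment preserves event-rate
semantics. Aggregation is unit → area-within-animal → across animals.

## Sensory responsiveness and activation

PETHs use a 1-s window offset 0.5 s before the event with 10-ms bins, in
spikes/s averaged over events. Events whose window would cross the
recording edge are dropped, not truncated, keeping the normalization exact.

The responsiveness rule compares the mean RW rate against
`mean + 2·SD` of the BLW bin rates, with the SD taken *across the 30
baseline bins of the event-averaged PETH* (population SD). An alternative —
SD across events — would measure a different quantity; the rule as stated
operates on the PETH. A consequence worth knowing: at typical firing rates
the across-bin SD reflects Poisson counting noise of single bins, which is
much larger than the standard error of the 20-bin RW mean, so the rule is
conservative — its false-positive rate on unmodulated Poisson units is far
below 5% (the test suite pins it against a 10⁴-replicate Monte-Carlo of the
rule itself).

Activation uses summed spike counts in equal-length windows (BLW −500 to
−200 ms; RW 0–300 ms) and the strict comparison `ΣRW > 1.5·ΣBLW`, so a
unit silent in both windows never responds (0 > 0 is false), while any RW
spike after an empty BLW does count — both edge cases are asserted in
tests. An area with no responsive units has activation rate 0 by
convention. Event windows closer than 1 s are used as-is; the stimulation
protocol's 2–3 s spacing mostly avoids overlap.

## Spindle–event coupling

Observed coupling is the fraction of spindle onsets with at least one
event in `[onset − 0.5 s, onset)`; an event exactly at onset does not
count as preceding. The null redraws **both** onset sets uniformly within
the behavioral-state or stimulation period (counts preserved, interval
lengths respected) 100 times and averages; a mode redrawing only events is
provided for sensitivity analysis. The mean of the shuffle distribution is
used for comparison, with the full per-shuffle vector retained in the
result. For events forming a Poisson process at rate λ the expected
coupling has the closed form 1 − exp(−λ/2), which calibrates the null in
the tests. Across-animal inference pairs observed and expected
probabilities per animal on the arcsine scale; with fewer than two animals
only descriptive output is produced.

## Pre/post anesthesia battery

Movement quantity over a period is the baseline-subtracted sum of the
pixel-change trace divided by the period duration. The baseline is the
mean over five 1-s no-movement windows. Two numerical choices matter:

- **Window selection.** Auto-selected windows are the candidates whose
  rolling 1-s sum is closest to the *median* of the no-movement
  distribution — a typical quiet window. Selecting the global minima
  instead would underestimate the baseline by about two standard deviations
  of the window mean, inflating both periods' quantities by the same
  offset and biasing the percent change toward zero. Manual windows can be
  supplied, mirroring an experimenter's by-eye choice.
- **Signed subtraction.** Baseline-subtracted samples are summed with
  sign, so symmetric sensor noise cancels and the quantity is an unbiased
  estimate of movement-related pixel change per second. Zero-clipping each
  sample (available as `clip_negative=True`) rectifies the noise into a
  positive offset common to both periods and drags the pre/post percent
  change several points toward zero at realistic noise levels.

Percent change is `100·(post − pre)/pre`, undefined (reported missing)
when the pre value is 0. ISIs are taken between consecutive spikes within
the same period interval — pairs spanning the injection gap are excluded.
The survivor function uses the strictly-greater convention (S equals 0 at
the largest ISI); the bottom fifth percentile uses the
interpolated-inverted-CDF convention (linear interpolation between order
statistics at positions i/n), under which the 5th percentile of the ISIs
{1, …, 100} ms is exactly 5 ms. Units contributing fewer than 20 ISIs to a
period are omitted; survivor plots pool ISIs across units.

## Statistics

The arcsine transform is arcsin(√p). Cohen's D is the mean difference over
the SD of differences (paired) or the pooled SD (unpaired). The 2×2
repeated-measures ANOVA is computed as three 1-df within-subject contrast
F tests (F = t² of the one-sample t on per-subject contrasts) — exact for
this design and free of sphericity concerns at 1 df — with partial
η² = F/(F + df_error); the tests cross-check F, df, p and η² against
pingouin's two-way RM-ANOVA to 1e-6. The four planned paired contrasts
(within state across movement, within movement across state) use a
Bonferroni-adjusted α of 0.05/4 = 0.0125. Identical paired samples return
t = 0, D = 0; a constant nonzero difference has zero variance and is
reported missing rather than infinite. Shapiro–Wilk is advisory only; no
nonparametric fallback is applied.

## Synthetic-session generator

The generator's defaults are the study-like conditions every recovery test
runs under:

| parameter | default | rationale |
|---|---|---|
| state budget (P8) | AS 57.7%, wake 30.9%, quiescence 11.4% | reported occupancies |
| state process | alternating renewal, exponential dwells (means ∝ budget) | simplest process matching occupancies; dwell distributions are a stand-in, not a claim about real data |
| twitch rate in AS | 0.2 Hz | a twitch every ~5 s of AS, typical of infant rats |
| wake-movement rate | 0.15 Hz | bouts, only onsets modeled |
| stimulations | exactly 50, gaps uniform 2–3 s, appended after the free period | stimulation protocol |
| movement bumps | rectangles, 5× baseline; 0.3 s (twitch/spasm), 0.8 s (wake) | supra-threshold by construction; rectangles keep run lengths exact for oracle tests |
| unit baselines | AS 4 Hz, wake 2 Hz, quiescence 1 Hz | AS-dominant firing, 2:1 AS:wake ratio |
| response kernel | boxcar, latency 30 ms, width 100 ms, gain 3× AS baseline | causal reafferent response within the 0–200 ms RW |
| spindles | 4/min in AS, 1/min in wake; 15 Hz Hann-windowed sinusoids, 150–400 ms, 5× background SD | AS-dominant spindling; Hann envelope gives a controllable detector-recall target |
| LFP background | 1/f-amplitude noise (flat below 1 Hz), SD 1 | scale-free background without biophysical claims |
| P8 gate | on/off telegraph, dwell means 3 s / 2 s, off factor 0.05 | discontinuous activity; independent of state so expected AS:wake ratios are preserved |
| urethane regime | shared population bursts 0.5 s at 8 Hz, silences 10 s + Exp(8 s) | burst suppression with guaranteed ≥ 10 s silences; yields ≈ 88% firing suppression against the pre-injection regime |
| pre/post durations | 1800 s each | the study's 30-min periods; also what makes ±5-point recovery of the movement suppression statistically attainable |
| movement suppression | 87% of movement *quantity* (bump area/s, thinned against the realized pre-period events) | suppressing event counts alone would over-suppress measured movement, because post spasms are short twitch-like bumps |

Randomness derives from one master seed through named substreams
(states/behavior/LFP/spikes/urethane), so a fixed seed reproduces a session
bit-for-bit while components stay independently perturbable. Spindle
bursts that would overlap are merged in the ground truth (logged). The
saline control arm (`drug="saline"`) generates an independent P8-like
block for the post period.

What the generator deliberately does **not** emulate: biophysical LFP
(volume conduction, laminar structure), realistic EMG spectra, video
itself (only the pixel-change trace), spike-waveform or sorting artifacts,
bout structure within wake movements, and any dependence of twitch timing
on spindles beyond the explicit `coupled_fraction` mechanism. Passing
recovery tests therefore demonstrates the correctness of the analysis
chain under the assumed statistical structure, not robustness to every
property of real recordings.

## Problem sizes

Test and acceptance fixtures use desk-scale problem sizes chosen as the
package's own defaults: 600-s free-behavior sessions (3000 s where a 5%
rate-ratio recovery is the target), 50-burst detector fixtures, 2 000–3 000
null units for classifier calibration against a 10⁴-replicate oracle, 100
random instances for the enumeration checks, and full 1800-s pre/post
periods for the anesthesia battery. The complete suite runs in well under a
minute of CPU; the acceptance script in seconds.

## Known limitations

- The spindle detector's onset accuracy is bounded by envelope resolution
  (see above); offsets inherit the same limit and are not refined.
- The shuffle null redraws onsets uniformly within a period, ignoring any
  within-period nonstationarity; a rate-matched null would be stricter.
- The responsiveness rule's conservatism (across-bin SD) is inherited from
  its definition, not corrected.
- `rm_anova_2x2` is specific to the 2×2 within design; larger designs
  should go to a general mixed-model package directly.
- Percent change is undefined for a zero pre-injection value and such
  animals are reported missing rather than imputed.
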