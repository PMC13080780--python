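# Methods

`pocketlab` re-creates, at desk scale, the validation experiment behind a
mobile visual-oddball task with simultaneous EEG/fNIRS recording: a
task-event engine, a synthetic participant model, and the full analysis
chain from raw multichannel signals to a cohort report. This note records
the model, its assumptions, the numerical choices, and what the synthetic
validation does and does not demonstrate about real recordings.

## Task model

A run is two silent 10 s baselines bracketing a 240 s stimulation block.
Stimuli appear every `isi` = 2 s (0.5 s on screen), giving
`floor(240/2) = 120` presentations. Rare "target" stimuli are separated by
7–21 frequent "standard" stimuli; gap lengths are drawn independently and
uniformly over the integers [7, 21]. The true generating rule of the
original protocol is not published — its observed mean gap (11.87) is
below the uniform mean of 14 — so the uniform draw is a deliberate,
configurable default and no attempt is made to match 11.87. All events are
timestamped on a run-local monotonic clock (0 at run start) and mirrored
into three streams (metadata / stimulus / marker), serialized as
JSON-lines. An optional constant clock offset and Gaussian jitter support
robustness tests; network transport and XDF import are out of scope.

## Synthetic participant

**Behavior.** Reaction times are lognormal, moment-matched to per-class
mean/SD (defaults 718/148 ms target, 542/122 ms standard — the cohort
values observed in the validation study). A response landing at or after
the next onset becomes an omission. Button choice matches the stimulus
class with probability `acc_class` (defaults 0.9458 / 0.9912).

**Cohort structure.** Between-participant variation enters as a shared
speed offset applied to both classes (SD 60 ms) plus an independent
target-slowing effect drawn around the 176 ms default difference
(SD 25 ms). Within-subject condition effects in RT tasks are strongly
correlated across conditions, so the class-specific spread is kept much
smaller than the marginal spread; a consequence is that a negative
target−standard difference is essentially impossible (≈10⁻¹² at profile
level), matching the observed all-positive cohort whose signed-rank Z is
the closed-form maximum. With trial-level noise added (~8 target trials
per run), a sign flip has probability ≈0.3 % per participant.

**EEG.** 32 channels at 250 Hz: 1/f-shaped Gaussian background
(default SD 5 µV), a power-line sinusoid (60 Hz, 2 µV), and a
stimulus-locked ERP — a single positive Gaussian bump (FWHM 200 ms)
centred at `p300_latency` (356 ms), class-scaled (3.5397 µV target,
0.74667 µV standard at the peak channel) and projected on the scalp by a
fixed weight table peaking at Cz with Pz at 0.769 (the observed Cz→Pz
target-amplitude ratio). N1/P2 subcomponents are not modelled. Because one
kernel and one weight table serve both classes, the generator cannot
reproduce the observed standard-class peculiarities (standard peak larger
at Pz than Cz, class-specific latencies); the standard-class defaults are
the Cz values, and parameter-recovery checks target the target class. A
configurable fraction of channels (3 %) draws impedance above 30 kΩ to
exercise pruning.

**fNIRS.** 43 long (30 mm) + 8 short (8 mm) channels at 10 Hz, two
wavelengths (760/850 nm). Long channels over the right-frontal ROI carry
an event-locked HbO response: a double-gamma HRF (canonical shape
time-stretched to peak at 9 s, undershoot ratio 1/6, unit peak) convolved
with the class impulse train and scaled (0.2 µM target, 0 standard).
HbR = −HbO/3 throughout — a fixed ratio that keeps the two-wavelength
inversion well-posed while only HbO is analysed. Systemic physiology is
cardiac (1.2 Hz, 0.30 µM), respiratory (0.25 Hz, 0.08 µM) and Mayer
(0.1 Hz, 0.10 µM) sinusoids with random phases plus a slow (<0.05 Hz)
skin fluctuation (0.10 µM); each short channel owns one realisation, and
a paired long channel receives `skin_share` = 0.7 of it plus 0.3 of a
private realisation. Concentrations go through the forward modified
Beer–Lambert model (below), after which motion spikes (0.5/min, 0.02 OD)
and baseline steps (0.2/min, 0.01 OD), white measurement noise (10⁻⁴ OD)
and a 3 % fraction of decoupled channels (noise only, no cardiac) are
injected in optical-density space. The noise magnitudes are this
package's defaults — the study reports none — chosen as typical for
research-grade wearable hardware: cardiac pulsation above the instrument
noise floor (otherwise the scalp-coupling index would be useless on any
real device), skin/systemic amplitudes of the same order as the neural
response.

Master-seed determinism: `SeedSequence(seed).spawn(n)` fans out one child
per participant, so any participant is reproducible in isolation.

## Analysis chain

**Behavior.** A response is attributed to the latest stimulus preceding it
by more than the 100 ms floor and at most the ISI; first response per
stimulus wins. Accuracy counts omissions as errors (denominator =
responded + omitted) — the original report does not state its
denominator; this choice is configurable. The cohort statistic is the
Wilcoxon signed-rank test on per-participant mean RTs: zero differences
dropped, mid-ranks, tie-corrected variance
`n(n+1)(2n+1)/24 − Σ(t³−t)/48`, `Z = (W⁺ − n(n+1)/4)/sd`, two-sided
normal p, effect size `r = Z/√n`. No continuity correction by default
(both variants rounded to the same Z at n = 53); the continuity-corrected
variant is the one that tracks the exact 2ⁿ enumeration within 0.05
absolute for 5 ≤ n ≤ 10 (the uncorrected worst case is 0.127 at n = 5).

**EEG.** Channels with impedance strictly above 30 kΩ are pruned. The
recording is low-passed at 45 Hz (4th-order Butterworth) and notched at
the line frequency (Q = 30), both applied forward-backward so peak
latencies are unbiased; DC is retained. Samples beyond ±100 µV (after
filtering) mark artifacts; an epoch containing a marked sample on a valid
channel is rejected — a deliberate reduction of ocular/muscle artifact
handling to amplitude thresholding. Epochs span −0.2…+1.0 s
(`round(1.2·rate)+1` samples, inclusive endpoints), are baseline-corrected
by the prestimulus mean, and averaged per class (mean ± SEM). The P300 is
the maximum of the class-mean waveform in 250–400 ms; ties break to the
earliest sample; a non-positive maximum is flagged rather than discarded.

**fNIRS.** Processing order: intensity → ΔOD = −log₁₀(I/I₀) (I₀ = temporal
mean, or first-baseline mean — the latter makes the forward/inverse round
trip exact on noise-free data) → scalp-coupling-index mask → motion
correction on OD → Beer–Lambert inversion → 0.08 Hz low-pass →
short-channel regression → epoching. The SCI is the Pearson correlation of
the two wavelengths band-passed to 0.5–2.5 Hz; channels below 0.4
(strict) are pruned, zero-variance channels flagged undefined. Motion
correction is two-stage: wavelet despiking (db4, 4 levels, detail
coefficients outside 1.5·IQR zeroed) then spline re-levelling of segments
flagged by a moving-SD-of-derivative criterion (window 1 s, 4× median),
with post-segment data re-anchored for continuity so persistent steps are
removed. The Beer–Lambert inversion solves the 2×2 system
`ΔOD(λ) = [ε_HbO(λ)·ΔHbO + ε_HbR(λ)·ΔHbR]·L·DPF(λ)` per sample, with the
widely used base-10 molar extinction compilation (760 nm: 0.586/1.548;
850 nm: 1.058/0.691 mM⁻¹cm⁻¹) and DPF 6.0 at both wavelengths; the
extinction matrix must have condition number < 100. The physiological
low-pass is a zero-phase Kaiser-window FIR (passband edge 0.08 Hz, ≥20 dB
per pass at 0.25 Hz). Each long channel is regressed on its nearest short
channel (geometric midpoint distance; explicit pairing configurable) with
an intercept, keeping the OLS residual; if every short channel is invalid
the signal passes through with a prominent warning flag. HbO epochs span
−1…+20 s with [−1, 0) baseline subtraction. With a 2 s ISI the 20 s
epochs overlap by construction; the class means are event-locked
averages, not deconvolved responses — standard-stimulus responses and
tails of neighbouring events superimpose, which is a documented
limitation shared with the original analysis.

**Group level.** Channel results are averaged within ROIs over valid
member channels (the shipped ROI table tokenizes the published channel
strings, correcting one left/right typo so no channel sits in two ROIs;
"central midline" and "temporal midline" are aliases for Cz). Grand
averages are across-participant means of participant ROI means with
SEM = SD/√n. A participant is dropped from a modality when more than half
its channels are invalid (the original exclusions state no rule; the
threshold is configurable). The cohort report emits the RT/accuracy
table, the Wilcoxon result, the Cz/Pz P300 peak table, right-frontal HbO
class means with peak time, and the exclusion log, as CSV/JSON plus
waveform figures.

## What the synthetic validation shows — and what it does not

Passing tests demonstrate that the analysis chain recovers the structure
the generator puts in: all-positive RT effects and the closed-form
signed-rank Z at n = 53; target-dominant P300 at the midline with latency
inside 250–400 ms; right-frontal HbO separation over 5–15 s post-stimulus
with the peak near 9 s; exact Beer–Lambert round trips; filter responses
to spec. They do not certify performance on real recordings: the
generator has no eye blinks or EMG (only amplitude outliers), no pulse
waveform morphology, a single ERP component, a literal spatial weight
table instead of a head model, and stationary noise. The printed study
values (718/542 ms, 94.58/99.12 %, 3.5397/0.74667 µV, 356 ms, ~9 s peak)
summarize human recordings that are not public; here they are generator
defaults, and the meaningful check is parameter recovery, not numerical
reproduction of the originals.

## Estimator resolution and problem sizes

The windowed-max P300 read-out is upward-biased by roughly 1.5× the
grand-average noise SD, and its latency estimate wanders by
≈40 ms per µV of grand-average noise because the 200 ms-FWHM bump is flat
near its peak (its value 16 ms off-peak is only 1.8 % below the maximum).
At the default 5 µV background and ~8 target trials per run, a 53-person
grand average has ≈0.26 µV of residual noise — enough to blur latency by
±10–20 ms, the same jaggedness the original 4-minute task produced.
Consequently the amplitude-recovery check runs on a 300-participant
EEG-only cohort (noise floor ≈0.11 µV, bias < 10 %), and the
latency-recovery check runs at a 0.5 µV background where the ±8 ms
(2-sample) tolerance is resolvable; both problem sizes are fixed choices
of this package. RT/accuracy recovery uses the standard n = 53 cohort.
The replication default (n = 53, EEG + fNIRS + behavior) completes in
well under a minute on one core.

## Degenerate inputs and tie-breaks

All-zero Wilcoxon differences raise (degenerate test); all-tied
magnitudes raise on zero variance. A class with no epochs raises, naming
the class. Events whose epoch window leaves the recording are dropped
with a warning, not an error. Zero-variance fNIRS channels get an
undefined SCI and are pruned with a reason code. Peak ties break to the
earliest sample. Schedules too short to hold a single target raise a
dedicated error. Config validation names the offending field; the CLI
maps configuration errors to exit code 2 and data errors to 3.
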