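# Methods

## The assay

A honeybee colony is probed with a short artificial vibrational pulse and
its reflex is read from an accelerometer in the central comb.  The
stimulus is a pure sinusoid under a Gaussian amplitude envelope: carrier
340 Hz, envelope FWHM 30 ms, total support 0.1 s.  Both figures hold
simultaneously because the envelope is centred in the window with its
tails truncated at the edges.  The carrier is `cos(2πf(t − t_c))` with
`t_c` the centre *sample* of the window, so the waveform is even-symmetric
about its centre and its peak (normalized to the configured amplitude)
falls exactly on the centre sample; this convention is fixed so outputs
are bit-reproducible.  Pulses fire on an hourly grid jittered by
independent Gaussian offsets (SD 15 min); any draw that would reorder two
pulses is re-drawn (up to 100 times, then the configuration is rejected).
The re-draw truncates roughly 0.2% of draws and shaves about 1% off the
realized offset SD — a documented property of the policy, allowed for in
the tests.

## Response metrics

With `E(t)` the rectified signal smoothed by a centred 4.5 ms moving
average (edges handled by shrinking the window, so `E` is exactly
homogeneous under amplitude scaling):

* positive response = mean `E` over the 4 s after the pulse minus mean
  `E` over the 1 s before it (positive when the bees buzz louder);
* negative response = mean pre-pulse `E` minus mean `E` over the 0.25 s
  after the pulse (positive when the signal drops);
* pulse magnitude = RMS of the raw signal over the pulse span.

"Mean vibration" is computed on the rectified smoothed envelope, not the
signed signal (whose mean is ≈ 0); RMS instead of mean absolute value
would only rescale the metrics.  The pulse span itself belongs to neither
window.  Windows are cut sample-exactly: a pulse 1 s into an extract puts
the pre-window at sample 0.

## Generative model (synthetic colonies)

The simulator produces traces with the statistical structure the analysis
assumes, plus a per-pulse ground-truth log, so every stage is testable
without a hive recording.

The trace is a single band-passed (50–2000 Hz Butterworth, zero-phase)
unit-variance Gaussian carrier, amplitude-modulated by

    σ(t) = baseline_rms · diurnal(t) · Π_pulses (1 − d·e^{−(t−t_end)/τ}) + buzz(t)

plus independent additive whoop chirps and the pulse artifact itself.
Immobilization is multiplicative on the colony envelope (moving bees
scale the whole signal; d = 0.20, τ = 1 s by default); the buzz adds
*linearly in the envelope domain*.  Two independent Gaussian sources
would add in quadrature under rectification, which would make the
measured positive response non-linear in the configured buzz amplitude;
modulating a common carrier keeps the response metrics exactly linear in
the planted amplitudes and gives closed-form expected values for the
tests.

The buzz comprises **two** independently scaled unit-peak templates — a
short-lived one (quadratic rise to a peak 1 s after the pulse, exponential
decay τ = 1 s) and a long-lived one (rise over 2 s, decay τ = 4 s) — with
per-event Gamma(shape 2) amplitude variability around means of 0.5 and
0.3 baseline-RMS units.  Two templates with independent amplitudes are
what make the collective buzz occupy exactly the first two principal
components downstream; the quadratic onset keeps the first 0.25 s nearly
buzz-free, so the immobilization drop remains visible, as it is in real
recordings.

Whoops are 80 ms upward 300→600 Hz chirps under a Gaussian envelope,
Poisson-distributed with mean 0.15 per pulse, amplitude 4 baseline-RMS
units (±30%), onset latency Gamma(shape 16, mean 200 ms) truncated to
(0, 2] s.  They model loud individual signals from bees near the sensor:
sporadic (a few hundred across thousands of pulses), clearly audible
above the colony background, and tightly clustered around the typical
200 ms latency.  Rectification adds envelopes in quadrature for
incoherent components, so a whoop must be genuinely loud to rise above
the colony envelope noise — amplitudes much below ~3 baseline-RMS units
are invisible to PCA at desk-scale event counts.

The pulse artifact is scaled by a transfer gain (default 20: the drive
dwarfs the colony signal, as in real recordings where it clips the
display).  For frequency sweeps the gain is a Gaussian bump peaked at
500 Hz (width 300 Hz) over a 0.15 floor, mirroring the measured shape of
the shaker-plus-comb transfer.

Seasonal campaigns are generated as per-pulse extracts (1 s pre + pulse +
4 s post + padding) rather than one continuous waveform: a season at
8 kHz would exceed 10^10 samples, and the analysis operates on
pulse-aligned extracts anyway.  A lead-in pad is simulated and discarded
so band-pass filter edge transients cannot bias the pre-pulse envelope.
Diurnal modulation multiplies baseline and buzz amplitudes via a 24-point
hourly profile; seasonal modulation multiplies per-day buzz amplitudes.

### Video

The video generator renders Gaussian blobs (σ = 2 px) random-walking with
per-frame Gaussian steps (0.6 px RMS) on a 96×128 frame at 50 FPS, 150
bees by default.  After each pulse the step size is multiplied by
`1 − d·e^{−(t−t_end)/τ}`.  Steps are kept small relative to the blob so
the mean absolute frame difference stays linear in the step size;
saturation (displacements beyond the blob) would bias the fitted recovery
constant low.  The video assay couples the shaker directly to the frame,
so its default immobilization depth is 0.9 — far deeper than the gentle
hive-wall knock — matching the near-total freezing seen on camera.  The
analytic expected-mobility curve (step factor at the time of the later
frame of each pair) is returned alongside for oracle checks.

## PCA separation and whoop detection

The response matrix holds the 4.5 ms-smoothed post-pulse envelopes, one
row per pulse, each minus its scalar pre-pulse envelope mean.  Rows are
sampled at the smoothing resolution (every 4.5 ms): the raw rate
oversamples the envelope ~36× and only inflates the noise dimensionality.
PCA (full SVD) is sign-fixed so each component's inner product with the
column mean is non-negative, making "decreasing first-PC score" a
reproducible ordering (ties broken by event epoch).  Reconstruction from
ranks 1–2 estimates the collective response; ranks 3–15 isolate the
idiosyncratic whoops.  Rank cut-offs are configuration parameters.

The whoop detector first removes the across-event column mean from the
rank-3–15 reconstruction (the shared buzz/drop template lives there),
then whitens each column by its robust (MAD) SD across events — colony
envelope noise scales with the local envelope, and without the whitening
the fluctuations around the buzz peak trigger false detections.  Per row,
whitened samples above 5 robust SDs are grouped into excursions, merged
within 20 ms, dropped if shorter than 10 ms, and each onset is walked
back to the last 1-SD crossing so it tracks the start of the whoop rather
than the instant it cleared the high threshold.

## Recovery fitting and frequency effectiveness

`M(t) = M0 − D·e^{−(t−t_end)/τ}` is fitted by bounded least squares with
a fixed initialization (M0 = pre-pulse mean, D = trough estimate,
τ = 0.5 s, τ ∈ [0.02, 30] s) so fits are deterministic; a depth
indistinguishable from zero leaves τ unidentifiable and flags the fit
with infinite residual.  Trough depth is measured at the first frame at
or after the pulse end, where immobilization is maximal.

Sweeps drive one beep per frequency (0→2000 Hz in 50 Hz steps, 2.2 s
apart; the 0 Hz entry is a null pulse).  Because 2.2 s is about two
recovery constants, each pulse's immediate pre-window still rides on the
previous recovery; the effectiveness curve therefore measures every
trough against a single baseline taken before the first pulse (a
per-pulse baseline mode exists for well-separated pulses, and the overlap
is logged as a warning).

## Reporting

Diurnal grids interpolate each day's metric linearly from the jittered
pulse times onto integer hours; cells outside a day's first/last pulse,
and days with fewer than two pulses, are explicitly missing, never zero.
Morning daily averages use a half-open local-time window, default
[00:00, 12:00) — "morning" is a configuration choice.  Colony outliers
are flagged per sliding window (default 7 days) when a colony's mean
exceeds the cross-colony median by 3 robust SDs (1.4826 × MAD); with
fewer than three colonies the statistic is meaningless and the call is
rejected.  All epochs are UTC; local time enters only in reporting.  The
metabolic duty cycle is `100 · response_duration / interval` — 0.14% for
a 5 s response to hourly stimulation.

## Problem sizes and numerical choices

Desk-scale defaults keep every stage fast while preserving the
phenomenology: 200-event campaigns for the PCA stage, 50-event runs for
the immobilization statistics, 900-frame (18 s) videos for recovery
fitting, and a 90 s frame stack for the 41-point sweep.  Band edges are
kept below Nyquist at reduced sample rates; reduced-rate simulations
(2 kHz, 50–900 Hz band) are used where only aggregate statistics matter.
All generators accept a numpy `Generator` or derive one from the config
seed; identical seeds give bit-identical outputs.

## What passing tests do and do not show

The simulator realizes exactly the envelope phenomenology the analysis
assumes — multiplicative freeze, additive-envelope buzz, loud sparse
chirps, Gaussian band-limited background.  Real colony noise is
non-Gaussian and non-stationary, real whoops vary in shape and can
overlap, comb transfer varies with position and season, and video of a
real comb contains occlusions and lighting drift.  Passing tests
therefore validate the *measurement machinery* (alignment, metrics,
separation, fitting, aggregation) and its statistical calibration on data
whose ground truth is known — not the biological claims themselves.

A known model-intrinsic gap: the negative-response metric averages the
exponentially recovering drop over a 0.25 s window, so it reads at most
`τ(1 − e^{−0.25/τ})/0.25 ≈ 88.5%` of the instantaneous 20% depth, and
concurrent buzz onset and whoops (present at the pilot defaults, as in
real data) fill part of the trough; the pilot-default reading is
therefore ~12–16% rather than the instantaneous 20%.
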