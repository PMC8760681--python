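# Methods

This note documents the models, parameter choices, and numerical decisions
behind `optolfp`, in the order data flow through the package.

## Session model and conventions

A session is `n_hours` (default 3) consecutive "hours" of `hour_s` seconds
(default 3600 s): pre-recording, light-ON, post-recording. Time is float
seconds from session start; every interval is half-open `[a, b)`; sample
`i` covers `[i/fs, (i+1)/fs)`, so a sample exactly on a boundary belongs
to the following interval. For stimulation sessions all magnitude and
spectral analyses of the light-ON hour use only its first
`hour_s − fadeoff_s` seconds (default 50 min), because light intensity
fades off over the final stretch of the illumination protocol.

Signals are stored as 16-bit EDF with one data record per second and a
symmetric physical range (±10 mV by default, widened to the next integer
mV when data exceed it), giving a worst-case quantization error of
`R/32768` mV. Events travel as CSV (`label,onset_s,duration_s`); light
pulses are rows labelled `pulse`, generalized seizures rows labelled `GS`.
The EDF reader/writer is intentionally minimal (the format's plain-ASCII
header plus little-endian int16 records); the test suite cross-checks
every written file against an independent EDF reader.

## Preprocessing

* **Downsampling** (10 kHz → 500 Hz for magnitude and burst analyses) uses
  a linear-phase FIR low-pass with cutoff 0.4× the output rate and
  `20·q + 1` taps for decimation factor `q`, applied polyphase with
  compensated delay (zero net phase) and linear edge padding. The tap rule
  keeps the transition width a fixed fraction of the output bandwidth, so
  the passband (<0.4·fs_out) is flat to <1% and the stopband at the output
  Nyquist is well beyond 20 dB regardless of the input rate. Zero phase
  matters because the line length is sensitive to phase distortion.
  Non-integer decimation factors are rejected rather than resampled.
* **Exclusion masking**: samples inside annotated `GS` intervals (the
  discharge *and* the postictal depression) are flagged excluded.
  Overlapping intervals are OR-ed. Excluded samples are dropped from sums
  and the effective duration shrinks accordingly — they are never
  zero-filled, which would deflate magnitude estimates at the boundaries.
  For burst statistics the whole session is dropped instead (see below).

## Line length

`L = Σ|x(k−1) − x(k)| / t` in mV/s, with `t` the included duration.
Differences bridging a masked gap are not counted. A window with fewer
than two included samples raises a distinct error — an undefined line
length is never reported as zero. Useful analytic anchors: a constant
trace gives 0; a unit-amplitude sinusoid of frequency f gives ≈ 4f (total
variation); a 0/1 alternation at 500 Hz gives 499 mV/s over one second.

Pulse-triggered analysis extracts, for every pulse `p` inside the
light-analysis window, `[p−2, p)` ("before"), `[p+w_p, p+w_p+2)` with
`w_p` the 10-ms pulse width ("after" — the window starts at the pulse
*offset* so the illumination artifact is excluded), and the same clock
offset shifted one hour earlier into the pre-recording ("pre"). The
"before" window abuts the pulse with no guard gap. A pulse whose windows
touch excluded samples or fall outside the recording is dropped from all
three series, keeping them aligned. Session means are arithmetic means
over the retained pulses.

## Spectral analysis

Welch PSDs are computed on raw-rate data with periodogram length 10× the
sampling rate (0.1-Hz grid), Hann window, 50% overlap, and per-segment
mean removal (the acquisition chain is AC-coupled, so DC carries no
signal; the spectrogram overlap/segment/FFT rules are fixed at 0.25×fs /
0.5×fs / 10×fs instead). Band power is the trapezoidal area under the
one-sided density over delta [1,4), theta [4,12), beta [12,30) and gamma
[30,120) Hz; both band edges enter as integration endpoints, so AUCs over
adjacent bands add exactly. Total AUC matches the signal variance to well
under 2% (Parseval). For masked traces the PSD is the duration-weighted
average of Welch PSDs over contiguous unmasked runs at least one
periodogram long; an hour with no such run is an error.

## Epileptiform activity

Spike detection runs on 500-Hz data: band-pass 5–80 Hz (4th-order
Butterworth, zero-phase), threshold at 5 robust standard deviations
(1.4826 × median absolute deviation — ordinary SD would be inflated by the
spikes themselves), one extremum per 80-ms refractory window. Spikes are
grouped into bursts as maximal runs with inter-spike gaps ≤ 2 s and ≥ 5
members, padded by half the sharp-wave width. Load classes use the
intra-burst spike rate r = members/duration: **high** if r ≥ 1 Hz and
duration ≥ 10 s, **medium** if r ≥ 0.5 Hz, otherwise **low**. These
thresholds are this package's own documented stand-ins — transparent,
deterministic, and configurable — not the values of any published
classifier. The burst ratio is high-load burst time over session time; a
session containing a generalized seizure is flagged dropped and its ratio
reported as missing (the long postictal suppression would bias it), never
as zero. The whole stage contains no randomness.

## Synthetic LFP generator

The generator produces the statistical structure the analyses assume —
and only that. Components, per channel:

* **Background**: 1/f^β noise (β = 1) band-limited to [1, 200] Hz, plus
  three oscillators realized as band-passed white noise scaled to a target
  RMS — theta (7 ± 1.5 Hz, 0.15 mV), beta (20 ± 4 Hz, 0.05 mV), gamma
  (40 ± 15 Hz, 0.04 mV). The upper background limit is the decimation
  passband edge at the 500-Hz analysis rate, which makes the line-length
  scale independent of the raw sampling rate chosen. The background RMS
  default (0.190 mV) was calibrated once, by direct computation, so the
  composite signal's 500-Hz line length is ≈ 50 mV/s — the magnitude
  scale of freely-moving hippocampal recordings; the habituation gains
  (1.00, 0.84, 0.79 per hour, stepwise) then reproduce hour-referenced
  declines of ≈ −8 and ≈ −10.5 mV/s.
* **Pulse response**: a multiplicative gain
  `g(t) = 1 ∓ s·Σ_k exp(−(t−p_k)/τ)` (suppression/enhancement), clipped
  below at 0.05 and identically 1 outside the light-ON window. Linear
  superposition of exponentials is the simplest model giving near-full
  recovery within a 20-s (0.05 Hz) inter-pulse interval and incomplete
  recovery within 10 s (0.1 Hz). The silencer default (s, τ) = (0.25,
  12 s) was chosen by closed-form evaluation so the steady-state
  after/pre and before/pre ratios at 0.1 Hz are ≈ 0.59 and ≈ 0.74; the
  true in vivo photocurrent kinetics are unknown, so τ is deliberately a
  free parameter. Because the gain is multiplicative and slowly varying,
  the line length of `g·x` over a window is the window-mean gain times the
  line length of `x` (to ~3% for 2-s windows) — the property that makes
  parameter recovery testable against the closed form.
* **Bursts**: sharp-wave kernels (a dominant sharp deflection with a
  smaller opposite after-wave, 40 ms, peak 8 robust SDs of the background)
  at jittered 2-Hz grids inside non-overlapping truth intervals placed
  with ≥ 5-s separation (wider than the 2-s grouping gap, so truth bursts
  cannot merge). Contralateral propagation, when on, copies the burst
  intervals at 0.8× amplitude.
* **Generalized seizures**: a ramped, sharpened 5-Hz rhythm (≥ 5 robust
  SDs) added to both channels, followed by multiplication with a 0.2
  postictal gain for 60 s; the annotated exclusion interval covers
  discharge plus postictal window. Seizure counts are Poisson with
  per-group rates (nonzero only for the two cyclase-carrying constructs).

Everything is deterministic given the config seed (per-channel,
per-component substreams). What the generator does **not** emulate: real
waveform morphology (spindles, sharp-wave ripples, theta-gamma coupling),
behavioural state transitions within an hour (habituation is stepwise),
movement or electrical artifacts, and channel cross-correlation of the
background. Passing tests therefore demonstrate that the pipeline
recovers what it claims to measure under the assumed signal model — not
that the model captures every property of real LFP.

## Statistics

Per-animal values are arithmetic means over technical replicates before
any test (n = animals). One-way repeated-measures ANOVA is computed
directly from within-subject sums of squares with no sphericity
correction (a documented limitation; with two conditions F equals the
squared paired t exactly). The two-way repeated-measures ANOVA delegates
to pingouin; Tukey and Dunnett comparisons to scipy; Dunn's post hoc is
implemented here (rank z-tests with tie correction, Bonferroni-scaled
over the tested pairs — the scaling convention is a package choice, as
statistical software differs here). All p-values are two-tailed; every
result records its α (0.05/k where k comparisons share a family, e.g.
α = 0.025 for the two post-baseline hours). Degenerate inputs (zero
variance, identical pairs, missing cells) raise errors rather than
returning NaN. Parametric vs non-parametric dispatch is the caller's
choice per analysis, not automated normality testing.

## Problem sizes and tolerances

Tests and the acceptance script run at reduced scale chosen for
statistical headroom: 1-kHz raw rate with 10-min "hours" for habituation
and burst analyses, 15-min "hours" for the seed-robustness checks of the
recovery patterns, and full 60-min hours (150 pulses at 0.05 Hz) for the
suppression-depth recovery, where the measured after/pre ratio matches the
closed-form prediction to well within 5% (typically <0.5%). Burst-ratio
recovery is accurate to ~0.01 against a ±0.03 criterion; truth-interval
Jaccard overlap is ≈ 0.98. The pipeline report bundle contains no
wall-clock state, so repeated runs under one master seed are
byte-identical.

## Known limitations

* The EDF container requires integer sampling rates and whole-second
  durations (natural for this protocol).
* Artifact rejection beyond annotated seizures (and a conservative
  cross-channel seizure auto-detector) is out of scope; annotations are
  authoritative.
* Burst-load thresholds are stand-ins; absolute burst ratios on real data
  would need threshold calibration against visual marking.
* RM ANOVA reports uncorrected degrees of freedom (no
  Greenhouse–Geisser), matching common practice in the field's software.
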