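# Methods

This note documents the models, conventions and numerical choices behind
`apneabelt`, and what the synthetic experiments do and do not demonstrate.

## Synthetic cardiorespiratory generator (`simgen`)

The generator emulates a chest-worn acquisition setup during sleep with
deliberately simple but controllable physiology.

**ECG.** A train of Gaussian-mixture PQRST templates is placed at cumulative
RR intervals. Per beat the RR interval is drawn uniformly from
`rr_normal_range` (default 0.8–1.0 s) or, inside an apnea event,
`rr_apnea_range` (default 1.1–1.2 s). The R deflection of a normal beat is
the midpoint of `ramp_normal_range` (default 0.6–0.8 mV) modulated
sinusoidally by the instantaneous respiration phase — so the R-amplitude
fluctuation *is* the respiratory modulation, spanning the configured range —
plus 0.002 mV beat-to-beat jitter; apneic beats sit at `ramp_apnea_mV`
(default 0.6 mV) with no respiratory modulation (the breath is held).
R peaks are snapped to the sample grid, so the emitted ground-truth index
list is exact. Baseline wander (sinusoids at 0.15–0.33 Hz) and white noise
are added on top.

Two numerical details matter:

- *Area balancing.* Each template carries two wide, shallow restoration
  lobes at ±0.46 s from R whose areas cancel both the net area and the first
  moment of the P/Q/R/S/T Gaussians. Without this the beat train has
  low-frequency content that the 0.5 Hz high-pass of the denoiser converts
  into an amplitude bias of a few hundredths of a mV, which would corrupt
  R-amplitude recovery; with it, configured R amplitudes survive denoising
  to about ±0.01 mV.
- The first beat is placed at 1.5 s so no beat sits inside the zero-phase
  filter's edge transient.

**Respiration.** A frequency-modulated oscillation whose instantaneous
frequency wanders inside `resp_freq_range` (default 0.1–1.0 Hz, the band the
belt electronics are designed for), with a slowly varying amplitude and 2 %
additive noise. During an apnea event the envelope drops to 5 % of normal
(a ≥ 90 % collapse) with 0.5-s smooth transitions.

**Apnea events.** Unless explicitly placed via `forced_events`, the number
of events is Poisson with mean `apnea_rate_per_hour × hours` (default
6 events/h) and durations are uniform on [10, 30] s — holds of at least
10 s, with 30 s as a realism cap — placed without overlap and with ≥ 10 s
gaps. A minute is labelled apneic iff its overlap with any single event
reaches `apnea_min_duration_s` (default 8 s, matching the rule threshold).

**Motion.** Per-axis accelerometer noise of 0.005 g plus occasional bursts
(2–5 s, 0.2–0.5 g, default 4/h), logged so gating can be verified.

**Determinism.** One integer seed; per-channel substreams are spawned from a
`numpy` `SeedSequence`, so identical configs give bit-identical output.

**What the generator does not model:** QRS morphology changes other than
amplitude scaling, arrhythmia, electrode motion artefact coupled into the
ECG, obstructive-vs-central apnea differences (both are represented as one
"breath hold + bradycardia + lower R amplitude" signature), and any coupling
between motion bursts and ECG noise. Consequences below.

## Conditioning twins (`conditioning`)

The respiration chain is gain 80, one second-order low-pass at 88.46 Hz and
a DC boost to mid-rail ahead of a 12-bit ADC; the ECG chain is gain 1000
into a 24-bit ADC. Filters are bilinear-transform Butterworth designs of the
stated order and cutoff — maximally flat is the standard choice when only
"second-order active low-pass" is specified — which places the −3 dB point
exactly at the cutoff. The ADC model rounds to the LSB grid
(`adc_range / 2^bits`) *without saturation*: an ideal infinite-range
quantizer. This keeps the gain/filter stage exactly linear before
quantization and bounds quantization error by half an LSB; rail clipping is
deliberately out of scope. The respiration ADC resolution is not a datasheet
value; 12 bits is this package's default for a generic microcontroller ADC.

## Denoising and R-peak detection (`ecg_dsp`)

Denoising is a 4th-order Butterworth band-pass, 0.5–40 Hz, applied
forward–backward (zero phase), plus a 50 Hz powerline notch when the
sampling rate allows one (at the default 100 Hz it does not, and the band
edge at 40 Hz already suppresses that region). Zero phase keeps R-peak
positions within a sample or two of the raw signal.

Detection is classic Pan–Tompkins: 5–15 Hz band-pass, five-point derivative,
squaring, 150 ms moving-window integration, dual adaptive thresholds with a
200 ms refractory period and RR-based search-back (trigger at 1.66× the
running mean RR of the last 8 intervals; search-back ties resolve to the
earlier candidate). Thresholds are initialized from the first 2 s of the
integrated signal and updated multiplicatively from running signal/noise
peak estimates, so detection is invariant to positive rescaling of the
input. Detected fiducials are refined to the local maximum of the denoised
ECG within ±50 ms (an idempotent step), then peaks closer than 0.2 s are
pruned keeping the larger amplitude; implied RR outside [0.2, 3] s is
treated as artefact.

## Feature streams (`features`)

- Excess kurtosis uses biased (1/n) central moments: `K = m4/m2² − 3`; a
  flat segment (zero peak-to-peak) is an error, not a silent zero.
- The EDR closed form `sqrt((sqrt(1+K²)−1)/(σ²K))` is algebraically
  identical to the four-moment form because `γ4 = σ⁴(K+3)` for moments of
  one segment; both forms are kept and cross-checked in tests. Guards:
  `|K| < 1e−8` returns the removable-singularity limit 0; `K < 0`
  (platykurtic segment, outer root undefined) returns 0 with a warning.
  Both guards keep downstream streams NaN-free.
- EDR and RRI knots sit at the left R peak of their inter-peak interval,
  RAMP knots at each R peak; all three are cubic-spline interpolated
  (natural boundary) to a shared uniform grid at 3 Hz — enough to Nyquist-
  cover 1 Hz respiration while keeping minute segments at 180 × 3 samples —
  with edge values held outside the first/last knot.
- Minute segmentation z-scores each channel over the whole record (the
  classifier should see relative, not absolute, levels) and uses half-open
  `[60k, 60(k+1))` windows; a trailing partial minute is discarded.
- `hrv_summary` provides the conventional time-domain set (mean RR, SDNN,
  RMSSD, pNN50) and LF/HF band powers via Lomb–Scargle on the irregular
  beat times; it is a standard convenience summary, not an input to the
  minute classifier.

## Classifiers (`detect`, `nn`)

The minute classifier is a stacked LSTM (3 layers, hidden size 64 per
layer — the recurrent width is this package's choice) feeding a dense head
of 128/64/32/1 with ReLU activations and a sigmoid output, trained with
two-term binary cross-entropy (natural log), Adam (lr 1e−3, batch 32),
global-norm gradient clipping at 5, forget-gate bias 1, for up to 50 epochs.
The one-term, base-10 loss variant is retained as
`bce_loss_single_term` for loss-value comparison only: it ignores negative
minutes and cannot train a binary output. The implementation is pure numpy
(forward + BPTT), verified against central finite differences, and exactly
reproducible for a given seed. The decision threshold is 0.5 with ties
classified positive.

Baselines (SVM, RFC, DTC, KNN, AdaBoost, GNB, QDA, BP/MLP) use scikit-learn
defaults with pinned seeds — except QDA, which needs `reg_param = 1e−3`
because the pooled-sequence summary features are collinear — on per-minute
channel means/SDs plus an 8-point mean-pooled sequence per channel, with the
identical stratified train/validation split as the LSTM (default 25 %
validation, per-minute splitting of one record).

## Breathing rule and motion gate

The rule operationalizes "sustained abnormal waveform" as: moving-RMS
envelope (2-s window) below 20 % of the record's median envelope. A
rectangular RMS window smears a true collapse edge inward by roughly half a
window at that floor, so raw sub-threshold runs understate the collapse by
~1.8 s; each run is therefore dilated by half a window per side before the
duration test, restoring the underlying collapse support. With this
compensation the 8-s boundary is sharp: a 7.5-s collapse produces no event
and an 8.0-s collapse produces one, as the sweep in
`scripts/acceptance.py` measures. A silent (all-zero) channel flags the
whole record with a warning rather than silently passing.

The motion gate marks a minute unusable when the standard deviation of the
(median-centred) acceleration magnitude exceeds 0.02 g — low enough that a
2-s, 0.2-g burst inside a minute trips it while the 0.005-g noise floor does
not. Unusable minutes are excluded from AHI event counting and reported
separately; how the three outputs (classifier, breathing rule, motion)
should be *fused* into a single decision is left open deliberately, and the
screening report carries them side by side.

AHI from minute labels counts each maximal run of apneic minutes as one
event over the usable hours.

## What the synthetic experiments show — and don't

The default study conditions (balanced 240-minute sets, RR 0.8–1.0 s vs
1.1–1.2 s, R amplitude 0.6–0.8 vs ~0.6 mV) make the classes separable
almost by the per-minute RRI mean alone, and both the LSTM and every
baseline reach near-perfect held-out accuracy within a few epochs, while
label-shuffled training stays at chance. This validates the *plumbing* —
features carry the class signal end to end through detection, interpolation
and normalization, and the trainer can exploit it — but says nothing about
accuracy on real polysomnography-annotated data, where class overlap,
inter-subject variability and annotation noise dominate. Results on real
recordings should be established per-subject with held-out subjects, which
the per-minute split here does not emulate.

## Problem sizes

Defaults used by the test suite and acceptance script: 300-s records for
signal-level checks, 240-minute single-subject datasets for classifier
checks, 20 training epochs, 1000-draw oracle comparisons and a 10⁴-table
metric fuzz. These sizes were chosen so the full suite exercises every
claim at comfortable statistical margins while remaining quick on one CPU.
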