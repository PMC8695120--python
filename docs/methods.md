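# Methods

This note documents the models, parameter choices, numerical conventions
and limitations behind `tremorloop`.  Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## The synthetic patient (plant)

The plant emulates the sensing streams of an implanted research platform
for essential tremor: cortical LFP from a strip electrode over sensorimotor
cortex, a wrist-worn 9-axis IMU, surface EMG, and the applied stimulation
amplitude.  It is driven by a prompt schedule (rest / overt movement /
imagined movement intervals) and by the stimulation input, and is fully
deterministic given one session seed.  All noise is pre-generated from
named substreams of that seed and is independent of the stimulation input,
so a closed-loop run and a scripted run with the same seed share
sample-exact noise — which makes paired comparisons (adaptive vs.
stimulation-off on the identical plant) exact.

**LFP (µV, 422 Hz by default; 200/800 Hz supported).**
Three components:

1. *Pink background*: white Gaussian noise shaped to a 1/f power spectrum
   (amplitude ∝ 1/√max(f, 1 Hz) to keep variance finite), normalized to an
   RMS of `pink_noise_scale_uv` (default 3 µV).
2. *Beta rhythm*: a unit-RMS band-limited Gaussian carrier (4th-order
   Butterworth band-pass over `beta_band`, default 12–30 Hz, zero-phase
   filtered so it is stationary from the first sample) multiplied by an
   amplitude envelope
   `beta_baseline_amp_uv × (1 − erd_fraction × g(t))`, where `g` is the
   first-order smoothed movement gate.  A band-limited carrier rather than
   a single tone was chosen because movement-related desynchronization
   affects the whole band, and a tone would concentrate the decodable
   signal in ~3 Welch bins.  Default `beta_baseline_amp_uv` = 4 µV and
   `erd_fraction` = 0.5 (a 75% band-power drop, a deep but plausible ERD);
   neither is claimed to match any patient — they are free parameters.
   Imagined movement drives the ERD gate but not the peripheral channels.
3. *Stimulation artifact*: a tone at the stimulation frequency with
   amplitude `stim_artifact_gain_uv_per_v × V(t)` (default 0.5 µV/V) plus
   a broadband floor lift (white noise, 0.05 µV/V).  The artifact's true
   spectral shape on a real device is unknown; a tone + floor is the
   minimal model that (a) makes stimulation state decodable from a band
   near the stimulation frequency and (b) corrupts a stim-off-trained
   spectral decoder applied to stim-on data, which is the phenomenon that
   motivates the dual-decoder design.  A stimulation frequency at or above
   the LFP Nyquist frequency is rejected (the artifact tone would alias).

**Gyroscope (deg/s, 100 Hz).**  A sub-movement-band voluntary component
(0.4 Hz sinusoid gated by overt movement, amplitude 30 deg/s split across
axes), Gaussian sensor noise (0.5 deg/s RMS per axis), and a tremor tone at
`tremor_freq_hz` (default 5 Hz) on the x-axis whose amplitude relaxes with
time constant `tremor_time_constant_s` (0.5 s) toward
`tremor_baseline_amp_dps × (1 − efficacy(V))` during movement and toward 0
at rest.  Confining the tremor tone to one axis keeps the sinusoid power
identity (band power = amplitude²/2) exact for the magnitude spectrum.
Default baseline amplitude 20 deg/s, in the range of moderate postural
tremor.  Accelerometer and compass channels are noise placeholders.

**Efficacy curve.**  A logistic in voltage (half-max 1 V, slope 4 /V)
rescaled so that efficacy(0 V) = 0 exactly and the asymptote stays 1.  The
rescaling matters: without it, zero stimulation would still suppress ~2% of
tremor amplitude and the stim-off tremor-power identity would not hold.
At the default therapeutic 2 V, efficacy ≈ 0.98.

**EMG (mV, 500 Hz).**  Baseline noise (0.02 mV RMS) plus a broadband burst
(0.5 mV RMS) gated by overt movement.

**Dynamics.**  All state transitions (movement onset/offset, tremor
growth/decay) are first-order exponentials with 0.5 s time constants,
implemented as one-pole filters with state carried across simulation
chunks so closed-loop (tick-by-tick) and scripted (segment-by-segment)
generation produce identical samples.

## Spectral features

* **Welch PSD**: Hann window, 1.0 s segments, 50% overlap (≈1 Hz bins at
  all supported rates), one-sided density, no detrending — so the integral
  over all bins approximates the signal mean-square (Parseval), which the
  tests check to 5%.
* **Bands** are half-open `[lo, hi)` in Hz with membership by bin center;
  this makes band power exactly additive over partitions.
* **Normalization** is a per-bin z-score against training mean/sd; a
  zero-variance bin raises an error naming the bin.
* **Gyroscope magnitude spectrum**: Welch PSD per axis, then the per-bin
  Euclidean norm √(Px²+Py²+Pz²).
* **Peak tremor frequency**: the largest local maximum of the magnitude
  spectrum in 1.5–8.0 Hz; content below 1.5 Hz is ordinary voluntary
  movement and is excluded.  A peak must exceed 4× the median in-band
  level (noise-floor criterion); otherwise the result is an explicit
  "no tremor peak".  Ties resolve to the lower frequency.  Resolution
  coarser than 0.5 Hz is rejected.  The tremor band is peak ± 1 Hz,
  clipped to 1.5–8.0 Hz.
* **5 Hz band-power telemetry emulation**: causal 4th-order Butterworth
  band-pass → square → single-pole exponential smoother (default 0.5 s) →
  decimation to 5 Hz.  For a steady in-band tone of amplitude a the output
  settles at the tone power a²/2; a step is tracked to 90% within three
  smoothing time constants.  The real device's analog chain and scaling
  are proprietary, so only relative comparisons are meaningful.

## Movement decoders

**Distributed spectral decoder** (`SpectralMovementClassifier`): per-bin
weights `w = mean z(movement) − mean z(rest)` with pooled-training z
scoring (identity-covariance LDA); score = logistic(w·z + b) with slope
fixed at 1 in z units.  The bias anchors the *midpoint between the class
means* at score 0.5, so the default threshold θ = 0.5 is the balanced
decision point and lowering θ trades false positives for sensitivity.
(Anchoring 0.5 at the rest-class mean was considered and rejected: it
pins half of all rest windows above 0.5 by construction, making any
accuracy target at θ = 0.5 unreachable.)  Because beta power drops during
movement, beta-bin weights come out negative and desynchronized spectra
score high.  Two decoders are trained in parallel on stim-off and stim-on
calibration data; each is only consulted on data from its own regime (see
the controller's decision hold below).  Training requires ≥5 spectra per
class; the default training extraction takes 2 s windows stepped by 1 s,
skipping 1 s margins around prompt transitions.

**Embedded two-band cascade** (`EmbeddedBandClassifier`): features are
log₁₀ band powers from the 5 Hz telemetry chain in a stimulation band
(stimulation frequency ± 5 Hz) and a beta band (12–28 Hz by default,
mirroring typical on-board settings; the distributed decoder uses 12–30).
Training uses exactly four ≥30 s state blocks (stim off/on × rest/
movement), discarding the first three smoothing time constants of each
feature stream.  The stimulation-state threshold is the midpoint of the
off/on class-mean log stimulation-band powers (a warning flag is set if
the means are separated by less than one pooled sd); the per-state beta
thresholds are rest/movement midpoints *raised* by the sensitivity bias
δ (default 0.25 log₁₀ units, a free parameter), so low-beta (movement) is
called more readily — deliberately favoring stimulation over power
savings.  Inference is a cascade: stimulation band → inferred state →
that state's beta threshold → movement.  A single linear function of both
bands would be an alternative realization; the cascade is the minimal
structure consistent with per-state thresholds.

**Peripheral trigger**: rectified moving-average envelope (default 0.25 s
window) with a fixed threshold and hold-time hysteresis (the detector
releases only after the envelope stays at/below threshold for `hold_s`).

## Stimulation controller

Four-state automaton: OFF →(one movement call)→ RAMP_UP →(amplitude
reaches V_max)→ ON →(K consecutive rest calls, default K = 3)→ RAMP_DOWN
→(amplitude reaches V_min)→ OFF, with re-triggering from RAMP_DOWN on a
movement call.  The asymmetry — single-call trigger, K-call release — is
the "tuned for sensitivity" preference: missing movement is worse than
stimulating at rest.  Amplitude moves by at most `ramp_rate × tick` per
tick (default 2 V/s, i.e. 1 s for the 0→2 V traverse — fast but
slew-limited, as paresthesia limits how quickly patients tolerate ramping),
with snapping within 1e-9 V so an exact N-step traverse lands on the
target.  V_min is configurable (default 0) so the same machine can express
high/low graded switching.

Timing: distributed mode quantizes decisions to the 400 ms packet grid and
delays commands by 400 ms transport, giving a biomarker-to-response
latency bounded by 800 ms; embedded mode ticks at the 5 Hz band-power rate
with no transport delay; peripheral mode uses the distributed timing.

**Decision hold during regime transitions (distributed mode).**  The
classifier tag follows the machine state (off-decoder in OFF/RAMP_DOWN,
on-decoder in RAMP_UP/ON), but the 2 s trailing spectral buffer follows
the *applied* amplitude, which lags the state by the transport delay and
the ramp.  A spectrum whose window spans an amplitude change — or that was
recorded entirely in the other regime — matches neither decoder's training
distribution; in particular, the artifact bins of the off-decoder have
near-zero training variance, so stim-contaminated buffers produce
saturated, essentially random scores.  Without protection this causes a
permanent ON ↔ RAMP_DOWN ↔ RAMP_UP oscillation (the off-decoder,
consulted at the start of RAMP_DOWN on still-stimulated data, immediately
re-triggers).  The controller therefore issues a fresh decision only when
the applied amplitude over the whole buffer matches the active decoder's
regime (V_min everywhere for the off-decoder, V_max everywhere for the
on-decoder) and otherwise holds its previous call — the triggering
movement call persists through RAMP_UP, and the rest run that initiated
RAMP_DOWN persists through the descent.  Embedded mode needs no hold: its
stimulation-band feature tracks the amplitude itself and the per-state
thresholds remain meaningful at intermediate amplitudes.

## Therapy evaluation

* **Tremor severity** = (tremor-band power)² / (total power), both
  integrated from the gyroscope magnitude spectrum per sliding window
  (default 2 s windows, 1 s hop).  Squaring the band power emphasizes
  windows where the tremor rhythm dominates; dividing by total power
  discounts windows dominated by broadband voluntary movement.  Windows
  with total power below 1e-10 (deg/s)² score 0.  The quantity is
  unit-bearing ((deg/s)² at the default exponent), so only within-pipeline
  comparisons are meaningful; `severity_exponent = 1` gives the plain,
  dimensionless band-power fraction as an alternative.
* **TEED** = Σ over constant-amplitude segments of V²·(f·p/z)·Δt, in
  joules for SI inputs (150 Hz, 90 µs, 1200 Ω defaults).  The primary
  exported quantity is the unit-invariant ratio against always-on
  stimulation at V_max over the same interval; per-second energies over
  movement and rest time are also reported.
* **Detection metrics** are computed by exact interval overlap between the
  applied-amplitude step function and the schedule: sensitivity = % of
  movement time at or above the effective level (default: 100% of V_max,
  configurable for a clinically-effective-level variant), false-positive
  rate = the same over rest time, any-stimulation fractions analogously,
  and one onset-to-effective-level latency per movement event (searched
  until the next onset; events never reaching the level are flagged, not
  averaged in).  Imagined-movement prompts carry no overt movement and
  count as rest.

## Study conditions used by the tests and the acceptance script

Calibration sessions: 120 s, 5 prompts of 8–12 s.  Closed-loop evaluation
sessions: 480 s, 10 prompts of 15–25 s (hold-posture prompts of tens of
seconds, interleaved with rest gaps averaging ~25 s).  The rest gaps must
comfortably exceed the loop's intrinsic turn-off lag (rest detection + K
ticks of hysteresis + ramp-down, ~4 s); with much shorter gaps the
stimulator correctly never shuts off between prompts and rest-time
metrics degenerate.  The acceptance script runs 5 sessions per mode; the
acceptance test suite runs 20.  These sizes keep the full suite under a
minute of closed-loop simulation while leaving the Monte-Carlo margins
comfortable.

## What passing tests do and do not show

The plant is a phenomenological, single-patient-like model: stationary 1/f
background, one tremor frequency, noiseless prompt adherence, an
idealized monotone efficacy curve, and an artifact model invented for lack
of published characterization.  Passing the suite demonstrates that the
decoding, control and evaluation machinery is correct and that the closed
loop behaves as designed *under these conditions*; it does not demonstrate
clinical performance.  Real cortical spectra are nonstationary across
sessions and electrode placements, real tremor is multi-component and
fluctuates, and real artifact structure depends on hardware — all reasons
the per-patient calibration workflow (montage selection, per-patient
training, threshold tuning) exists in practice and is mirrored here only
in simplified form.

## Known limitations

* No biophysical thalamocortical model; ERD depth, tremor amplitude and
  efficacy are free parameters, not fitted to any patient.
* The severity statistic is unit-bearing at its default exponent; absolute
  values are not comparable across window lengths or units conventions.
* The embedded decoder's high false-positive rate is inherent to its
  deliberate stimulation-on bias, not a defect the suite tries to remove.
* The graded (amplitude-banded) control strategy and frequency/pulse-width
  adaptation are out of scope; V_min > 0 merely leaves room for the
  high/low variant.
* Accelerometer/compass channels are placeholders; artifact rejection
  beyond the regime-purity hold is not implemented.
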