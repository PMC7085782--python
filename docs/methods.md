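# Methods

This note records the models behind `atcfes`, the parameters that matter,
and the design decisions taken where more than one reasonable choice
existed. Nothing here states a number the test suite or
`scripts/acceptance.py` does not itself compute.

## Signal models

### sEMG surrogate

No physiological motor-unit model is used. The generator produces
amplitude-modulated band-limited Gaussian noise:

    v(t) = (n0 + g·a(t)) · w(t)

with `a(t)` the activation envelope in [0, 1] and `w` zero-mean,
unit-variance noise band-passed to 30–400 Hz (4th-order Butterworth,
re-normalized after filtering). This is the minimal model with the one
property the ATC feature relies on: the rate of threshold crossings grows
monotonically with signal amplitude, hence with activation. A property test
verifies that monotonicity by Monte-Carlo.

Defaults (electrode-referred): `g = 2 mV` RMS at full activation — raw
sEMG spans hundreds of µV to tens of mV peak — and `n0 = 20 µV` RMS
baseline. The baseline value matters: after the 1000× conditioning gain it
becomes 20 mV, the regime a ~30 mV comparator hysteresis is sized for. A
much smaller floor would leave the step-down threshold search without a
detectable baseline (the detector could never re-arm inside the hysteresis
band), which is not how a real front end behaves. Simulation rate is 2 kHz
(the analog chain is band-limited to 400 Hz; 2 kHz resolves the full band),
configurable.

What the surrogate does **not** model: motor-unit recruitment and firing
statistics, electrode-skin impedance, movement artifact, power-line
interference, fatigue. Passing tests therefore show that the *control
method* behaves as specified on signals with the assumed
amplitude-monotonicity, not that it is robust to every artifact of real
recordings.

### Conditioning chain

First-order high-pass at 30 Hz cascaded with a second-order low-pass at
400 Hz (digital Butterworth via bilinear design, standing in for the
analog RC + Sallen-Key stages), gain 1000. Filtering is **causal** —
the hardware runs in real time — so no zero-phase filtering anywhere in the
signal path. Tests check DC rejection, mid-band gain within 10 % of 1000
(against the designed response, tolerance covering corner roll-off) and
≥ 20 dB attenuation at 4 kHz.

### Event detection

Schmitt-trigger semantics: starting armed, an event fires at the first
sample ≥ threshold; the detector re-arms when a sample falls to
threshold − hysteresis (default 30 mV). Decisions taken where the hardware
description is silent:

- the hysteresis band extends **downward** from the threshold (trigger at
  T, re-arm at T − h), because calibration places T just above the rest
  baseline — a band extending upward would make the nominal threshold
  unreachable from baseline noise;
- only rising crossings count (the single-edge interrupt convention);
- timestamps are the crossing sample's time, no sub-sample interpolation.

### Goniometer model

Joint angle = AROM · smooth(activation), where smooth is a zero-phase
2nd-order low-pass at 3 Hz (human movement bandwidth), rescaled so the
configured peak is preserved; sampled at 80 Hz and quantized to the 12-bit
encoder grid (360°/4096 ≈ 0.088° per count). The encoder's separately
specified absolute accuracy is not modeled (quantization only). Zero-phase
smoothing is acceptable here because the angle generator is an *input*
generator, not part of the real-time path.

## ATC windowing

Half-open windows [t0 + k·w, t0 + (k+1)·w), w = 130 ms. The number of
windows over a span is `ceil((t1−t0)/w)`: the trailing partial window is
emitted. This choice makes count conservation exact (every event in
[t0, t1) falls in exactly one window — a hypothesis property test) and
reproduces the 180 s / 0.13 s ≃ 1385 window arithmetic. Rounding to the
nearest window count instead would drop events in the tail whenever the
fractional part is below one half, breaking conservation.

## Controller

- **LUT fill**: linear ramp from 0 to I_max across indices gate…ATC_max.
  Only the endpoints are dictated by calibration ("step and range"); linear
  is the minimal assumption and user-supplied level vectors are accepted.
- **Noise gate**: indices 0 and 1 are forced to 0 mA.
- **Median of 4**: mean of the middle pair, rounded half-up (indices are
  integral), clamped to [0, ATC_max]; counts beyond ATC_max saturate at the
  top index.
- **Settling**: a sustained count step reaches the middle-pair mean after
  two window updates and fully settles after three (when 3 of the 4 buffer
  entries carry the new value). This is an arithmetic property of the
  median of four, verified by test.
- **Pulse**: biphasic rectangular, +A for the phase width, 150 µs gap, −A
  for the phase width; frequency and width are session constants (defaults
  25 Hz, 300 µs, device-safe bounds enforced) — amplitude is the only
  run-time-modulated parameter.

## Calibration

- **Threshold**: step-down sweep (defaults: start 200 mV, step 5 mV) until
  the rest signal's TC rate first reaches 1 event per 130 ms window; the
  working threshold is that baseline + 30 mV. The criterion operationalizes
  "just above the baseline": one event per window is the smallest nonzero
  sustained activity the windowing can register.
- **ATC max**: median of per-repetition maxima, ≥ 4 repetitions enforced;
  an even count's median is rounded half-up to an integer.
- **AROM**: max − min of the angle recording; constant recordings are an
  error.
- **Current limit**: ascending grid (default 0.5 mA steps, 130 mA device
  ceiling) over the plant's *closed-form* steady-state map
  θ_ss(I) = AROM_plant · r(I); first grid current with Δθ ≥ 0.3·AROM, times
  1.1. The closed form is used rather than a finite simulation because any
  finite settle time undershoots the fixed point (at 5 time constants by
  0.7 %), which biases the grid search one step high precisely when a grid
  point sits exactly at the 30 % target; a test separately confirms the
  simulated step response converges to the same map.

## Plant (simulated stimulated limb)

Recruitment r(I): piecewise linear with a dead zone (default threshold
2 mA), slope 0.08 /mA and ceiling 0.85 — the ceiling below 1 reproduces the
clinical observation that the stimulated limb's peak excursion is smaller
than the voluntary one. Activation follows ȧ = (r(I) − a)/τ with τ = 0.25 s,
discretized *exactly* for piecewise-constant input (exponential update), so
the trajectory is dt-invariant at shared time points; the output angle
AROM · a is delayed by a pure 0.15 s electromechanical delay. No plant
parameters are measured quantities; they are simulation conventions chosen
to give physiologically plausible lags. Not modeled: Hill-type mechanics,
fatigue, joint inertia.

## Closed-loop session

A virtual clock advances one ATC window at a time; the per-window command
timestamp is window-end + 10 ms processing delay (total modeled latency
140 ms, asserted on log timestamps). The simulated limb is driven by
channel 0's amplitude under zero-order hold; multi-channel sessions log all
channels but the single-joint plant tracks the agonist channel.
Per-channel generator seeds derive from the master seed by a counter scheme
(`master·10007 + 101·stream + channel`, mod 2³¹−1), giving bitwise
reproducibility of the full session for a fixed seed.

Default session: 12 repetitions of 4 s separated by 3 s rest (87 s, 670
windows). The acceptance script's timing check runs 180 s. These sizes keep
the full suite and the acceptance run in seconds while exercising every
stage at the protocol's native rates.

## Similarity evaluation

Repetition boundaries are detected on the therapist trace (runs where the
deviation from the rest level exceeds 10 % of the range, padded by a 0.5 s
guard, clipped to midpoints so epochs never overlap; runs under 100 ms are
discarded as glitches) and the *same* sample windows are applied to the
patient trace — both limbs share the session timeline, and the guard
absorbs the stimulation lag. Baseline removal uses the mean of the first
0.25 s of each epoch; normalization divides by each subject's own AROM.
The correlation maximum is taken over the full lag range −(N−1)…N−1; the
shorter epoch is zero-padded *after* baseline removal so padding adds no
spurious correlation. The fast path (`numpy.correlate`) is tested against a
brute-force double loop to 1e−10.

With the default generator and plant tuning the simulated loop reaches
mean σ ≈ 0.97 over 12 repetitions (see `examples/05_closed_loop_session.py`
and the acceptance-property test asserting σ ≥ 0.8). In-vivo similarity is
lower and subject-dependent; the simulation shares the method, not the
variability of human muscle.

## Known limitations

- The surrogate's TC statistics are those of Gaussian noise; real sEMG is
  spiky and non-stationary, so calibrated ATC_max values here should not be
  read as physiological.
- One plant joint per session; antagonist co-stimulation is not simulated.
- The stimulator wire protocol is out of scope; commands are logged as CSV
  and a simplified line-protocol text form.
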