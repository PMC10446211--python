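# Methods

## Scope and model

`delaypop` analyzes stimulus encoding in converging sensory populations
when spike arrival times are spread by axonal conduction delays.  All
information estimates are linear lower bounds obtained from the
stimulus–response coherence; all population responses are plain
averages of member firing rates (the simplest readout — no weighting,
no explicit integrator dynamics).

### Firing rates and response moments

Single-trial firing rates are estimated by convolving the spike train
with a unit-mass Gaussian kernel (σ = 1 ms for recorded-style data,
1.25 ms for model populations) sampled on a 20 kHz grid.  The
convolution is zero-padded, so a spike closer than ~5σ to an edge
loses part of its kernel mass; rate integrals therefore match spike
counts only away from the edges (checked to ±0.5 %).  All standard
deviations (CV_ISI, response modulation σ_mod, across-trial
variability σ_psth) are population moments (divide by n), since the
defining time- and trial-averages are plain means.

### Vector strength and phases

Spike phases are measured per carrier cycle: the phase of a spike is
2π times its latency after the preceding cycle onset divided by that
cycle's period.  For synthetic sinusoidal carriers the onsets are
rising zero crossings; for recorded non-sinusoidal carrier shapes a
rising half-maximum crossing detector is provided.  Vector strength is
the resultant length of the unit phase vectors divided by the spike
count (the bare vector sum is not bounded by one; normalization by n
gives the conventional [0, 1] range where 1 means perfect locking).

### Spectral estimation

Spectra are Welch estimates: segments of about one second (2¹⁵ samples
at 40 kHz; the nearest power of two at other rates), 50 % overlap,
Hann window, per-segment mean subtraction.  Segments from all trials
are pooled into a single average, so cross-spectra vanish only to the
level expected from the total segment count.  The cross-spectrum
follows the conj(X)·Y convention: a response lagging the stimulus by d
has transfer-function phase −2π f d.  The coherence is clipped at
1 − 10⁻¹² before the −log₂(1 − γ²) integrand, which is integrated by
trapezoid on the native Welch grid with linearly interpolated band
edges.  Band-limited stimuli are integrated over the stimulated band
only.

Welch coherence carries a positive small-sample bias of order
1/n_segments; no bias correction is applied (deliberately out of
scope), so very small information rates include an estimator floor of
roughly −Δf·log₂(1 − 1/n_segments).  Conclusions that compare
curves estimated with equal segment counts (population size sweeps,
delay grids) are insensitive to this common offset; absolute
single-cell MI values at small segment counts are not.

Cutoff frequencies scan outward from the curve's peak to the first
crossing of max/√2 (gain) or max/2 (coherence), linearly interpolated;
a curve that never falls below threshold reports the range edge with a
flag.  The half-maximum convention for coherence cutoffs is a package
choice isolated behind the `mode` switch.

### Population assembly and delay injection

Homogeneous populations are unique random combinations of distinct
trials of one cell; heterogeneous populations take at most one trial
per cell.  Heterogeneous members are first aligned to the stimulus by
subtracting their cell's STA delay (the lag of the spike-triggered
average's peak); trials of a single cell share one delay, so alignment
of homogeneous populations is a no-op.  Conduction delays are mimicked
by one zero-mean Gaussian draw (sd σ_delay) per member applied rigidly
to all of that member's spikes — jitter within a train is never
altered.  Draws are clipped at ±4σ to bound spike loss at the trace
edges; spikes shifted outside the recording are dropped.

In the σ_delay × σ_kernel filter grid the synaptic low-pass proxy is
implemented by widening the rate-estimation kernel itself rather than
by an extra convolution, so the stated σ_kernel is the actual Gaussian
width applied.  Because coherence is invariant under linear filtering
of the response, kernel widening reduces MI only through numerical
floors, whereas delay spread genuinely decorrelates members — the grid
therefore shows a much steeper drop along the delay axis, matching the
physiological argument that delay spread is more destructive than
synaptic filtering.  The same population memberships are reused at
every grid point so that the grid isolates filtering effects from
membership sampling noise.

### LIF population simulator

The membrane model is the dimensionless LIF
τ_m dV/dt = −V + I_offset + I_stim + √(2D) ξ(t) with
Euler–Maruyama steps V ← V + (Δt/τ_m)(−V + I) + (√(2D·Δt)/τ_m)·N(0,1),
threshold θ, reset V_reset, and spike times recorded at the crossing
step (no sub-step interpolation; Δt = 0.01 ms makes the bias far below
the kernel width).  Defaults: τ_m 0.25 ms, I_offset 2.5, 2D = 5, θ = 1,
V_reset 0, Δt 0.01 ms — verified against two closed forms: the
noise-free ISI −τ_m ln(1 − θ/I) and the threshold-free
Ornstein–Uhlenbeck variance D/τ_m (in the model's millisecond units).
The integrator is a numba-jitted loop; per-neuron seeds are spawned
from one seed sequence.

Populations are uniform 1-D arrays (density 2000 m⁻¹ by default) whose
axons converge on one target, so arrival times grow monotonically
along the array; delays are referenced to the population center (near
end leads, far end lags).  Only the delay spread
(n − 1)/(density·velocity) affects the stimulus–response coherence — a
common offset shifts phases only.  Every neuron receives the identical
frozen band-limited noise stimulus plus independent intrinsic noise;
the population response is the average 1.25 ms-kernel rate of the
delayed trains.

For the MI-vs-size sweep, `max(sizes)` neurons are simulated once per
trial and each (velocity, size) condition reuses those trains with its
own delay pattern — exact up to rate-grid rounding, because a rigid
spike shift commutes with kernel rate estimation.  The average of the
population filter over the stimulated band has its first null near
n = 1/(f_band · Δ_delay); for 7 m/s, 2000 m⁻¹ and the 200–300 Hz band
this predicts the MI curve to fall back to the single-neuron level in
the mid-50s of neurons, which the simulation reproduces.  The
acceptance script estimates the crossing from 24 trials per sweep,
4096-sample segments and three independent sweep repetitions averaged
per size (sizes 1–72, denser around the crossing); these sizes keep
the whole computation in the low minutes on one core while the
remaining estimator noise moves the crossing by only a few neurons.

### Synthetic P-unit generator

The surrogate encoder reuses the LIF integrator with drive

    I(t) = bias + locking · max(0, sin(2π f_EOD t)) · (1 + g·AM(t)) − A(t)

where A(t) is a spike-triggered adaptation current (increment 0.05,
decay 30 ms).  Phase locking, cycle skipping, burstiness and
rate-coded AM responses emerge from this one mechanism.  Adaptation is
essential: without negative ISI correlations, per-cycle Bernoulli
firing forces CV_ISI ≈ √(1 − p), which cannot jointly reproduce the
empirical firing rates and CVs of P-units; spike-frequency adaptation
is a standard ingredient of published P-unit models.

Heterogeneity is drawn per cell: EOD frequency uniform in 611–875 Hz,
locking strength uniform in 1.7–3.4, bias log-uniform in 0.06–0.5,
noise intensity log-uniform in 0.08–0.22, AM gain uniform in 1.5–4.0,
receptor position uniform in 0.2–0.8 of a 0.15 m body.  These ranges
were calibrated once so that a generated population reproduces the
empirical summary bands of recorded P-units — baseline rate
≈ 290 ± 90 Hz spanning ~140–480 Hz, CV_ISI ≈ 0.6, vector strength
≈ 0.83, burst fraction ≈ 0.27, driven response modulation
≈ 140 ± 20 Hz at 10 % contrast — and are stored in a config dataclass
(`HeterogeneityRanges`), not hard-coded.  The distributional forms are
package choices; the empirical literature constrains only the summary
statistics.  Single-cell lower-bound MI of the surrogates comes out
higher than for real P-units (the surrogate is more linear than a real
electroreceptor); MI was deliberately not used as a calibration
target.

Each cell's spikes (baseline and driven) are shifted by its
ground-truth conduction delay position·body_length/velocity, so that
localization and velocity analyses can be validated in closed loop.
Frozen-noise contract: identical seeds reproduce bit-identical stimuli
and spike trains.

What the generator does **not** emulate: receptor-level biophysics,
dipole-field electrostatics, body-geometry changes of the carrier
waveform along the body, serial ISI correlations beyond one adaptation
timescale, and saturation nonlinearities of strongly driven afferents.
Passing tests on synthetic data therefore demonstrate correctness of
the analysis chain and recoverability of imposed ground truth, not
fidelity of any particular biological parameter.

### Localization and conduction velocity

Receptor positions are estimated from dipole scans: the Welch power of
the firing rate at the stimulation frequency (1 s segments, Hann, 50 %
overlap) versus dipole position is fitted with a four-parameter
Gaussian (center, width, amplitude, additive baseline — the
spontaneous-rate power floor), initialized at the scan argmax.  The
fitted center is intensity-invariant.

Preferred phases grow linearly with receptor distance and wrap at one
carrier cycle.  K-means (k = 2, 10 restarts, seeded) on per-axis
standardized (phase, position) points splits the cloud; the cluster
with the larger mean position is shifted by +2π when its mean phase
lies below the rostral cluster's — the signature of a wrap, since
phase must increase with distance.  A residual pass then fixes any
remaining *downward* jumps larger than π along the position-sorted
sequence (the intrinsic response phase can place two wrap points
inside the sampled range); upward jumps are left untouched because
sparsely sampled steep stretches produce genuine gaps.  The operation
is idempotent.  Absolute delays are phase/(2π f_EOD), per cell;
velocity is the inverse slope of the ordinary least-squares regression
of delay on position (a common latency offset is absorbed by the
intercept).  Velocity-recovery validation keeps the delay spread of a
study within about 1.5 carrier cycles (position span scaled with the
ground-truth velocity) and collapses the per-study EOD band: with
several-cycle spreads and strongly heterogeneous carrier frequencies a
single 2π split is ill-posed for any method of this family.

## Numerical and design notes

- Spike times are kept as continuous seconds; rate estimation bins
  them at the rate grid (50 µs default), the only discretization in
  the analysis chain.
- All randomness flows through `numpy.random.SeedSequence` spawning;
  identical configs reproduce identical outputs byte for byte.
- Degenerate inputs are first-class: empty trains give zero rates,
  flat scans and non-convergent fits raise a localization error with
  diagnostics, zero-variance features are flagged in correlation
  tables, zero stimulus power masks the transfer function.
- The CLI (`delaypop synth/characterize/velocity/popinfo/lifsweep/
  report`) validates config keys by name and writes a manifest
  (package version, config echo and hash) next to every output.
- Reading the deposited NIX archive of the original recordings is an
  optional adapter (`delaypop.nix_adapter`) that converts to the
  package's plain-text study layout; the core package never imports
  nixio.

## Known limitations

- The coherence lower bound ignores information in nonlinear response
  components; all heterogeneity-benefit statements concern linear
  decoding.
- Welch coherence bias is uncorrected (see above); absolute MI values
  at small segment counts carry a positive floor.
- The surrogate P-unit is not a biophysical receptor model; its MI
  scale exceeds that of real afferents.
- Homogeneous populations are limited by the recorded/generated trial
  count, exactly as in experiments.
- The delay-injection model treats members as independent; correlated
  noise across afferents and weighted readouts are out of scope.
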