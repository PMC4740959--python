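# Methods

## Reservoir model

The simulator implements a leaky echo state network whose recurrent layer
is one of five fixed interconnects: one-way ring, two-way ring, center
(hub only), hybrid (ring + hub), and dense random with Bernoulli-masked
connectivity. The hybrid update is

    Xc[n]  = W_up · X[n-1]
    X~[n]  = f( W_in u[n] + W_down Xc[n] + W_ring X[n-1]⟲ )
    X[n]   = α X~[n] + (1-α) X[n-1]

with `⟲` the one-step ring rotation: neuron *s* receives from *s−1*
(mod N), i.e. a left rotation of the state vector. The hub neuron is
linear (no activation) and is excluded from the readout. The initial
state is zero and the washout default is zero; both are exposed. The
leak convention keeps a fraction 1−α of the previous state, the standard
leaky-integrator form, so α = 1 is memoryless.

Only the readout is trained, by ridge-regularised normal equations
`W_out = (Y Xᵀ)(X Xᵀ + λI)⁻¹`, solved with a symmetric linear solver
rather than explicit inversion. λ defaults to 1e−8 for conditioning;
λ = 0 is honoured exactly and raises a diagnostic advising λ > 0 if the
Gram matrix is singular.

Two decision protocols: a per-time-step threshold (default 0.5, the
midpoint of {0,1} targets) on a single output for binary streams, with
accuracy the fraction of correct time steps; and per-segment
winner-take-all over time-averaged outputs for multi-class segments,
with ties broken toward the lowest class index and accuracy the fraction
of correct segments.

### Graph metrics

Diameter and mean distance are computed over ordered pairs of distinct
reservoir neurons; paths may route through the hub but the hub is not an
endpoint (the diameter-2 property concerns reservoir-to-reservoir
communication). Disconnected graphs report an infinite sentinel rather
than raising. For a directed one-way ring the ordered-pair mean distance
is N/2, which is what the implementation computes and tests; a commonly
quoted 2N/3 figure corresponds to a different averaging convention and
is deliberately not reproduced.

Per-neuron synapse bookkeeping counts the links a neuron owns: input +
ring for the one-way ring (2), plus the up and down hub couplings for
the hybrid (4). The physical-layout report maps a hybrid reservoir onto
a doubly twisted torus in row-major ring order, eight labelled links per
node of which four are incoming; it is descriptive only — no placement
optimisation is attempted.

## Digital datapath emulation

The digital model reproduces the RTL arithmetic rather than idealising
it: values live on a Q(int.frac) two's-complement grid (default
Q(10.20); the format is configurable since some builds use more
fractional bits), every multiplier and adder output is re-quantised,
rounding truncates toward −∞ (dropping low bits in two's complement) and
overflow saturates. The activation is a five-band piecewise-linear tanh
keyed on |x| against breakpoints 0.5 and 1.5 with slopes 1 and 1/2 —
powers of two so hardware shifts replace multipliers. Its worst-case
deviation from exact tanh is 1 − tanh(1.5) ≈ 0.0949 at ±1.5, which the
test suite verifies by dense-grid search. The leak is fixed at α = 0.5
(add then one-bit right shift), and inter-neuron values are registered:
each neuron reads its neighbours' previous-step outputs, so the digital
trajectory converges to the ideal α = 0.5 / PWL-tanh trajectory as the
fraction width grows (verified at 52 bits to 1e−9). Weights are
quantised once at load time.

## Analog device models

All analog blocks are closed-form subthreshold expressions evaluated
numerically; no transistor-level transient simulation is performed.

* **Neuron**: `i_x = I_max tanh(i_s R_in / (2 n V_T))`, the differential
  pair transfer in weak inversion. Defaults: I_max = 1 nA, V_T = 26 mV,
  n = 1.2, V_DD = 0.55 V.
* **Mismatch synapse**: each current mirror's gain error is
  `exp(ΔVth/(n V_T))` with ΔVth ~ N(0, A_Vth²/(W·L)) (Pelgrom scaling,
  A_Vth = 4 mV·µm for the 45 nm process assumed). Weight magnitudes are
  therefore lognormal with σ_ln = A_Vth/(√(W·L)·n·V_T) ≈ 2.85 at minimal
  45 nm sizing; the variance formula carries the (n·V_T)² divisor
  required for consistency with the mirror-gain exponent. Signs are
  assigned ±1 with probability 1/2 (random polarity wiring). The
  synapse output is `i_s = w2 I_max − w1 ix⁻`, algebraically equal to
  `(ix⁺ − ix⁻)·w1/2 + I_max·b` with bias b = w2 − w1/2 under the
  complementarity constraint ix⁺ + ix⁻ = I_max, which is enforced at
  1e−6·I_max.
* **Cost models**: neuron area 5·A_match and power I_max·V_DD; mismatch
  synapse area A_match(2+4a) (max 6·A_match at a = 1) and power
  V_DD·I_max(2η + η·w1 + w2 + 2) with activity factor η = 0.5; readout
  area (N·M+9)·A_match and power ηNM·I_max·V_DD + 2M·I_bias·V_DD.
  A_match = 20250 nm² (10× minimal 45 nm sizing, keeping the threshold
  spread below 5%). The baseline deterministic synapse's expected area
  is 2·A_match·E[k/gcd(1/w_res, k)] over the discrete weight grid,
  evaluated exactly for the uniform grid and by truncated probability
  mass (99.99% quantile) for normal/lognormal grids.

Power totals evaluate synapse terms either at the lognormal medians
(w1 = w2 = nominal ratio; the default, giving exactly affine-in-N totals
for ring/hybrid and quadratic for 50%-dense random reservoirs) or per
Monte Carlo sample to expose the mismatch-induced spread. The random
topology's synapse count uses the expected value `connectivity·N²`. A
published end-to-end mixed-signal power figure for a 30-neuron build is
not reconstructable from these block formulas without knowing the weight
statistics behind it, so the report prints both modes instead of
matching a single number.

## Memristor readout

The device model is tunnelling-dominated: current
`(1−γ+gγ)·G_moff·ξ1·sinh(v·ξ1)` with separate ξ parameters per voltage
polarity, state velocity a sinh of the over-threshold drive gated by a
boundary window that pins γ ∈ [0,1], integrated by forward Euler with
configurable dt. The prefactor symbol g is interpreted as the on/off
conductance ratio (boundary interpolation between off and on
conductance). **The ξ defaults are synthetic placeholders** chosen for
smooth monotone switching; no fit to laboratory I–V data is claimed.

Crossbar columns pair an excitatory and an inhibitory device:
`w = R(G⁺−G⁻)/(G⁺+G⁻)`, so |w| < R always and the readout is exactly
linear in the input currents. Training is stochastically gated,
sign-based supra-threshold pulsing: per presented sample, the sign of
error × state selects the row to potentiate, and the pulse fires with
probability ∝ |error × state| (clipped to 1); all conductance change
flows through the Euler device update. This rule is this module's
documented contract, validated by its convergence property on separable
data, not by equivalence to any externally defined algorithm. A known
limitation: because both rows only potentiate, prolonged training
saturates both devices and the differential weight decays — training
should stop once the error is small (the tests use 10 epochs), or
devices be re-initialised near the off state before training.

## Reservoir-quality metrics

Kernel quality is the numerical rank of the state matrix across input
cases (singular values above tol·σ_max, with tol the standard
machine-epsilon rule scaled by the larger dimension). The
Lyapunov-style exponent is `k·Σ_j ln(‖x_j−x̂_j‖/‖u_j−û_j‖)` with k = 1 by
default, Euclidean norms, nearest neighbours found among the inputs
excluding self with ties to the lowest index, and exact duplicate inputs
rejected with their indices (the ratio is undefined). One scalar is
returned per evaluation set.

## Synthetic data

The generators emulate the *shape* of the two benchmark corpora, not
their physiology:

* EEG-like (defaults 173.61 Hz, 23.6 s, single channel): class 0 is
  pink noise plus a moderate 8–12 Hz oscillation; class 1 adds ~3 Hz
  sinusoidal bursts of 5× background amplitude recurring every 1 s with
  90% duty cycle, so the abnormal activity spans the segment the way
  ictal activity does while still arriving in discrete bursts.
* EMG-like (defaults 4 kHz, 20 s, 8 channels, 5 classes): each class is
  a fixed random per-channel gain profile (contrast 4×) applied to
  20–450 Hz brick-wall band-limited noise under a slow 0.3–0.8 Hz
  contraction wobble, scaled with 4σ headroom and quantised to the
  signed 12-bit ADC range. A 2 Hz inner margin keeps modulation
  sidebands inside the band.

Both are fully determined by their seed. The classes are deliberately
easier than real recordings — there is no volume conduction, electrode
noise or motor-unit structure — so passing accuracy gates demonstrates
pipeline correctness, not clinical performance. Segment splitting cuts
non-overlapping parts and discards sub-part tails (20 s at 4 s parts
gives exactly 5); the train/test split is seeded and stratified.

Both classification pipelines front-end the signal with rectified
amplitudes normalised by the training-split maximum (|x|/max), the
standard envelope representation for seizure energy and muscle
activity; for the zero-mean EMG-like noise this is essential, since an
odd-symmetric tanh reservoir averages raw amplitude information away.

## Problem sizes and evaluation protocol

The held-out accuracy gates run at reduced dataset sizes chosen as the
package's own test protocol: EEG-like, 28 segments per class at the full
23.6 s/173.61 Hz shape (20 train / 8 test), hybrid N = 100, α = 0.5,
washout 50 steps, uniform weights on [−0.5, 0.5]; EMG-like, 6 segments
per class at 1 kHz (the 20–450 Hz band fits comfortably under the
Nyquist limit), split into 4 s parts, 25 train / 5 test parts per class,
hybrid N = 100. The washout and the reduced weight scale stabilise the
per-time-step protocol against the startup transient and keep held-out
accuracy comfortably above the 90%/80% gates across seeds. The
experiment driver derives every stage's seed from one global seed plus
fixed per-stage offsets, and its manifest is byte-identical across
repeated runs of the same configuration.

## Known limitations

* No spectral-radius tuning, online learning, or
  backpropagation-through-time; the readout is batch least squares.
* The digital model covers datapath arithmetic, not timing, resource or
  clock-rate estimation.
* Analog models ignore short-channel effects, temperature, wire
  parasitics and sneak paths; memristor parameters are placeholders.
* The synthetic tasks bound what the accuracy gates can show about real
  EEG/EMG performance (see above).
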