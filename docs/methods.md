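# Methods

This note records the modeling conventions, numerical choices and design
decisions behind `snnkit`, and what the synthetic benchmarks do and do
not demonstrate.

## Modeling conventions

Every signal is a dense array `[batch, time, components]`; a single
time-slice drops the time axis. Spike signals are strictly {0, 1}-valued.
The library attributes **no physical units** to any quantity — the user
owns unit consistency. Documentation examples use milliseconds for `dt`
and the time constants, and Hz for encoder rates; the rate encoder is the
single place where that convention is baked in (per-step spike
probability `rate[Hz] · dt[ms] · 10⁻³`).

State is double precision by default; `init(..., single_precision=True)`
switches the engine to float32 for training throughput.

One seeded random source is threaded through the package. Substreams are
derived from `(seed, purpose, group id, …)` via stable CRC32 hashing, so
adding a monitor, reordering unrelated groups, or drawing extra trial
seeds never perturbs any other stream.

## Neuron and synapse updates

The LIF and LI updates are the exact solutions of the leaky ODE sampled
on the clock grid (`exp(−dt/τ)` cached by `time_dep`). Three choices fix
the discrete semantics:

- **Threshold comparison is `u ≥ Θ`** — equality spikes.
- **Spike detection happens after integrating the current step's input**;
  the reset applies to the state carried into the next step.
- **The refractory gate multiplies only the input term** — the membrane
  keeps decaying during the refractory window. The gate reopens once the
  time since the last spike reaches ρ, so with dt = 1 and ρ = 5 the five
  steps after a spike integrate nothing and the minimum inter-spike
  interval is 6 steps.

Synaptic groups compute their output from the **pre-update** current
(the printed-equation ordering), so a spike arriving at a synapse
influences its target one engine step after arrival. This is the single,
documented semantics; a same-step alternative is deliberately not
offered. Synaptic state is dense `[N_src, N_tgt]` even for pruned
(zero-weight) pairs, which keeps vectorization trivial at the intended
scales (≤ ~16k synapses per group).

The Izhikevich model is integrated by `k = ceil(1/h)` forward-Euler
substeps of the canonical right-hand side `0.04v² + 5v + 140 − u + S`
(the adimensional substep `h` drives numerical stability). The equations
carry their own millisecond timescale and contain no `dt`: one engine
step advances the model by one model-time unit, and using a different
`dt` requires the user to rescale. Refractoriness is intrinsic to the
dynamics; the generic refractory wrapper can still impose an explicit ρ.

Output delays discretize to `round(δ/dt)` engine steps (ties to even);
sub-`dt` delays round to zero with a warning.

## Stack ordering

For every candidate ordering of the groups, a delay-substituted directed
adjacency matrix is built (entry `[r, c]` = delay of the connection from
position r to position c; non-connections = `−ε` with
`ε = 10⁻⁹ · dt`). The ordering minimizing the lower-triangular sum is
selected; enumeration is exhaustive up to 8 groups (40 320 orders,
negligible cost) and lexicographic in the order groups were added, with
the earliest minimum winning. Beyond 8 groups an explicit
`heuristic=True` flag enables a greedy fallback (drop maximal-delay
back-edges until acyclic, then topologically sort).

Orderings are never rejected, only ranked: a zero-delay connection may
land in the lower triangle, where it acquires one engine step of
implicit latency (logged as a warning). A consequence worth spelling out
is that the minimizer *prefers* cutting a cycle at a zero-delay
connection — that costs only the ε bookkeeping term, strictly less than
any positive delay. Whether back-latency should instead be charged
against the declared connection delay is ambiguous in the lower-
triangular-sum objective itself; this implementation applies the
objective literally and documents the ambiguity. For any feedforward
network the result is a plain topological order with a connection-free
lower triangle.

Buffer planning assigns one temporary-storage slot per group and aliases
every reader onto its source's slot. During a step, readers placed after
their writer see the value written in the same step; feedback readers
(writer later in the stack) see the previous step's value, and zeros on
the first step. This is the defined recurrence semantics, verified
against a naive per-edge-mailbox simulator.

## Training

Backpropagation-through-time runs over the full sequence (no truncation;
task sequences are ≤ a few hundred steps). The forward pass is the plain
engine simulation, so training-time inference is bitwise identical to
deployment inference. Backward rules are implemented per model as
reverse-mode adjoint recursions through the time-steps and the stack
(including one-step-delayed adjoint routing across feedback reads).

- Spike nonlinearities use the normalized fast-sigmoid pseudo-derivative
  `g(u) = 1/(1 + β|u − Θ|)²` with default slope β = 10 (peak 1 at
  threshold, 1/4 at Θ ± 1/β); β is recorded in the training history
  metadata.
- Membrane resets and refractory gates are treated as non-differentiable
  (detached), the standard convention in surrogate-gradient SNN training.
- The readout takes the **maximum over time** of each output neuron's
  membrane (a non-spiking LI group is required), into a softmax
  log-likelihood loss. ADAM uses the canonical 0.9/0.999/1e-8 defaults
  and learning rate 10⁻³ unless configured otherwise.
- The trainer supports the input/LIF/LI/Izhikevich neuron models and
  1st/2nd-order synapse groups with zero group delay; delay- or
  refractory-wrapped groups are inference-only and rejected at pairing.

On a path free of spiking nonlinearities (readout-only training) the
gradient is exact and agrees with central finite differences to ~10⁻⁷
relative error; through spiking layers the surrogate gradient is a
biased descent signal by construction, validated by loss decrease on
separable tasks.

Trained weights are owned by the `TrainableModel` (model objects are
rebuilt from the network spec whenever the batch size changes, so
weights living only on model instances would not survive re-batching).

## Encoders and synthetic data

The rate encoder maps intensities in [0, 1] to rates that are zero at or
below a threshold fraction (default 20%) of the dynamic range and linear
up to `f_max` (default 500 Hz) at full intensity; spikes are drawn as a
per-step Bernoulli process (Poisson-like), with a deterministic
evenly-spaced mode behind the `regular` flag. Temporal upscaling uses
per-channel cubic splines (exact at the endpoints; traces shorter than 4
samples fall back to linear with a warning).

Delta modulation is implemented in two explicit interpretations, chosen
to reproduce the channel arithmetic of practical multi-bit encoder
circuits without claiming any specific circuit: **bipolar** (per-channel
accumulator initialized at the first sample; UP/DOWN spikes on ±delta
crossings; 2C output channels) and **thermometer** (k graded channels
per input channel, channel m firing when the per-step change magnitude
reaches m·delta; kC channels). Both are invariant to a constant signal
offset.

Two generators emulate the *structure* of the experimental data the
toolkit targets, not their statistics: `gen_rate_classes` (class
identity in disjoint high-rate channel blocks — decodable by
construction) and `gen_sensor_sweep` (smooth class-dependent spatial
bumps traversing a sensor array, destined for the spline + delta
pipeline). Passing tests on these shows the machinery is correct and
that the training loop can exploit rate structure; it says nothing about
accuracy on real speech, tactile or biosignal recordings, which carry
noise, class overlap and temporal variability these generators omit.

## Reference architectures and the desk-scale benchmark

`build_lsm` assembles the liquid-state-machine reference: a pass-through
input layer, recurrent LIF reservoir, LI readout, with dense synapse
groups whose derived sizes at the reference scale (50/125/10 neurons)
are 6 250 / 15 625 / 1 250 components, exactly 200 non-zero
input-to-reservoir weights and ~2 300 non-zero recurrent weights, and
neuron/synapse time constants of 64 ms / 8 ms. The wiring recipe beyond
those counts is not fixed by the reference material, so it is a
configurable default: uniform random support, 80% of reservoir neurons
excitatory (sign set per source neuron), uniform weight magnitudes with
scales (0.05 input, 0.02 recurrent) chosen once so that rate-coded input
drives the reservoir at a moderate ~50–60 Hz mean rate — neither silent
nor saturated. Readout weights start small and positive so output
membranes rise and peak late, keeping the max-over-time credit
assignment deep in time (a symmetric init can trap a class logit at an
early-time peak where almost no gradient flows).

The desk-scale benchmark (`snnkit.tasks`) trains a 20-input /
60-reservoir / 3-output LSM for 30 epochs (batch 16, learning rate
5·10⁻³) on the three-class synthetic rate task, T = 100 steps — sizes
chosen so a full run takes tens of seconds on one CPU while exercising
every stage the full-scale tasks use.

## Hardware non-ideality analysis

Quantization snaps weights to `n` equidistant, symmetric, signed levels
spanning `[−max|w|, +max|w|]` per group (a global range option exists
for hardware realism), then adds Gaussian write noise with
`σ = Δ/6` — adjacent level distributions cross at 3σ, so the mass read
past the crossing point is `2Φ(−3) ≈ 0.27%`, the ~0.3% overlap
characteristic of measured memristive conductance distributions.
Noiseless quantization is idempotent and scale-equivariant when the
range is data-derived.

Drift applies `|w|(t) = |w₀| · (t/t₀)^(−ν)` with per-weight exponents
`ν ~ Normal(ν̄, σ_ν)` truncated at zero, signs preserved. This is an
explicitly parameterized stand-in for device-specific drift compact
models, not a fit to any particular device. Drift sweeps start from the
unquantized trained weights (write-verify storage assumed).

Known desk-scale limitation: the synthetic rate task is separable enough
that the trained readout often survives even 1-bit weight storage (the
sign pattern alone classifies), so the quantization sweep verifies the
guaranteed properties — high-bit convergence to the full-precision
accuracy, monotone non-degradation within trial error, exact equality at
the drift reference time — rather than the full degradation-to-chance
curve, which emerges only on harder many-class tasks (and does appear
for some seeds). Absolute accuracy-versus-bits values for real datasets
are out of scope.

## Degenerate inputs and tie-breaks

- All-zero weight matrices make quantization a warned no-op (the level
  range is undefined).
- Equal 2nd-order time constants collapse the synaptic kernel to zero;
  the model permits but does not recommend them.
- Max-over-time readout ties resolve to the earliest step (argmax
  convention); gradient flows only to the selected step.
- Stack-order ties resolve to the earliest permutation in the order
  groups were added.
- `ε = 10⁻⁹·dt` keeps any sum of ε terms below every representable
  delay difference at double precision for networks up to ~10³ groups.
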