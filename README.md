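# snnkit

Compact-model **spiking neural network (SNN) simulation** for prototyping
hardware neuromorphic systems.

Designers of memristive or CMOS neuromorphic circuits need to answer
questions like *"will this reservoir architecture still classify once the
weights live on 3-bit devices that drift?"* long before silicon exists.
`snnkit` targets exactly that workflow: networks are assembled from
*groups* — sets of components (neurons or synapses) sharing one
time-discrete compact model — simulated by a fixed-time-step clock-driven
engine, trained off-line with surrogate-gradient backpropagation-through-
time, and then stress-tested against hardware non-idealities (weight
quantization with stochastic write error, power-law conductance drift).

## Models

All state is vectorized over `[batch, time, components]`; quantities are
unitless (examples use the ms/mV convention). Each model implements three
methods: `time_dep(dt)` (pre-computes dt-dependent constants),
`set_initial_state(batch)`, and `advance_timestep(input) -> output`.

**Leaky synapse (1st order)** — per presynaptic spike δᵢ(t), weight wᵢⱼ
feeds an exponentially decaying current, and the group output integrates
it over the time-step:

    Iᵢⱼ(t+dt) = Iᵢⱼ(t) · exp(−dt/τ_α) + wᵢⱼ · δᵢ(t)
    Oⱼ(t)     = φ · Σᵢ Iᵢⱼ(t) · τ_α (1 − exp(−dt/τ_α))

A 2nd-order variant tracks separate positive/negative branches (τ_α⁺,
τ_α⁻), producing a double-exponential kernel. Synaptic groups are dense
(fully connected); pruning is a zero weight. Output delays and
refractoriness are composable wrappers.

**Leaky integrate-and-fire (LIF) neuron** —

    u(t+dt) = u(t) · exp(−dt/τ_β) + Π(t) · S(t)
    O(t)    = 1 if u ≥ Θ else 0;  on spike: u ← u_r, Π ← 0 for time ρ

The gate Π suppresses input integration during the refractory period.
The non-spiking **LI** variant (no threshold/reset) serves as analog
readout. An **Izhikevich** model (forward-Euler with stability substep
`h`, `k = ceil(1/h)`) covers rich nonlinear firing patterns.

**Execution stack** — arbitrary (including recurrent) topologies are
linearized by minimizing the lower-triangular sum (LTS) of the
delay-substituted directed adjacency matrix over group orderings;
feedback connections then read the previous engine step's output through
a pre-allocated temporary-storage buffer whose reader addresses alias the
writer slots.

**Training** — the forward pass stays the exact simulation (spikes are
Heaviside steps); the backward pass substitutes the normalized
fast-sigmoid pseudo-derivative `g(u) = 1/(1 + β|u − Θ|)²`. Logits are
the per-neuron maximum over time of a leaky-integrator readout's
membrane, fed to a softmax log-likelihood loss and ADAM.

## Worked example

Three input channels drive one LIF neuron through a leaky synapse group;
the membrane time constant is swept 10…100 ms across ten parallel batch
simulations via a generator-function parameter:

```python
import snnkit as sk

net, clock, x = sk.demo_three_input_fixture()   # [10, 100, 3] raster
sim = sk.init(net, clock, batch_size=10, seed=0)
sim.set_monitor("out", ["u"])
output = sim.run(x)                             # [10, 100, 1] spikes
u = sim.get_monitored_results("out")["u"][:, :, 0]
print("stack order:", sim.stack.order)
for b in (0, 4, 9):
    print(f"tau = {10*(b+1):3d} ms: peak membrane u = {u[b].max():.3f}, "
          f"spikes = {int(output[b].sum())}")
```

prints

```
stack order: ['in', 'syn', 'out']
tau =  10 ms: peak membrane u = 2.961, spikes = 31
tau =  50 ms: peak membrane u = 2.974, spikes = 33
tau = 100 ms: peak membrane u = 2.938, spikes = 34
```

— one run yields the whole parameter sweep: slower membranes (larger τ)
retain charge longer and fire slightly more under the same drive, while
every peak stays just under the threshold Θ = 3 reached at spike times.

A full pipeline (liquid state machine on a synthetic three-class
rate-coded task, training only the reservoir-to-output weights) is one
call:

```python
from snnkit.tasks import run_lsm_rate_benchmark
res = run_lsm_rate_benchmark(seed=1)
print(res.test_accuracy)        # 1.0 after 30 epochs
```

A `snnkit` command-line tool (`simulate`, `train`, `robustness`) wraps
the same library for shell use; see `snnkit --help`.

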