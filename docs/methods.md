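# Methods

This note documents the modelling choices, numerical conventions, and
limitations of spikesim. Everything here is normative for the
implementation: where an ordering or a tie-break was open, the choice made
is stated so that oracles and user code can rely on it.

## Simulation model

The simulator is clock-driven: all populations and connections advance on a
fixed grid `dt` (default 1.0 ms). A `run(inputs, time)` call executes
`⌊time/dt⌋` synchronous steps; if `time` is not divisible by `dt` the
remainder is truncated with a warning. Within a step:

1. pre-synaptic drive to every layer is computed from the spikes emitted at
   the previous step (all-zero on the first step after a reset), plus any
   user-supplied drive row for that step;
2. every population steps once (see the per-neuron schedule below);
3. supervisory clamps, if given, force the clamped neurons' spike and trace;
4. connections with a learning rule update, then re-apply their structural
   mask and weight bounds;
5. monitors record the post-update values.

The one-step synaptic latency makes the update order-independent: spikes at
step *t* are a function of state at *t−1* only. Per-target weight
normalization is enforced at the start of each `run` call and re-enforced
when the call returns, so the "sum of incoming weights equals `norm`"
invariant holds at every run boundary even when plasticity acted during the
run. A run that performs no learning is unaffected (normalization is
idempotent).

Each network owns a single seedable `numpy.random.Generator`; weight
initialization, encoders driven through the pipeline, and action sampling
all consume it, which is what makes whole experiments bit-reproducible from
one seed.

## Neuron models

Per-step schedule for all spiking populations: traces decay → refractory
counters decrement → non-refractory neurons integrate → spike condition is
tested (inclusive, `v ≥ v_thr`) → spiking neurons reset and re-arm the
refractory window → traces of spiking neurons are set.

- **LIF** (defaults: `v_rest = −65 mV`, `v_reset = −65 mV`,
  `v_thr = −52 mV`, `τ_m = 100 ms`, `refrac = 5 ms`): forward Euler,
  `v ← v + (dt/τ_m)(v_rest − v) + I`, decay applied before the drive. The
  zero-drive trajectory therefore equals the geometric recurrence
  `v_rest + (v₀−v_rest)(1−dt/τ_m)^k` exactly, which the tests assert to
  1e−10 relative error, and converges to the analytic exponential as
  `dt → 0` (checked at dt = 0.1 ms within 1%). During refractoriness the
  voltage is held at `v_reset` and drive is ignored; the counter is
  decremented by `dt` each step. These numeric defaults are implementation
  choices in the physiological range, not values with an external source.
- **IF**: the same without the leak term.
- **Adaptive LIF**: adds a per-neuron threshold offset `θ`, incremented by
  `theta_plus` on each spike and decaying with `tau_theta`. `theta_plus = 0`
  by default, i.e. adaptation is off unless requested; `θ` is deliberately
  *not* cleared by `reset_state`, since it is slow, learned excitability
  rather than per-example dynamic state.
- **Izhikevich**: Euler integration of `v' = 0.04v² + 5v + 140 − u + I`,
  `u' = a(bv − u)`; spike at `v ≥ v_peak = 30 mV`, then `v ← c`,
  `u ← u + d`. Defaults are the regular-spiking set (a = 0.02, b = 0.2,
  c = −65, d = 8). Two Euler half-steps are taken per `dt` when
  `dt > 0.5 ms`, because the quadratic term is unstable at 1 ms near
  threshold.
- **Spike traces**: multiplicative decay `x ← x·e^(−dt/τ_x)` (τ_x = 20 ms
  default) with set-to-1 on spike, which bounds `x ∈ [0, 1]`; an additive
  (+1) mode exists behind the `traces_additive` flag.

**Units.** Connection outputs are added directly to the membrane voltage
(mV per step). There are no synaptic conductances or synaptic current time
constants; this is the simplest model consistent with a per-step drive
vector, and all oracles are stated in it.

## Connections

Weights are stored pre × post; transport is `wᵀs`. Default initialization
is uniform on [0, 1) from the network RNG. Sparse connections are
dense-backed with a fixed binary mask; masked entries are re-zeroed after
every update and normalization, which restores learning on sparse
topologies deterministically. Normalization rescales each target's incoming
weights multiplicatively to the requested signed sum; a target whose
incoming sum is exactly zero has no finite scale factor and is left
unchanged with a warning. Signed (not absolute-value) sums were chosen so
that an explicitly inhibitory connection keeps its sign structure; this is
the main open judgement call in the module.

"Convolution" is cross-correlation (no kernel flip), images are
(channel, row, column), 0-based. The transport accumulates one filter tap
at a time in ascending (channel, row, column) order, vectorized over output
positions. This makes every output element's floating-point addition
sequence identical to the textbook nested-loop implementation, so
equivalence tests can demand bitwise equality rather than a tolerance; the
cost is acceptable because convolutional transport is used at small scale
here. Locally connected layers carry an independent filter per output
position with the same tap ordering. Plasticity rules apply to dense and
masked-dense connections; convolutional connections are fixed-weight in
this build (a weight-shared update rule has no single canonical discrete
form, and nothing downstream requires one).

## Learning rules

All rules are local and run on the current step's spike vectors and the
decay-then-set traces. With learning rates `ν_pre, ν_post ≥ 0`
(possibly asymmetric):

- Hebbian: `Δw = ν_pre·x_pre⊗s_post + ν_post·s_pre⊗x_post`. A
  `coincidence_only` flag replaces traces with current spikes.
- PostPre: `Δw = ν_post·x_pre⊗s_post − ν_pre·s_pre⊗x_post`. For an
  isolated pair separated by Δt the net change is
  `±ν·e^(−Δt/τ_x)` with the sign given by the order, which the tests check
  against a hand recurrence to 1e−10.
- MSTDP: `P⁺ ← P⁺e^(−dt/τ₊) + s_pre`, `P⁻ ← P⁻e^(−dt/τ₋) − s_post`,
  `ξ = P⁺⊗s_post + s_pre⊗P⁻`, `Δw = γ·r·ξ·dt`. The trackers are updated
  with the current spikes *before* ξ is read, so a same-step pre/post
  coincidence contributes immediately. Calling a reward-modulated rule
  without a reward raises a configuration error rather than silently
  assuming `r = 0`.
- MSTDPET: `z ← z·e^(−dt/τ_z) + ξ`, `Δw = γ·r·z·dt`. Defaults:
  `τ₊ = τ₋ = 20 ms`, `τ_z = 25 ms`, `γ = 0.1`.

For graded (real-valued) sources the rule consumes the real activity row in
place of both `s_pre` and `x_pre`, giving a rate-based Hebbian limit; this
is what the clamped supervised model trains with.

Eligibility and timing trackers are dynamic state and are cleared by
`reset_state`; weights never are.

## Encodings

- Poisson: per-step Bernoulli with `p = rate·dt/1000`, capped at 1 with a
  warning — the natural dialect for a clock-driven simulator. An
  exact-exponential-ISI mode exists behind a flag (binning can merge
  near-coincident events, so its counts run a few percent low at high
  rates).
- Bernoulli: intensities in [0, 1] (rescaled by the maximum if above);
  one independent draw per step.
- Rank order: neurons with positive intensity fire exactly once, ordered by
  descending intensity, ties broken by ascending index; spike times occupy
  consecutive steps from 0 and are compressed uniformly
  (`t_j = ⌊j·steps/n⌋`) when positive neurons outnumber steps. The latency
  map is a package convention chosen to be deterministic and testable.
- Image intensity → rate convention: linear, 128 Hz at unit intensity by
  default.
- Observation differencing subtracts the elementwise maximum over the
  history buffer and floors at 0; with history length 1 this degenerates to
  last-frame subtraction, with an empty history to a passthrough.

## Readouts

`assign_labels` uses per-class *mean* spike counts (not sums) so unbalanced
class counts do not bias assignments. All argmax tie-breaks — neuron
assignment, both voting schemes, group prediction — resolve to the lowest
class index; a completely silent neuron is therefore assigned class 0 with
an all-zero proportions row, and is excluded from class scores rather than
contributing NaN. Assignments are computed post hoc from the final training
pass by default; nothing prevents recomputing them online between epochs.
The logistic readout delegates to scikit-learn's multinomial
`LogisticRegression` and rejects single-class input explicitly.

## Pipeline

Actions are selected from the output layer's spikes summed over the
previous observation's simulation window (`sim_time` steps); the first
cycle, having no previous window, sees all-zero sums, for which both action
samplers fall back to the uniform distribution. Observations are stored in
the history buffer only at indices ≡ 0 (mod `delta`); the difference
against the buffer is taken *before* the current observation is inserted,
so with `delta = 1` the buffer always holds the previous frame. The
environment's reward is forwarded unchanged to reward-modulated rules on
every simulation step of the window. On episode end the environment and the
network's dynamic state are reset and the buffer cleared; weights persist.
Between dataset examples the same reset convention applies.

## Canned architectures

- **Competitive unsupervised network**: input → excitatory LIF (all-to-all,
  PostPre, per-target normalization, default `norm = 0.1·n_input`,
  `ν = (10⁻⁴, 10⁻²)`, `w_max = 1`) → inhibitory LIF via one-to-one
  excitation (`excite = 22.5`); inhibitory → excitatory is all-to-all
  except self with weight `−inhib` (`inhib = 17.5`). The excitatory
  population uses reset −60 mV; the inhibitory one faster dynamics
  (rest −60, reset −45, threshold −40, τ_m = 10 ms, refrac 2 ms). Adaptive
  excitatory thresholds are implemented but off by default. Training
  presents each Poisson-encoded image for 250 ms (a package default chosen
  for synthetic 10×10 images; larger/harder data warrants longer
  presentations) and resets dynamic state between examples.
- **Clamped supervised network**: graded input all-to-all onto an IF output
  partitioned into class groups; during training one randomly chosen neuron
  of the true class's group is clamped to spike every step, and the trace
  Hebbian rule plus per-target normalization pulls that neuron's filter
  toward the current example. Gradient-based training is out of scope, so
  this clamp-plus-Hebbian scheme is the package's supervision mechanism;
  prediction is by the most active group.
- **Reservoir**: input weights N(0, 1), recurrent weights
  N(0, 1/n_reservoir) by default (the variance-1 and variance-12 variants
  are reachable through `recurrent_std`, since a printed recurrent scale of
  "N(0,12)" is ambiguous and variance 12 saturates small reservoirs),
  per-neuron thresholds N(−52, 1); no plasticity. Per-example reservoir
  spike counts feed the logistic readout.
- **Benchmark network**: n Poisson inputs with rates U(0, 100) Hz,
  all-to-all N(0, 1) weights onto n LIF neurons, 1000 ms at dt = 1. The
  harness reports wall-clock seconds per grid point but never asserts them:
  timing is hardware-dependent. Note the dense weight matrix is n², so the
  top of the standard 250…10,000 grid needs ~0.8 GB per matrix; the
  reported experiments use smaller grids.

## Synthetic data

The blob-image generator stands in for image classification benchmarks: a
fixed geometric template per class (bars, diagonal, corner blocks —
pairwise correlation < 0.5 by construction), plus Gaussian pixel noise
clipped at zero, shuffled with a seed. It emulates the property that
matters for these architectures — classes occupy distinct, stable regions
of pixel space at moderate noise — and none of the properties that make
real image datasets hard: no within-class deformation, no overlapping
class manifolds, no intensity structure beyond the template. Passing the
end-to-end tests therefore shows the learning machinery works (filters
specialize, assignments recover classes), not that the architecture would
reach any particular accuracy on a real benchmark. Scripted spike trains
and the deterministic 4-action toy environment play the same role for the
plasticity and RL loops.

The experiment scale used in tests and the acceptance script — 3 classes,
10×10 images, 100 excitatory neurons, 3 passes over 300 training images,
150 held-out samples — is the package's standard desk-scale configuration
for this generator.

## Serialization

Networks serialize to a single pickle archive wrapped with a magic string
and format version. Loading verifies both and wraps any unpickling failure
in a `NetworkLoadError`, so truncated or foreign streams fail loudly.
Round-trips preserve weights bitwise and, because the RNG state travels
with the network, seeded runs after a round-trip reproduce the original
trajectories exactly.

## Known limitations

- No conductance-based synapses, synaptic delays, or arbitrary user
  differential equations; neuron dynamics are the fixed Euler forms above.
- Plasticity on convolutional/locally connected transport is not
  implemented.
- The per-step Bernoulli Poisson dialect slightly distorts ISI statistics
  at rates approaching `1000/dt` Hz (probability cap).
- Everything is single-threaded NumPy; the benchmark harness measures this
  implementation only.
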