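# spikesim

A clock-driven spiking neural network (SNN) simulator oriented toward
machine-learning experimentation: heterogeneous neuron populations, plastic
synaptic connections, spike encodings of dense data, biologically inspired
learning rules (including reward modulation), spike-based classification
readouts, and a pipeline loop that couples networks to datasets and
reinforcement-learning environments.

It is written for researchers who want to prototype SNN experiments —
unsupervised competitive learning, clamped supervised learning, reservoir
computing, spiking RL agents — in plain NumPy, with every stochastic
component seedable and every trajectory bit-reproducible.

## The models

**Simulation.** All state advances synchronously on a fixed grid `dt` (ms).
One `Network.run(inputs, time)` call executes `⌊time/dt⌋` steps; the drive a
layer receives at step *t* is computed from the spikes its afferents emitted
at step *t−1* (one-step synaptic latency), so results are independent of the
order in which layers update.

**Neurons.** The workhorse is the leaky integrate-and-fire neuron under
forward-Euler integration,

    v ← v + (dt/τ_m)(v_rest − v) + I,    spike iff v ≥ v_thr,

with post-spike reset to `v_reset` and an absolute refractory period.
Integrate-and-fire (no leak), McCulloch–Pitts (stateless threshold),
Izhikevich (quadratic membrane with recovery variable `u`), binary spike
sources, and graded current sources are also provided. Every spiking
population maintains an exponentially decaying spike trace
`x ← x·exp(−dt/τ_x)`, set to 1 on a spike.

**Plasticity.** Rules attach to connections and run once per step:

- *Hebbian*: `Δw = ν_pre·x_pre⊗s_post + ν_post·s_pre⊗x_post` — every
  near-coincidence potentiates.
- *PostPre STDP*: `Δw = ν_post·x_pre⊗s_post − ν_pre·s_pre⊗x_post` —
  pre-before-post strengthens, post-before-pre weakens.
- *MSTDP / MSTDPET* (reward-modulated STDP, after Florian's discrete-time
  formulation): per-neuron timing trackers `P⁺, P⁻` form the instantaneous
  STDP quantity `ξ = P⁺⊗s_post + s_pre⊗P⁻`; the weight change is `γ·r·ξ·dt`,
  or, with an eligibility trace, `z ← z·e^(−dt/τ_z) + ξ`, `Δw = γ·r·z·dt`,
  so a delayed reward still credits recent pairings.

Connections support elementwise weight bounds, structural sparsity masks,
per-target weight normalization (`Σ_i w_ij = norm`, re-enforced on every
`run` call), and shared-filter or locally connected 2-D convolutional
transport.

**Encodings.** `poisson` (rates in Hz → per-step Bernoulli with
`p = r·dt/1000`), `bernoulli` (intensities in [0,1]), and deterministic
`rank_order` (one spike per neuron, earlier for stronger inputs).

**Readouts.** `assign_labels` gives each neuron the class on which it fired
most during training; `all_activity` and `proportion_weighting` turn spike
counts on new examples into class votes; a multinomial logistic readout
(scikit-learn) handles real-valued features such as reservoir spike counts.

## Worked example

Unsupervised learning of synthetic 3-class images with the competitive
(excitatory/inhibitory) architecture, then classification from neuron label
assignments:

```python
import numpy as np
from spikesim import fixtures, models

images, labels = fixtures.generate_blob_images(
    n_classes=3, shape=(10, 10), noise=0.1, samples_per_class=60, seed=0)
result = models.run_diehl_cook_experiment(
    images[:120], labels[:120], images[120:180], labels[120:180],
    n_classes=3, n_neurons=50, epochs=2, time=250.0, seed=0)
print(f"all-activity accuracy:        {result['all_activity_accuracy']:.3f}")
print(f"proportion-weighting accuracy: {result['proportion_weighting_accuracy']:.3f}")
print(f"neurons assigned per class:    "
      f"{np.bincount(result['assignments'].assignment, minlength=3)}")
```

Output:

```
all-activity accuracy:        1.000
proportion-weighting accuracy: 1.000
neurons assigned per class:    [48  1  1]
```

Each image is Poisson-encoded (128 Hz at unit intensity) and presented for
250 ms; STDP with per-target normalization shapes the input filters while
lateral inhibition forces different excitatory neurons onto different
classes. Held-out images are then classified perfectly by the most active
assigned group. Most silent neurons default to class 0 (the documented
tie-break), which is why the assignment histogram is skewed; classification
is carried by the active, class-specific neurons.

A command-line interface mirrors the library:
`spikesim simulate|encode|pipeline|experiment|benchmark|fixtures --help`.

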