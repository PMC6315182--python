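"""Canned network architectures.

Three ready-made networks cover the main machine-learning uses of the
simulator:

* :func:`build_diehl_cook` — the competitive unsupervised architecture:
  Poisson input all-to-all onto excitatory LIF neurons (trace STDP,
  per-target weight normalization), one-to-one excitation of an inhibitory
  population whose all-to-all-except-self feedback enforces competition, so
  excitatory neurons learn prototypical input filters without labels.
* :func:`build_supervised_two_layer` — a graded-input layer all-to-all onto
  an integrate-and-fire output partitioned into class groups; during
  training a randomly chosen neuron of the true class's group is clamped to
  spike every step, dragging its filter toward the current example.
* :func:`build_reservoir` — a fixed random recurrent LIF reservoir whose
  per-example spike counts serve as features for a logistic readout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import encoding, evaluation
from .learning import Hebbian, PostPre
from .network import Network
from .nodes import AdaptiveLIFNodes, IFNodes, InputNodes, LIFNodes, RealInputNodes
from .topology import Connection
from .utils import ensure_rng

__all__ = [
    "build_diehl_cook",
    "run_diehl_cook_example",
    "run_diehl_cook_experiment",
    "ClampSchedule",
    "build_supervised_two_layer",
    "train_supervised",
    "predict_supervised",
    "build_reservoir",
    "reservoir_features",
]


# -- competitive unsupervised network ----------------------------------

def build_diehl_cook(
    n_input,
    n_neurons=100,
    excite=22.5,
    inhib=17.5,
    nu=(1e-4, 1e-2),
    norm=None,
    w_max=1.0,
    theta_plus=0.0,
    dt=1.0,
    seed=None,
) -> Network:
    """Competitive unsupervised network (input -> excitatory -> inhibitory).

    Parameters
    ----------
    n_neurons : int
        Size of the excitatory population (the inhibitory population
        matches it).
    excite, inhib : float
        Magnitudes of the one-to-one exc->inh weights and the hollow
        all-to-all inh->exc weights (the latter applied with negative sign).
    nu : (float, float)
        (depression, potentiation) learning rates of the PostPre STDP rule
        on the input->exc connection.
    norm : float, optional
        Desired sum of incoming input->exc weights per excitatory neuron;
        defaults to ``0.1 * n_input``.
    theta_plus : float
        Adaptive-threshold increment of the excitatory neurons (0 disables
        adaptation, the default).
    """
    net = Network(dt=dt, seed=seed)
    net.add_layer("input", InputNodes(n_input))
    exc = AdaptiveLIFNodes(
        n_neurons,
        v_rest=-65.0, v_reset=-60.0, v_thr=-52.0,
        tau_m=100.0, refrac=5.0, trace_tau=20.0,
        theta_plus=theta_plus, tau_theta=1e7,
    )
    inh = LIFNodes(
        n_neurons,
        v_rest=-60.0, v_reset=-45.0, v_thr=-40.0,
        tau_m=10.0, refrac=2.0, trace_tau=20.0,
    )
    net.add_layer("exc", exc)
    net.add_layer("inh", inh)
    if norm is None:
        norm = 0.1 * n_input
    w_in = 0.3 * net.rng.random((n_input, n_neurons))
    conn_in = Connection(
        net.layers["input"], exc, w=w_in, w_min=0.0, w_max=w_max,
        norm=norm, update_rule=PostPre(nu_pre=nu[0], nu_post=nu[1]),
    )
    conn_in.normalize()
    net.add_connection("input", "exc", conn_in)
    eye = np.eye(n_neurons)
    net.add_connection(
        "exc", "inh", Connection(exc, inh, w=excite * eye)
    )
    net.add_connection(
        "inh", "exc", Connection(inh, exc, w=-inhib * (1.0 - eye))
    )
    return net


def run_diehl_cook_example(net: Network, image, time=250.0, intensity=128.0,
                           train=True) -> np.ndarray:
    """Present one image (Poisson-encoded) and return excitatory spike counts.

    Pixel intensities map linearly to firing rates (``intensity`` Hz at
    pixel value 1).  Dynamic state is reset afterwards, as between dataset
    examples; learned weights persist.
    """
    rates = np.asarray(image, dtype=float) * intensity
    train_spikes = encoding.poisson(rates, time=time, dt=net.dt, rng=net.rng)
    net.learning = bool(train)
    records = net.run(inputs={"input": train_spikes}, time=time)
    counts = records["exc"].sum(axis=0).astype(float)
    net.reset_state()
    return counts


def run_diehl_cook_experiment(
    train_images,
    train_labels,
    test_images,
    test_labels,
    n_classes,
    n_neurons=100,
    epochs=3,
    time=250.0,
    intensity=128.0,
    seed=0,
    **build_kwargs,
) -> dict:
    """Train, assign neuron labels, and score the unsupervised classifier.

    Neuron labels are assigned from the activity recorded on the final
    training pass; held-out examples are classified with the all-activity
    and proportion-weighting readouts.
    """
    n_input = int(np.prod(np.asarray(train_images).shape[1:]))
    net = build_diehl_cook(n_input, n_neurons=n_neurons, seed=seed,
                           **build_kwargs)
    last_counts = None
    for epoch in range(epochs):
        counts = [
            run_diehl_cook_example(net, img, time=time, intensity=intensity)
            for img in train_images
        ]
        last_counts = np.array(counts)
    assignments = evaluation.assign_labels(last_counts, train_labels, n_classes)
    test_counts = np.array([
        run_diehl_cook_example(net, img, time=time, intensity=intensity,
                               train=False)
        for img in test_images
    ])
    preds_all = evaluation.all_activity(test_counts, assignments)
    preds_prop = evaluation.proportion_weighting(test_counts, assignments)
    test_labels = np.asarray(test_labels)
    return {
        "network": net,
        "assignments": assignments,
        "train_counts": last_counts,
        "test_counts": test_counts,
        "all_activity_accuracy": float((preds_all == test_labels).mean()),
        "proportion_weighting_accuracy": float(
            (preds_prop == test_labels).mean()
        ),
    }


# -- clamped supervised network ----------------------------------------

@dataclass
class ClampSchedule:
    """Partition of the output layer into class groups, with clamp sampling."""

    groups: np.ndarray  # shape (n_classes, n_per_class) of neuron indices

    @property
    def n_output(self) -> int:
        return self.groups.size

    def sample(self, label: int, rng) -> np.ndarray:
        """Boolean clamp vector forcing one random neuron of the label's group."""
        forced = np.zeros(self.n_output, dtype=bool)
        forced[rng.choice(self.groups[int(label)])] = True
        return forced

    def group_counts(self, counts: np.ndarray) -> np.ndarray:
        """Sum per-neuron spike counts within each class group."""
        return np.array([counts[g].sum() for g in self.groups])


def build_supervised_two_layer(
    n_input,
    n_per_class,
    n_classes,
    nu=(0.05, 0.05),
    norm=None,
    dt=1.0,
    seed=None,
):
    """Two-layer clamped supervised network.

    Returns ``(network, schedule)`` where the schedule partitions the output
    integrate-and-fire layer into ``n_classes`` groups of ``n_per_class``
    neurons and samples the training-time spike clamp.
    """
    n_output = n_per_class * n_classes
    net = Network(dt=dt, seed=seed)
    net.add_layer("input", RealInputNodes(n_input))
    out = IFNodes(n_output, v_rest=-65.0, v_reset=-65.0, v_thr=-52.0,
                  refrac=0.0, trace_tau=20.0)
    net.add_layer("output", out)
    if norm is None:
        norm = 0.05 * n_input
    w = net.rng.random((n_input, n_output))
    net.add_connection(
        "input", "output",
        Connection(
            net.layers["input"], out, w=w, w_min=0.0, w_max=np.inf,
            norm=norm, update_rule=Hebbian(nu_pre=nu[0], nu_post=nu[1]),
        ),
    )
    schedule = ClampSchedule(
        groups=np.arange(n_output).reshape(n_classes, n_per_class)
    )
    return net, schedule


def _real_input_rows(image, steps):
    row = np.asarray(image, dtype=float).reshape(-1)
    return np.broadcast_to(row, (steps, row.size))


def train_supervised(net: Network, schedule: ClampSchedule, images, labels,
                     epochs=1, time=50.0) -> None:
    """Clamp-train the supervised network on (images, labels)."""
    steps = net.n_steps(time)
    net.learning = True
    for _ in range(epochs):
        for image, label in zip(images, labels):
            forced = schedule.sample(label, net.rng)
            net.run(
                inputs={"input": _real_input_rows(image, steps)},
                time=time,
                clamp={"output": forced},
            )
            net.reset_state()


def predict_supervised(net: Network, schedule: ClampSchedule, images,
                       time=50.0) -> np.ndarray:
    """Predict by the most active output group (ties to the lowest class)."""
    steps = net.n_steps(time)
    net.learning = False
    preds = []
    for image in images:
        records = net.run(
            inputs={"input": _real_input_rows(image, steps)}, time=time
        )
        counts = records["output"].sum(axis=0).astype(float)
        preds.append(int(np.argmax(schedule.group_counts(counts))))
        net.reset_state()
    return np.array(preds)


# -- reservoir ----------------------------------------------------------

def build_reservoir(
    n_input,
    n_reservoir=625,
    input_std=1.0,
    recurrent_std=None,
    threshold_mean=-52.0,
    threshold_std=1.0,
    dt=1.0,
    seed=None,
) -> Network:
    """Fixed random recurrent LIF reservoir with heterogeneous thresholds.

    Input weights are drawn from N(0, input_std^2); recurrent weights from
    N(0, recurrent_std^2) with ``recurrent_std`` defaulting to
    ``1 / sqrt(n_reservoir)``; per-neuron voltage thresholds from
    N(threshold_mean, threshold_std^2).  No plasticity.
    """
    net = Network(dt=dt, seed=seed)
    rng = net.rng
    if recurrent_std is None:
        recurrent_std = 1.0 / np.sqrt(n_reservoir)
    thresholds = rng.normal(threshold_mean, threshold_std, size=n_reservoir)
    net.add_layer("input", InputNodes(n_input))
    res = LIFNodes(
        n_reservoir, v_rest=-65.0, v_reset=-65.0, v_thr=thresholds,
        tau_m=100.0, refrac=5.0,
    )
    net.add_layer("reservoir", res)
    net.add_connection(
        "input", "reservoir",
        Connection(net.layers["input"], res,
                   w=rng.normal(0.0, input_std, size=(n_input, n_reservoir))),
    )
    net.add_connection(
        "reservoir", "reservoir",
        Connection(res, res,
                   w=rng.normal(0.0, recurrent_std,
                                size=(n_reservoir, n_reservoir))),
    )
    return net


def reservoir_features(net: Network, images, time=100.0, intensity=128.0,
                       encoder=encoding.poisson) -> np.ndarray:
    """Per-example reservoir spike counts, for use as readout features."""
    features = []
    for image in images:
        rates = np.asarray(image, dtype=float) * intensity
        train = encoder(rates, time=time, dt=net.dt, rng=net.rng)
        records = net.run(inputs={"input": train}, time=time)
        features.append(records["reservoir"].sum(axis=0).astype(float))
        net.reset_state()
    return np.array(features)
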