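"""Spike-based classification readouts.

In the unsupervised setting each neuron is assigned the class of data on
which it fires most during training (``assign_labels``); new examples are
then classified from those assignments either by mean activity of each
class's neurons (``all_activity``) or weighting each neuron's activity by
how class-specific it was during training (``proportion_weighting``).
All argmax tie-breaks resolve to the lowest class index.

A multinomial logistic-regression readout on arbitrary real feature
vectors (e.g. reservoir spike counts) is provided via scikit-learn.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.linear_model import LogisticRegression

__all__ = [
    "NeuronAssignments",
    "assign_labels",
    "all_activity",
    "proportion_weighting",
    "logreg_fit",
    "logreg_predict",
]


@dataclass
class NeuronAssignments:
    """Per-neuron class assignment with supporting statistics.

    ``rates[i, c]`` is neuron i's mean spike count over training examples of
    class c; ``assignment[i] = argmax_c rates[i, c]`` (ties to the lowest
    class); ``proportions`` are rates normalized per neuron (rows of zeros
    for silent neurons).
    """

    assignment: np.ndarray
    rates: np.ndarray
    proportions: np.ndarray

    @property
    def n_classes(self) -> int:
        return self.rates.shape[1]


def _check_table(counts, labels=None):
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 2 or counts.size == 0:
        raise ValueError("activity table must be a non-empty 2-D array")
    if (counts < 0).any():
        raise ValueError("spike counts must be nonnegative")
    if labels is not None:
        labels = np.asarray(labels)
        if labels.shape != (counts.shape[0],):
            raise ValueError("labels must align with the table's rows")
    return counts, labels


def assign_labels(counts, labels, n_classes) -> NeuronAssignments:
    """Assign each neuron the class on which it spiked most, on average."""
    counts, labels = _check_table(counts, labels)
    if labels.min() < 0 or labels.max() >= n_classes:
        raise ValueError("labels must lie in [0, n_classes)")
    n_neurons = counts.shape[1]
    rates = np.zeros((n_neurons, n_classes))
    for c in range(n_classes):
        mask = labels == c
        if mask.any():
            rates[:, c] = counts[mask].mean(axis=0)
    row_sums = rates.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        proportions = np.where(row_sums > 0, rates / row_sums, 0.0)
    return NeuronAssignments(
        assignment=rates.argmax(axis=1), rates=rates, proportions=proportions
    )


def all_activity(counts, assignments: NeuronAssignments) -> np.ndarray:
    """Predict the class whose assigned neurons are most active on average."""
    counts, _ = _check_table(counts)
    scores = np.zeros((counts.shape[0], assignments.n_classes))
    for c in range(assignments.n_classes):
        members = assignments.assignment == c
        if members.any():
            scores[:, c] = counts[:, members].mean(axis=1)
    return scores.argmax(axis=1)


def proportion_weighting(counts, assignments: NeuronAssignments) -> np.ndarray:
    """Like :func:`all_activity` but each neuron's count is weighted by the
    proportion of its training activity that fell on the scored class."""
    counts, _ = _check_table(counts)
    scores = np.zeros((counts.shape[0], assignments.n_classes))
    for c in range(assignments.n_classes):
        members = assignments.assignment == c
        if members.any():
            weighted = counts[:, members] * assignments.proportions[members, c]
            scores[:, c] = weighted.mean(axis=1)
    return scores.argmax(axis=1)


def logreg_fit(features, labels, seed=0, max_iter=1000) -> LogisticRegression:
    """Fit a multinomial logistic-regression readout on real feature vectors."""
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    if not np.isfinite(features).all():
        raise ValueError("features must be finite")
    if np.unique(labels).size < 2:
        raise ValueError("logistic readout needs at least two classes")
    model = LogisticRegression(max_iter=max_iter, random_state=int(seed))
    model.fit(features, labels)
    return model


def logreg_predict(model: LogisticRegression, features) -> np.ndarray:
    """Predict class labels with a fitted logistic readout."""
    return model.predict(np.asarray(features, dtype=float))
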