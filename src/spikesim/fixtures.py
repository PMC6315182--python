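"""Synthetic datasets and scripted spike trains.

Generates class-structured images (distinct geometric templates plus
truncated Gaussian pixel noise) that play the role handwriting/natural-image
benchmarks play for spiking classifiers, and exactly scripted spike trains
for plasticity-rule oracles — so every other module is testable with no
download.
"""

from __future__ import annotations

import numpy as np

from .encoding import SpikeTrain
from .utils import ensure_rng

__all__ = ["blob_templates", "generate_blob_images", "generate_scripted_spikes"]


def blob_templates(n_classes=3, shape=(10, 10)) -> np.ndarray:
    """Distinct nonnegative class templates (bars, diagonals, blocks).

    Templates use non-overlapping or weakly overlapping supports so their
    pairwise correlations stay below 0.5 by construction; intensities are 1
    on the pattern and 0 elsewhere.
    """
    h, w = shape
    if n_classes < 1 or n_classes > 6:
        raise ValueError("between 1 and 6 template classes are supported")
    if h < 6 or w < 6:
        raise ValueError("template images must be at least 6x6")
    templates = np.zeros((n_classes, h, w))
    makers = [
        lambda t: t.__setitem__((slice(1, 3), slice(None)), 1.0),     # top bar
        lambda t: t.__setitem__((slice(None), slice(w - 3, w - 1)), 1.0),  # right bar
        lambda t: np.fill_diagonal(t, 1.0),                           # diagonal
        lambda t: t.__setitem__((slice(h - 3, h - 1), slice(0, w // 2)), 1.0),
        lambda t: t.__setitem__(
            (slice(h // 2 - 1, h // 2 + 1), slice(0, 2)), 1.0
        ),
        lambda t: t.__setitem__(
            (slice(h - 2, h), slice(w - 4, w)), 1.0
        ),
    ]
    for c in range(n_classes):
        makers[c](templates[c])
    # construction guarantee: templates are pairwise dissimilar
    flat = templates.reshape(n_classes, -1)
    for i in range(n_classes):
        for j in range(i + 1, n_classes):
            r = np.corrcoef(flat[i], flat[j])[0, 1]
            assert r < 0.5, "template construction violated dissimilarity"
    return templates


def generate_blob_images(
    n_classes=3,
    shape=(10, 10),
    noise=0.1,
    samples_per_class=100,
    seed=0,
    templates=None,
):
    """Sample noisy images around class templates.

    Each sample is its class template plus Gaussian pixel noise with
    standard deviation ``noise``, clipped at 0 (intensities stay
    nonnegative).  Samples are shuffled; labels stay aligned.

    Returns
    -------
    images : (n_classes * samples_per_class, *shape) array
    labels : aligned integer class vector
    """
    rng = ensure_rng(seed)
    if templates is None:
        templates = blob_templates(n_classes, shape)
    templates = np.asarray(templates, dtype=float)
    n_classes = templates.shape[0]
    n = n_classes * samples_per_class
    images = np.repeat(templates, samples_per_class, axis=0)
    labels = np.repeat(np.arange(n_classes), samples_per_class)
    if noise > 0:
        images = images + rng.normal(0.0, noise, size=images.shape)
        images = np.clip(images, 0.0, None)
    order = rng.permutation(n)
    return images[order], labels[order]


def generate_scripted_spikes(events, time, n, dt=1.0) -> SpikeTrain:
    """Build a spike train containing exactly the scripted (step, neuron) events.

    Duplicate events place a single spike; out-of-range events raise.
    """
    steps = int(np.floor(time / dt + 1e-9))
    out = np.zeros((steps, n), dtype=np.uint8)
    for step, neuron in events:
        if not (0 <= step < steps and 0 <= neuron < n):
            raise ValueError(f"event ({step}, {neuron}) outside train bounds")
        out[step, neuron] = 1
    return SpikeTrain(out, dt=dt, time=time)
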