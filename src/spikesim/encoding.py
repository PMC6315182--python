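"""Spike encodings of non-negative dense data, and raw-data preprocessing.

Encoders turn an array of intensities or firing rates into a
:class:`SpikeTrain` — a binary array with one row per simulation step and
one column per neuron (the neuron axes keep the data's shape).  All encoders
produce exactly ``floor(time / dt)`` rows and are deterministic given a seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .utils import ensure_rng

__all__ = [
    "SpikeTrain",
    "poisson",
    "bernoulli",
    "rank_order",
    "preprocess",
    "difference",
]


def _n_steps(time: float, dt: float) -> int:
    if dt <= 0:
        raise ValueError("dt must be positive")
    if time <= 0:
        raise ValueError("time must be positive")
    return int(np.floor(time / dt + 1e-9))


def _validate_stimulus(data) -> np.ndarray:
    data = np.asarray(data, dtype=float)
    if np.isnan(data).any():
        raise ValueError("stimulus contains NaN")
    if (data < 0).any():
        raise ValueError("stimulus intensities must be non-negative")
    return data


@dataclass
class SpikeTrain:
    """Binary spike record: ``data`` has shape (steps, *neuron_shape).

    ``dt`` and ``time`` (ms) record the temporal grid the train was built on.
    """

    data: np.ndarray
    dt: float = 1.0
    time: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if not np.isin(self.data, (0, 1)).all():
            raise ValueError("spike trains must be binary")
        self.data = self.data.astype(np.uint8)
        if self.time is None:
            self.time = self.data.shape[0] * self.dt

    @property
    def n_steps(self) -> int:
        return self.data.shape[0]

    @property
    def n_neurons(self) -> int:
        return int(np.prod(self.data.shape[1:]))

    def rows(self) -> np.ndarray:
        """2-D float view (steps, neurons) for feeding a network input layer."""
        return self.data.reshape(self.n_steps, -1).astype(float)

    def counts(self) -> np.ndarray:
        """Per-neuron spike count over the whole train (flattened)."""
        return self.rows().sum(axis=0)


def poisson(data, time, dt=1.0, rng=None, exact_isi=False) -> SpikeTrain:
    """Encode firing rates (Hz) as independent Poisson spike trains.

    Default dialect is the clock-driven per-step Bernoulli approximation:
    each step a neuron with rate ``r`` spikes with probability
    ``r * dt / 1000`` (capped at 1 with a warning).  With ``exact_isi=True``,
    exponential inter-spike intervals are drawn and binned onto the grid.
    """
    data = _validate_stimulus(data)
    steps = _n_steps(time, dt)
    rng = ensure_rng(rng)
    if exact_isi:
        flat = data.reshape(-1)
        out = np.zeros((steps, flat.size), dtype=np.uint8)
        for i, rate in enumerate(flat):
            if rate <= 0:
                continue
            t = rng.exponential(1000.0 / rate)
            while t < steps * dt:
                out[int(t // dt), i] = 1
                t += rng.exponential(1000.0 / rate)
        return SpikeTrain(out.reshape((steps, *data.shape)), dt=dt, time=time)
    p = data * dt / 1000.0
    if (p >= 1.0).any():
        warnings.warn(
            "rate * dt >= 1000: per-step spike probability capped at 1",
            RuntimeWarning,
            stacklevel=2,
        )
        p = np.minimum(p, 1.0)
    draws = rng.random((steps, *data.shape))
    return SpikeTrain((draws < p).astype(np.uint8), dt=dt, time=time)


def bernoulli(data, time, dt=1.0, rng=None) -> SpikeTrain:
    """Encode intensities in [0, 1] as per-step Bernoulli spikes.

    Intensities above 1 are rescaled by the array maximum first.
    """
    data = _validate_stimulus(data)
    if data.size and data.max() > 1.0:
        data = data / data.max()
    steps = _n_steps(time, dt)
    rng = ensure_rng(rng)
    draws = rng.random((steps, *data.shape))
    return SpikeTrain((draws < data).astype(np.uint8), dt=dt, time=time)


def rank_order(data, time, dt=1.0, rng=None) -> SpikeTrain:
    """Single spike per neuron, earlier for stronger inputs; deterministic.

    Neurons with positive intensity fire exactly once, ordered by descending
    intensity (ties broken by ascending index); zero intensity neurons stay
    silent.  Spike times occupy consecutive steps from 0, compressed
    uniformly into the available window when positive neurons outnumber
    steps.  ``rng`` is accepted for encoder-interface uniformity and ignored
    (the encoding is deterministic).
    """
    data = _validate_stimulus(data)
    steps = _n_steps(time, dt)
    flat = data.reshape(-1)
    out = np.zeros((steps, flat.size), dtype=np.uint8)
    positive = np.flatnonzero(flat > 0)
    # stable sort on negated intensity: descending value, ascending index ties
    order = positive[np.argsort(-flat[positive], kind="stable")]
    n_pos = order.size
    for j, idx in enumerate(order):
        t = j if n_pos <= steps else int(j * steps // n_pos)
        out[t, idx] = 1
    return SpikeTrain(out.reshape((steps, *data.shape)), dt=dt, time=time)


# -- raw-data preprocessing --------------------------------------------

def _crop(data, top=0, left=0, height=None, width=None):
    h = data.shape[-2] - top if height is None else height
    w = data.shape[-1] - left if width is None else width
    if top < 0 or left < 0 or top + h > data.shape[-2] or left + w > data.shape[-1]:
        raise ValueError("crop region outside array bounds")
    return data[..., top:top + h, left:left + w]


def _subsample(data, factor=2):
    factor = int(factor)
    if factor < 1:
        raise ValueError("subsample factor must be >= 1")
    # top-left element of each factor x factor block
    return data[..., ::factor, ::factor]


def _binarize(data, threshold=0.5):
    return (data > threshold).astype(float)


def _rescale(data, scale=1.0):
    return data * scale


_PREPROCESS_OPS = {
    "crop": _crop,
    "subsample": _subsample,
    "binarize": _binarize,
    "rescale": _rescale,
}


def preprocess(data, ops) -> np.ndarray:
    """Apply an ordered list of preprocessing steps to a raw array.

    Each element of ``ops`` is a mapping with an ``"op"`` key naming one of
    ``crop``, ``subsample``, ``binarize``, ``rescale``; remaining keys are
    passed to the step as keyword arguments.
    """
    data = np.asarray(data, dtype=float)
    for op in ops:
        op = dict(op)
        name = op.pop("op")
        if name not in _PREPROCESS_OPS:
            raise ValueError(f"unknown preprocessing op {name!r}")
        data = _PREPROCESS_OPS[name](data, **op)
    return data


def difference(current, history) -> np.ndarray:
    """New information in an observation relative to a history of observations.

    Returns ``max(current - elementwise-max(history), 0)``; with an empty
    history the observation passes through unchanged.
    """
    current = np.asarray(current, dtype=float)
    frames = list(history)
    if not frames:
        return current
    stacked = np.stack([np.asarray(f, dtype=float) for f in frames])
    if stacked.shape[1:] != current.shape:
        raise ValueError("history frame shape does not match observation")
    return np.maximum(current - stacked.max(axis=0), 0.0)
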