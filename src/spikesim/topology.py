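"""Synaptic connection types.

A connection transports the activity of a source population to a drive
vector on its target population.  Variants: dense all-to-all
(:class:`Connection`), structurally masked sparse (:class:`SparseConnection`),
two-dimensional convolution with shared filters (:class:`Conv2dConnection`)
and locally connected layers with an independent filter per output position
(:class:`LocallyConnectedConnection`).

"Convolution" follows the deep-learning convention: cross-correlation
without kernel flip, image axes ordered (channel, row, column), 0-based.

Dense-shaped connections support elementwise weight bounds, per-target
weight normalization (the desired sum of incoming weights per target
neuron, re-enforced by the parent network at the start of every ``run``),
and plasticity via an attached learning rule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .utils import ensure_rng

__all__ = [
    "Connection",
    "SparseConnection",
    "ConvSpec",
    "Conv2dConnection",
    "LocallyConnectedConnection",
]


class Connection:
    """Dense all-to-all connection with weight matrix ``w`` of shape (pre, post).

    Parameters
    ----------
    source, target : Nodes
        Pre- and post-synaptic populations.
    w : array, optional
        Initial weights, shape ``(source.n, target.n)``.  If omitted, drawn
        uniformly from [0, 1) using ``rng``.
    w_min, w_max : float
        Elementwise weight bounds enforced after every plasticity update.
    norm : float, optional
        Desired sum of incoming weights per target neuron; enforced by
        :meth:`normalize` (signed sums).
    update_rule : LearningRule, optional
        Plasticity rule applied once per simulation step while learning is
        enabled.
    """

    def __init__(self, source, target, w=None, w_min=-np.inf, w_max=np.inf,
                 norm=None, update_rule=None, rng=None):
        self.source = source
        self.target = target
        if w is None:
            w = ensure_rng(rng).random((source.n, target.n))
        w = np.array(w, dtype=float)
        if w.shape != (source.n, target.n):
            raise ValueError(
                f"weight shape {w.shape} != ({source.n}, {target.n})"
            )
        if w_min > w_max:
            raise ValueError("w_min must not exceed w_max")
        self.w = w
        self.w_min = float(w_min)
        self.w_max = float(w_max)
        self.norm = None if norm is None else float(norm)
        self.update_rule = update_rule
        if update_rule is not None:
            update_rule.attach(self)
        self.clamp_weights()

    # -- transport ------------------------------------------------------
    def compute(self, activity: np.ndarray) -> np.ndarray:
        """Drive delivered to the target: ``w.T @ activity``."""
        activity = np.asarray(activity, dtype=float).reshape(-1)
        if activity.shape[0] != self.source.n:
            raise ValueError(
                f"activity length {activity.shape[0]} != source size {self.source.n}"
            )
        return self.w.T @ activity

    # -- maintenance ----------------------------------------------------
    def normalize(self) -> None:
        """Rescale each target's incoming weights so their signed sum is ``norm``.

        Targets whose incoming sum is zero are left unchanged with a warning
        (no finite scale factor exists).
        """
        if self.norm is None:
            return
        sums = self.w.sum(axis=0)
        zero = sums == 0
        if zero.any():
            warnings.warn(
                "normalize: target(s) with all-zero incoming weights left "
                "unchanged",
                RuntimeWarning,
                stacklevel=2,
            )
        scale = np.ones_like(sums)
        scale[~zero] = self.norm / sums[~zero]
        self.w *= scale

    def clamp_weights(self) -> None:
        """Project weights into [w_min, w_max] elementwise."""
        np.clip(self.w, self.w_min, self.w_max, out=self.w)

    def apply_mask(self) -> None:  # dense: nothing structurally zero
        pass

    def update(self, dt: float, reward=None) -> None:
        if self.update_rule is not None:
            self.update_rule.update(self, dt, reward=reward)
            self.apply_mask()
            self.clamp_weights()

    def reset_state(self) -> None:
        """Reset rule state (eligibility, timing trackers); weights persist."""
        if self.update_rule is not None:
            self.update_rule.reset_state()


class SparseConnection(Connection):
    """Dense-backed connection with a fixed binary structural mask.

    Entries where ``mask == 0`` are permanently zero — transport, plasticity
    and normalization never revive them — which makes every learning rule
    available on sparse topologies.
    """

    def __init__(self, source, target, mask, **kwargs):
        mask = np.asarray(mask)
        if mask.shape != (source.n, target.n):
            raise ValueError(
                f"mask shape {mask.shape} != ({source.n}, {target.n})"
            )
        if not np.isin(mask, (0, 1)).all():
            raise ValueError("mask must be binary")
        self.mask = mask.astype(bool)
        super().__init__(source, target, **kwargs)
        self.apply_mask()

    def apply_mask(self):
        self.w[~self.mask] = 0.0

    def normalize(self):
        super().normalize()
        self.apply_mask()


@dataclass(frozen=True)
class ConvSpec:
    """Geometry of a 2-D convolutional / locally connected layer."""

    in_channels: int
    out_channels: int
    kernel_height: int
    kernel_width: int
    stride: int = 1
    padding: int = 0

    def out_size(self, in_height: int, in_width: int) -> tuple[int, int]:
        oh = (in_height + 2 * self.padding - self.kernel_height) // self.stride + 1
        ow = (in_width + 2 * self.padding - self.kernel_width) // self.stride + 1
        if oh < 1 or ow < 1:
            raise ValueError("convolution output size must be positive")
        return oh, ow


class Conv2dConnection:
    """Two-dimensional convolution with one shared filter bank.

    Source activity is interpreted through ``source.shape`` as
    ``(in_channels, height, width)``; output drive is the flattened
    ``(out_channels, out_height, out_width)`` feature map.  Plasticity rules
    are not supported on convolutional connections in this build.
    """

    def __init__(self, source, target, spec: ConvSpec, w=None, rng=None):
        if len(source.shape) != 3 or source.shape[0] != spec.in_channels:
            raise ValueError(
                "source shape must be (in_channels, height, width) matching spec"
            )
        self.source = source
        self.target = target
        self.spec = spec
        _, in_h, in_w = source.shape
        self.out_shape = (spec.out_channels, *spec.out_size(in_h, in_w))
        if target.n != int(np.prod(self.out_shape)):
            raise ValueError(
                f"target size {target.n} != output feature-map size "
                f"{int(np.prod(self.out_shape))}"
            )
        shape = (spec.out_channels, spec.in_channels,
                 spec.kernel_height, spec.kernel_width)
        if w is None:
            w = ensure_rng(rng).random(shape)
        w = np.array(w, dtype=float)
        if w.shape != shape:
            raise ValueError(f"filter shape {w.shape} != {shape}")
        self.w = w
        self.update_rule = None
        self.norm = None

    def _padded(self, activity):
        x = np.asarray(activity, dtype=float).reshape(self.source.shape)
        p = self.spec.padding
        if p:
            x = np.pad(x, ((0, 0), (p, p), (p, p)))
        return x

    def _tap_slices(self, xp):
        """Yield (ci, u, v, window) per filter tap, taps in canonical order.

        Accumulating tap contributions in ascending (channel, row, col)
        order makes every output element's floating-point addition sequence
        identical to the textbook nested-loop cross-correlation, so results
        are bitwise reproducible against such a reference.
        """
        st = self.spec.stride
        _, oh, ow = self.out_shape
        for ci in range(self.spec.in_channels):
            for u in range(self.spec.kernel_height):
                for v in range(self.spec.kernel_width):
                    yield ci, u, v, xp[ci, u:u + st * oh:st, v:v + st * ow:st]

    def compute(self, activity):
        xp = self._padded(activity)
        out = np.zeros(self.out_shape)
        for ci, u, v, window in self._tap_slices(xp):
            for oc in range(self.spec.out_channels):
                out[oc] += self.w[oc, ci, u, v] * window
        return out.reshape(-1)

    def normalize(self):
        pass

    def clamp_weights(self):
        pass

    def update(self, dt, reward=None):
        pass

    def reset_state(self):
        pass


class LocallyConnectedConnection(Conv2dConnection):
    """Convolution-like layer without weight sharing.

    Each output position carries an independent filter; filters are stored
    with shape ``(out_channels, out_h, out_w, in_channels, kh, kw)``.
    """

    def __init__(self, source, target, spec: ConvSpec, w=None, rng=None):
        super().__init__(source, target, spec, w=np.zeros(
            (spec.out_channels, spec.in_channels,
             spec.kernel_height, spec.kernel_width)), rng=rng)
        shape = (spec.out_channels, *self.out_shape[1:],
                 spec.in_channels, spec.kernel_height, spec.kernel_width)
        if w is None:
            w = ensure_rng(rng).random(shape)
        w = np.array(w, dtype=float)
        if w.shape != shape:
            raise ValueError(f"filter shape {w.shape} != {shape}")
        self.w = w

    def compute(self, activity):
        xp = self._padded(activity)
        out = np.zeros(self.out_shape)
        for ci, u, v, window in self._tap_slices(xp):
            for oc in range(self.spec.out_channels):
                out[oc] += self.w[oc, :, :, ci, u, v] * window
        return out.reshape(-1)
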