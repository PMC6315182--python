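"""Neuron population models.

Each population owns its per-neuron state (voltage ``v``, binary spike vector
``s``, refractory counter ``refrac_count``, spike trace ``x``) and advances it
one time step at a time under Euler integration.  The normative within-step
schedule is: traces decay, drive is integrated, the spike condition is tested
(inclusive, ``v >= v_thr``), spiking neurons reset and re-arm their refractory
window, and finally traces of spiking neurons are set to 1 (or incremented by
1 in additive mode).

Drive is in voltage units (mV added per step): connection outputs are summed
directly onto the membrane, with no synaptic conductance or current time
constants.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Nodes",
    "InputNodes",
    "RealInputNodes",
    "McCullochPittsNodes",
    "IFNodes",
    "LIFNodes",
    "AdaptiveLIFNodes",
    "IzhikevichNodes",
]


class Nodes:
    """Abstract population of ``n`` neurons with spike traces.

    Parameters
    ----------
    n : int
        Number of neurons.
    shape : tuple of int, optional
        Spatial arrangement (e.g. ``(channels, height, width)`` for image
        inputs feeding convolutional connections).  ``prod(shape)`` must
        equal ``n``.  Defaults to ``(n,)``.
    trace_tau : float
        Spike-trace time constant in ms.
    traces_additive : bool
        If True, a spike adds 1 to the trace instead of setting it to 1.
    """

    def __init__(self, n, shape=None, trace_tau=20.0, traces_additive=False):
        n = int(n)
        if n < 1:
            raise ValueError("population size must be >= 1")
        if trace_tau <= 0:
            raise ValueError("trace_tau must be positive")
        self.n = n
        self.shape = tuple(shape) if shape is not None else (n,)
        if int(np.prod(self.shape)) != n:
            raise ValueError("prod(shape) must equal n")
        self.trace_tau = float(trace_tau)
        self.traces_additive = bool(traces_additive)
        self.s = np.zeros(n)
        self.x = np.zeros(n)

    @property
    def activity(self) -> np.ndarray:
        """Output transported by outgoing connections (binary spikes here)."""
        return self.s

    def step(self, drive: np.ndarray, dt: float) -> np.ndarray:
        raise NotImplementedError

    def reset_state(self) -> None:
        """Reset spikes and traces; subclasses add voltages and counters."""
        self.s = np.zeros(self.n)
        self.x = np.zeros(self.n)

    # -- shared helpers -------------------------------------------------
    def _check_drive(self, drive):
        drive = np.asarray(drive, dtype=float)
        if drive.shape != (self.n,):
            raise ValueError(
                f"drive shape {drive.shape} does not match population size {self.n}"
            )
        return drive

    def _decay_traces(self, dt):
        self.x *= np.exp(-dt / self.trace_tau)

    def _register_spikes(self, spikes):
        self.s = spikes.astype(float)
        if self.traces_additive:
            self.x += self.s
        else:
            self.x[spikes] = 1.0

    def clamp(self, forced: np.ndarray) -> None:
        """Force the given neurons to have spiked this step (supervision)."""
        forced = np.asarray(forced, dtype=bool)
        self.s = np.where(forced, 1.0, self.s)
        if self.traces_additive:
            self.x += forced.astype(float)
        else:
            self.x[forced] = 1.0


class InputNodes(Nodes):
    """Neurons whose spikes are supplied by the user (one row per step)."""

    def step(self, drive, dt):
        row = np.asarray(drive, dtype=float).reshape(-1)
        if row.shape != (self.n,):
            raise ValueError(f"input row shape {row.shape} != ({self.n},)")
        if not np.isin(row, (0.0, 1.0)).all():
            raise ValueError("input spike rows must be binary")
        self._decay_traces(dt)
        self._register_spikes(row.astype(bool))
        return self.s


class RealInputNodes(Nodes):
    """Graded source: passes a real-valued row downstream in place of spikes.

    Emulates constant current injection; the row is exposed unchanged as this
    population's activity, and doubles as its "spike" and trace values so
    that rate-based learning rules can consume it.
    """

    def __init__(self, n, shape=None, trace_tau=20.0):
        super().__init__(n, shape=shape, trace_tau=trace_tau)

    def step(self, drive, dt):
        row = self._check_drive(np.asarray(drive, dtype=float).reshape(-1))
        self.s = row
        self.x = row.copy()
        return self.s


class McCullochPittsNodes(Nodes):
    """Stateless threshold units: spike iff drive >= threshold."""

    def __init__(self, n, threshold=1.0, shape=None, trace_tau=20.0):
        super().__init__(n, shape=shape, trace_tau=trace_tau)
        self.threshold = float(threshold)

    def step(self, drive, dt):
        drive = self._check_drive(drive)
        self._decay_traces(dt)
        self._register_spikes(drive >= self.threshold)
        return self.s


class IFNodes(Nodes):
    """Integrate-and-fire: perfect integrator with threshold/reset/refractory."""

    def __init__(
        self,
        n,
        v_rest=-65.0,
        v_reset=-65.0,
        v_thr=-52.0,
        refrac=5.0,
        shape=None,
        trace_tau=20.0,
        traces_additive=False,
    ):
        super().__init__(n, shape=shape, trace_tau=trace_tau,
                         traces_additive=traces_additive)
        v_thr = np.broadcast_to(np.asarray(v_thr, dtype=float), (n,)).copy()
        if not (v_thr > v_reset).all():
            raise ValueError("v_thr must exceed v_reset")
        if refrac < 0:
            raise ValueError("refrac must be nonnegative")
        self.v_rest = float(v_rest)
        self.v_reset = float(v_reset)
        self.v_thr = v_thr
        self.refrac = float(refrac)
        self.v = np.full(n, self.v_rest)
        self.refrac_count = np.zeros(n)

    def _integrate(self, drive, dt, free):
        self.v[free] += drive[free]

    def step(self, drive, dt):
        drive = self._check_drive(drive)
        self._decay_traces(dt)
        refractory = self.refrac_count > 0
        self.refrac_count[refractory] = np.maximum(
            self.refrac_count[refractory] - dt, 0.0
        )
        free = ~refractory
        self._integrate(drive, dt, free)
        spikes = free & (self.v >= self.v_thr)
        self.v[spikes] = self.v_reset
        self.refrac_count[spikes] = self.refrac
        self._register_spikes(spikes)
        return self.s

    def reset_state(self):
        super().reset_state()
        self.v = np.full(self.n, self.v_rest)
        self.refrac_count = np.zeros(self.n)


class LIFNodes(IFNodes):
    """Leaky integrate-and-fire neurons.

    The membrane decays toward the rest potential with time constant
    ``tau_m`` under forward-Euler integration, decay applied before the
    drive::

        v <- v + (dt / tau_m) * (v_rest - v) + drive

    A neuron spikes when ``v >= v_thr`` (inclusive), then resets to
    ``v_reset`` and is held there for ``refrac`` ms, during which drive is
    ignored.
    """

    def __init__(
        self,
        n,
        v_rest=-65.0,
        v_reset=-65.0,
        v_thr=-52.0,
        tau_m=100.0,
        refrac=5.0,
        shape=None,
        trace_tau=20.0,
        traces_additive=False,
    ):
        super().__init__(
            n,
            v_rest=v_rest,
            v_reset=v_reset,
            v_thr=v_thr,
            refrac=refrac,
            shape=shape,
            trace_tau=trace_tau,
            traces_additive=traces_additive,
        )
        if tau_m <= 0:
            raise ValueError("tau_m must be positive")
        self.tau_m = float(tau_m)

    def _integrate(self, drive, dt, free):
        self.v[free] += (dt / self.tau_m) * (self.v_rest - self.v[free]) + drive[free]


class AdaptiveLIFNodes(LIFNodes):
    """LIF with an adaptive per-neuron threshold offset ``theta``.

    Each spike increments the neuron's threshold by ``theta_plus``; theta
    decays with time constant ``tau_theta``.  With ``theta_plus = 0``
    (default) the population behaves exactly like :class:`LIFNodes`.
    """

    def __init__(self, n, theta_plus=0.0, tau_theta=1e7, **kwargs):
        super().__init__(n, **kwargs)
        self.theta_plus = float(theta_plus)
        self.tau_theta = float(tau_theta)
        self.theta = np.zeros(n)

    def step(self, drive, dt):
        drive = self._check_drive(drive)
        self._decay_traces(dt)
        self.theta *= np.exp(-dt / self.tau_theta)
        refractory = self.refrac_count > 0
        self.refrac_count[refractory] = np.maximum(
            self.refrac_count[refractory] - dt, 0.0
        )
        free = ~refractory
        self._integrate(drive, dt, free)
        spikes = free & (self.v >= self.v_thr + self.theta)
        self.v[spikes] = self.v_reset
        self.refrac_count[spikes] = self.refrac
        self.theta[spikes] += self.theta_plus
        self._register_spikes(spikes)
        return self.s

    def reset_state(self):
        # theta is learned slow state, deliberately preserved across resets
        s = self.theta
        super().reset_state()
        self.theta = s


class IzhikevichNodes(Nodes):
    """Izhikevich neurons (quadratic membrane + recovery variable).

    Euler integration of ``v' = 0.04 v^2 + 5 v + 140 - u + I`` and
    ``u' = a (b v - u)``; a spike is emitted when ``v >= v_peak``, after
    which ``v <- c`` and ``u <- u + d``.  Two Euler half-steps per ``dt``
    are taken when ``dt > 0.5`` ms for stability of the quadratic term.
    Defaults are the regular-spiking parameter set.
    """

    def __init__(self, n, a=0.02, b=0.2, c=-65.0, d=8.0, v_peak=30.0,
                 shape=None, trace_tau=20.0):
        super().__init__(n, shape=shape, trace_tau=trace_tau)
        if a <= 0:
            raise ValueError("a must be positive")
        if v_peak <= c:
            raise ValueError("v_peak must exceed c")
        self.a, self.b, self.c, self.d = float(a), float(b), float(c), float(d)
        self.v_peak = float(v_peak)
        self.v = np.full(n, self.c)
        self.u = self.b * self.v

    def step(self, drive, dt):
        drive = self._check_drive(drive)
        self._decay_traces(dt)
        n_sub = 2 if dt > 0.5 else 1
        h = dt / n_sub
        for _ in range(n_sub):
            dv = 0.04 * self.v**2 + 5.0 * self.v + 140.0 - self.u + drive
            du = self.a * (self.b * self.v - self.u)
            self.v += h * dv
            self.u += h * du
        spikes = self.v >= self.v_peak
        self.v[spikes] = self.c
        self.u[spikes] += self.d
        self._register_spikes(spikes)
        return self.s

    def reset_state(self):
        super().reset_state()
        self.v = np.full(self.n, self.c)
        self.u = self.b * self.v
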