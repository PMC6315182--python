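"""Network core: synchronous clock-driven simulation of populations and
connections, state reset, monitoring, and serialization.

The network advances all components on a fixed grid ``dt``.  One call to
:meth:`Network.run` executes ``floor(time / dt)`` synchronous steps; at each
step the pre-synaptic drive to every layer is computed from the spikes the
source populations emitted on the *previous* step (one-step synaptic
latency — all-zero on the first step after a reset), merged additively with
any user-supplied drive, then every population steps once, plastic
connections update, and monitors record the post-update values.  Because
drive depends only on the previous step, the order in which layers update
within a step cannot affect the result.
"""

from __future__ import annotations

import io
import pickle
import warnings

import numpy as np

from .encoding import SpikeTrain
from .nodes import InputNodes, RealInputNodes
from .utils import NetworkLoadError, ensure_rng

__all__ = ["Network", "Monitor", "save_network", "load_network"]

_FORMAT_MAGIC = "spikesim-network"
_FORMAT_VERSION = 1


class Monitor:
    """Records a state variable of a population or connection each step.

    Parameters
    ----------
    obj : Nodes or Connection
        The component to observe.
    state_vars : sequence of str
        Attribute names to record (e.g. ``("s", "v")`` or ``("w",)``).
    """

    def __init__(self, obj, state_vars=("s",)):
        self.obj = obj
        self.state_vars = tuple(state_vars)
        self.records = {var: [] for var in self.state_vars}

    def record(self) -> None:
        for var in self.state_vars:
            self.records[var].append(np.array(getattr(self.obj, var)))

    def get(self, var: str) -> np.ndarray:
        """Recorded values, shape (steps_since_reset, *variable_shape)."""
        rows = self.records[var]
        if not rows:
            return np.empty((0,))
        return np.stack(rows)

    def reset_state(self) -> None:
        self.records = {var: [] for var in self.state_vars}


class Network:
    """Coordinates named layers (populations) and connections between them.

    Parameters
    ----------
    dt : float
        Simulation time step in ms.
    seed : int, optional
        Seeds the network-owned RNG threaded to all stochastic components
        (weight initialization, stochastic encoders run through the
        pipeline, action sampling).
    """

    def __init__(self, dt=1.0, seed=None):
        if dt <= 0:
            raise ValueError("dt must be positive")
        self.dt = float(dt)
        self.layers: dict[str, object] = {}
        self.connections: dict[tuple[str, str], object] = {}
        self.monitors: dict[str, Monitor] = {}
        self.learning = True
        self.rng = ensure_rng(seed)

    # -- construction ---------------------------------------------------
    def add_layer(self, name: str, nodes) -> None:
        if name in self.layers:
            raise ValueError(f"layer {name!r} already exists")
        self.layers[name] = nodes

    def add_connection(self, source: str, target: str, connection) -> None:
        for nm in (source, target):
            if nm not in self.layers:
                raise ValueError(f"connection endpoint {nm!r} is not a layer")
        if (source, target) in self.connections:
            raise ValueError(f"connection ({source!r}, {target!r}) already exists")
        if connection.source is not self.layers[source] or (
            connection.target is not self.layers[target]
        ):
            raise ValueError("connection endpoints do not match the named layers")
        self.connections[(source, target)] = connection

    def add_monitor(self, name: str, monitor: Monitor) -> None:
        if name in self.monitors:
            raise ValueError(f"monitor {name!r} already exists")
        self.monitors[name] = monitor

    # -- simulation -----------------------------------------------------
    def n_steps(self, time: float) -> int:
        if time <= 0:
            raise ValueError("time must be positive")
        steps = int(np.floor(time / self.dt + 1e-9))
        if abs(steps * self.dt - time) > 1e-9 * max(1.0, time):
            warnings.warn(
                f"time={time} not divisible by dt={self.dt}; truncating to "
                f"{steps} steps",
                RuntimeWarning,
                stacklevel=3,
            )
        if steps < 1:
            raise ValueError("time must cover at least one step (time >= dt)")
        return steps

    def get_inputs(self, activities=None) -> dict[str, np.ndarray]:
        """Pre-synaptic drive per layer from the given (or current) activity.

        ``activities`` maps layer name to source activity vector; by default
        each source population's current activity (previous-step output) is
        used.  Layers without incoming connections receive zeros.
        """
        drives = {name: np.zeros(layer.n) for name, layer in self.layers.items()}
        for (src, tgt), conn in self.connections.items():
            act = (
                activities[src] if activities is not None
                else self.layers[src].activity
            )
            drives[tgt] = drives[tgt] + conn.compute(act)
        return drives

    def run(self, inputs=None, time=None, reward=None, clamp=None):
        """Simulate for ``floor(time/dt)`` synchronous steps.

        Parameters
        ----------
        inputs : dict, optional
            Maps layer name to a :class:`SpikeTrain` or array with one row
            per step.  Rows drive Input layers as spikes, RealInput layers
            as graded activity, and are added to the synaptic drive of any
            other layer.
        time : float
            Simulated duration in ms.
        reward : float, optional
            Scalar reward forwarded to reward-modulated learning rules on
            every step of this call.
        clamp : dict, optional
            Maps layer name to a boolean vector (or steps x n array) of
            neurons forced to spike each step (supervisory clamp).

        Returns
        -------
        dict mapping layer name to a (steps, n) binary spike record.
        """
        steps = self.n_steps(time)
        inputs = {} if inputs is None else dict(inputs)
        clamp = {} if clamp is None else dict(clamp)
        rows: dict[str, np.ndarray] = {}
        for name, train in inputs.items():
            if name not in self.layers:
                raise KeyError(f"inputs names unknown layer {name!r}")
            arr = train.rows() if isinstance(train, SpikeTrain) else np.asarray(
                train, dtype=float
            )
            arr = arr.reshape(arr.shape[0], -1)
            if arr.shape != (steps, self.layers[name].n):
                raise ValueError(
                    f"input for layer {name!r} has shape {arr.shape}; expected "
                    f"({steps}, {self.layers[name].n})"
                )
            rows[name] = arr
        clamp_rows: dict[str, np.ndarray] = {}
        for name, forced in clamp.items():
            if name not in self.layers:
                raise KeyError(f"clamp names unknown layer {name!r}")
            forced = np.asarray(forced, dtype=bool)
            if forced.ndim == 1:
                forced = np.broadcast_to(forced, (steps, forced.shape[0]))
            if forced.shape != (steps, self.layers[name].n):
                raise ValueError(f"clamp for layer {name!r} has wrong shape")
            clamp_rows[name] = forced

        # per-target weight normalization, enforced once per run call
        for conn in self.connections.values():
            conn.normalize()

        records = {
            name: np.zeros((steps, layer.n), dtype=np.uint8)
            for name, layer in self.layers.items()
        }
        for t in range(steps):
            drives = self.get_inputs()
            for name, layer in self.layers.items():
                if isinstance(layer, (InputNodes, RealInputNodes)):
                    row = rows.get(name)
                    layer.step(
                        row[t] if row is not None else np.zeros(layer.n), self.dt
                    )
                else:
                    drive = drives[name]
                    if name in rows:
                        drive = drive + rows[name][t]
                    layer.step(drive, self.dt)
                if name in clamp_rows:
                    layer.clamp(clamp_rows[name][t])
                if not isinstance(layer, RealInputNodes):
                    records[name][t] = layer.s != 0
            if self.learning:
                for conn in self.connections.values():
                    conn.update(self.dt, reward=reward)
            for monitor in self.monitors.values():
                monitor.record()
        # re-enforce per-target sums so the invariant also holds after
        # plasticity updates made during this call
        for conn in self.connections.values():
            conn.normalize()
        return records

    def reset_state(self) -> None:
        """Reset dynamic state (voltages, spikes, traces, counters, monitors).

        Learned weights are untouched.
        """
        for layer in self.layers.values():
            layer.reset_state()
        for conn in self.connections.values():
            conn.reset_state()
        for monitor in self.monitors.values():
            monitor.reset_state()

    # -- serialization --------------------------------------------------
    def save(self, path_or_stream) -> None:
        save_network(self, path_or_stream)


def save_network(network: Network, path_or_stream) -> None:
    """Serialize a network (topology, parameters, weights) to one archive."""
    payload = {
        "magic": _FORMAT_MAGIC,
        "format_version": _FORMAT_VERSION,
        "network": network,
    }
    if hasattr(path_or_stream, "write"):
        pickle.dump(payload, path_or_stream)
    else:
        with open(path_or_stream, "wb") as fh:
            pickle.dump(payload, fh)


def load_network(path_or_stream) -> Network:
    """Restore a network saved by :func:`save_network`.

    Raises :class:`~spikesim.utils.NetworkLoadError` on truncated, corrupt,
    or version-mismatched archives.
    """
    try:
        if hasattr(path_or_stream, "read"):
            payload = pickle.load(path_or_stream)
        else:
            with open(path_or_stream, "rb") as fh:
                payload = pickle.load(fh)
    except (pickle.UnpicklingError, EOFError, AttributeError, MemoryError,
            OSError, ValueError) as exc:
        raise NetworkLoadError(f"cannot read network archive: {exc}") from exc
    if not isinstance(payload, dict) or payload.get("magic") != _FORMAT_MAGIC:
        raise NetworkLoadError("stream is not a spikesim network archive")
    if payload.get("format_version") != _FORMAT_VERSION:
        raise NetworkLoadError(
            f"unsupported archive version {payload.get('format_version')!r}"
        )
    network = payload["network"]
    if not isinstance(network, Network):
        raise NetworkLoadError("archive does not contain a Network")
    return network


def loads_network(data: bytes) -> Network:
    """Restore a network from in-memory bytes (see :func:`load_network`)."""
    return load_network(io.BytesIO(data))


def dumps_network(network: Network) -> bytes:
    """Serialize a network to in-memory bytes (see :func:`save_network`)."""
    buf = io.BytesIO()
    save_network(network, buf)
    return buf.getvalue()
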