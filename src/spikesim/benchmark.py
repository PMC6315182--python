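"""Benchmark network: timing the simulator core across network sizes.

The benchmark network is a population of ``n`` Poisson inputs with firing
rates drawn uniformly from [0, 100] Hz, connected all-to-all (standard
normal weights) to an equally sized population of LIF neurons, simulated
for 1000 ms at dt = 1.0 ms.  Wall-clock seconds are reported for
information only — they depend on the host and are never asserted.
"""

from __future__ import annotations

import time as _time

import numpy as np
import pandas as pd

from . import encoding
from .network import Network
from .nodes import InputNodes, LIFNodes
from .topology import Connection

__all__ = ["build_benchmark_network", "run_benchmark", "default_grid"]


def default_grid(start=250, stop=10000, step=250):
    """The standard size grid: 250 to 10,000 in steps of 250."""
    return list(range(start, stop + 1, step))


def build_benchmark_network(n, dt=1.0, seed=None):
    """Build the n-input -> n-LIF benchmark network.

    Returns ``(network, rates)`` where ``rates`` (Hz) are the input
    population's sampled Poisson rates, drawn from U(0, 100).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    net = Network(dt=dt, seed=seed)
    rates = net.rng.uniform(0.0, 100.0, size=n)
    net.add_layer("input", InputNodes(n))
    lif = LIFNodes(n)
    net.add_layer("lif", lif)
    net.add_connection(
        "input", "lif",
        Connection(net.layers["input"], lif,
                   w=net.rng.normal(0.0, 1.0, size=(n, n))),
    )
    return net, rates


def run_benchmark(ns, time=1000.0, dt=1.0, seed=0) -> pd.DataFrame:
    """Simulate the benchmark network at each size; report timing and spikes.

    One row per grid point: population size, steps executed, wall-clock
    seconds of the run call, and total input/LIF spike counts.
    """
    ns = list(ns)
    if any(b <= a for a, b in zip(ns, ns[1:])):
        raise ValueError("size grid must be strictly increasing")
    rows = []
    seeds = np.random.SeedSequence(seed).spawn(len(ns))
    for n, ss in zip(ns, seeds):
        net, rates = build_benchmark_network(
            n, dt=dt, seed=np.random.default_rng(ss)
        )
        train = encoding.poisson(rates, time=time, dt=dt, rng=net.rng)
        t0 = _time.perf_counter()
        records = net.run(inputs={"input": train}, time=time)
        seconds = _time.perf_counter() - t0
        rows.append({
            "n": n,
            "steps": records["input"].shape[0],
            "seconds": seconds,
            "input_spikes": int(records["input"].sum()),
            "lif_spikes": int(records["lif"].sum()),
        })
    return pd.DataFrame(rows)
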