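"""Network core tests: synchronous stepping, causality, reset semantics,
monitors, and serialization."""

import io

import numpy as np
import pytest

import spikesim as ss
from spikesim.network import dumps_network, loads_network
from spikesim.utils import NetworkLoadError
from conftest import make_two_layer


class TestStepCounts:
    @pytest.mark.parametrize("dt,expected", [(0.25, 40), (0.5, 20), (1.0, 10)])
    def test_steps_equal_floor_time_over_dt(self, dt, expected):
        net = make_two_layer(dt=dt)
        steps = net.n_steps(10.0)
        assert steps == expected
        rec = net.run(time=10.0)
        assert all(r.shape[0] == expected for r in rec.values())

    def test_truncation_warns(self):
        net = make_two_layer(dt=1.0)
        with pytest.warns(RuntimeWarning, match="truncating"):
            assert net.n_steps(10.5) == 10

    def test_nonpositive_time_rejected(self):
        net = make_two_layer()
        with pytest.raises(ValueError):
            net.run(time=0.0)


class TestCausality:
    def test_one_step_synaptic_latency(self):
        """Input spike at step 3 first moves the target voltage at step 4."""
        net = make_two_layer(w=np.ones((3, 2)))
        train = ss.fixtures.generate_scripted_spikes([(3, 0)], time=10, n=3)
        lif = net.layers["post"]
        voltages = []
        monitor = ss.Monitor(lif, ("v",))
        net.add_monitor("v", monitor)
        net.run(inputs={"pre": train}, time=10.0)
        v = monitor.get("v")[:, 0]
        assert np.all(v[:4] == -65.0)
        assert v[4] != -65.0

    def test_quiescent_network_stays_at_rest(self):
        net = make_two_layer()
        rec = net.run(time=20.0)
        assert rec["post"].sum() == 0
        assert np.all(net.layers["post"].v == -65.0)

    def test_deterministic_given_seed(self):
        def run_once():
            net = ss.Network(dt=1.0, seed=9)
            net.add_layer("in", ss.InputNodes(20))
            lif = ss.LIFNodes(10)
            net.add_layer("out", lif)
            net.add_connection("in", "out", ss.Connection(
                net.layers["in"], lif, rng=net.rng))
            train = ss.poisson(np.full(20, 80.0), time=50,
                               rng=np.random.default_rng(3))
            return net.run(inputs={"in": train}, time=50.0)

        a, b = run_once(), run_once()
        for k in a:
            assert np.array_equal(a[k], b[k])


class TestGetInputs:
    def test_no_connections_zero_drive(self):
        net = ss.Network()
        net.add_layer("a", ss.LIFNodes(4))
        drives = net.get_inputs()
        assert np.array_equal(drives["a"], np.zeros(4))

    def test_dense_drive_is_wt_s(self, rng):
        w = rng.normal(size=(3, 2))
        net = make_two_layer(w=w)
        s = np.array([1.0, 0.0, 1.0])
        drives = net.get_inputs({"pre": s, "post": np.zeros(2)})
        np.testing.assert_allclose(drives["post"], w.T @ s)

    def test_converging_connections_add(self, rng):
        net = ss.Network(seed=0)
        a, b = ss.InputNodes(3), ss.InputNodes(2)
        tgt = ss.LIFNodes(4)
        wa, wb = rng.normal(size=(3, 4)), rng.normal(size=(2, 4))
        net.add_layer("a", a)
        net.add_layer("b", b)
        net.add_layer("t", tgt)
        net.add_connection("a", "t", ss.Connection(a, tgt, w=wa))
        net.add_connection("b", "t", ss.Connection(b, tgt, w=wb))
        sa, sb = np.array([1.0, 1.0, 0.0]), np.array([0.0, 1.0])
        drives = net.get_inputs({"a": sa, "b": sb, "t": np.zeros(4)})
        np.testing.assert_allclose(drives["t"], wa.T @ sa + wb.T @ sb)


class TestErrors:
    def test_unknown_input_layer(self, two_layer_net):
        with pytest.raises(KeyError, match="unknown layer"):
            two_layer_net.run(inputs={"nope": np.zeros((10, 3))}, time=10.0)

    def test_row_count_mismatch(self, two_layer_net):
        with pytest.raises(ValueError, match="shape"):
            two_layer_net.run(inputs={"pre": np.zeros((7, 3))}, time=10.0)

    def test_duplicate_connection_rejected(self):
        net = make_two_layer()
        with pytest.raises(ValueError, match="already exists"):
            net.add_connection("pre", "post", ss.Connection(
                net.layers["pre"], net.layers["post"],
                w=np.ones((3, 2))))


class TestReset:
    def _spiking_net(self):
        net = make_two_layer(
            w=np.full((3, 2), 5.0),
            rule=ss.PostPre(nu_pre=1e-2, nu_post=1e-2),
            w_min=0.0, w_max=10.0,
        )
        train = ss.poisson(np.full(3, 300.0), time=30,
                           rng=np.random.default_rng(0))
        net.run(inputs={"pre": train}, time=30.0)
        return net

    def test_reset_restores_rest_state(self):
        net = self._spiking_net()
        net.reset_state()
        post = net.layers["post"]
        assert np.all(post.v == post.v_rest)
        assert post.s.sum() == 0
        assert post.x.sum() == 0
        assert post.refrac_count.sum() == 0

    def test_weights_survive_reset(self):
        net = self._spiking_net()
        w = net.connections[("pre", "post")].w.copy()
        assert not np.array_equal(w, np.full((3, 2), 5.0))  # STDP acted
        net.reset_state()
        np.testing.assert_array_equal(net.connections[("pre", "post")].w, w)

    def test_reset_idempotent(self):
        net = self._spiking_net()
        net.reset_state()
        snap = {k: v.v.copy() for k, v in net.layers.items()
                if hasattr(v, "v")}
        net.reset_state()
        for k, v in snap.items():
            np.testing.assert_array_equal(net.layers[k].v, v)


class TestMonitors:
    def test_monitor_matches_returned_spikes(self):
        net = make_two_layer(w=np.full((3, 2), 20.0))
        mon = ss.Monitor(net.layers["post"], ("s", "v"))
        net.add_monitor("post", mon)
        train = ss.poisson(np.full(3, 200.0), time=25,
                           rng=np.random.default_rng(1))
        rec = net.run(inputs={"pre": train}, time=25.0)
        assert mon.get("s").shape == (25, 2)
        np.testing.assert_array_equal(mon.get("s"), rec["post"])
        assert mon.get("v").shape == (25, 2)

    def test_monitor_emptied_on_reset(self):
        net = make_two_layer()
        mon = ss.Monitor(net.layers["post"], ("s",))
        net.add_monitor("post", mon)
        net.run(time=10.0)
        net.reset_state()
        assert mon.get("s").shape == (0,)


class TestNormalizationDuringRun:
    def test_sums_equal_norm_after_run_with_stdp(self):
        net = make_two_layer(
            w=np.random.default_rng(0).random((3, 2)),
            rule=ss.PostPre(nu_pre=5e-2, nu_post=5e-2),
            w_min=0.0, w_max=5.0, norm=1.5,
        )
        train = ss.poisson(np.full(3, 300.0), time=50,
                           rng=np.random.default_rng(2))
        net.run(inputs={"pre": train}, time=50.0)
        sums = net.connections[("pre", "post")].w.sum(axis=0)
        np.testing.assert_allclose(sums, 1.5, atol=1e-6)


class TestSerialization:
    def _trained_net(self):
        net = make_two_layer(
            w=np.random.default_rng(5).random((3, 2)),
            rule=ss.PostPre(nu_pre=1e-2, nu_post=1e-2),
            w_min=0.0, w_max=2.0, seed=7,
        )
        train = ss.poisson(np.full(3, 200.0), time=20,
                           rng=np.random.default_rng(6))
        net.run(inputs={"pre": train}, time=20.0)
        return net

    def test_roundtrip_weights_bitwise_equal(self):
        net = self._trained_net()
        clone = loads_network(dumps_network(net))
        np.testing.assert_array_equal(
            clone.connections[("pre", "post")].w,
            net.connections[("pre", "post")].w,
        )
        assert clone.dt == net.dt
        assert list(clone.layers) == list(net.layers)

    def test_seeded_run_identical_after_roundtrip(self):
        net = self._trained_net()
        clone = loads_network(dumps_network(net))
        train = ss.poisson(np.full(3, 150.0), time=30,
                           rng=np.random.default_rng(8))
        rec_a = net.run(inputs={"pre": train}, time=30.0)
        rec_b = clone.run(inputs={"pre": train}, time=30.0)
        for k in rec_a:
            np.testing.assert_array_equal(rec_a[k], rec_b[k])

    def test_truncated_stream_raises(self):
        data = dumps_network(self._trained_net())
        with pytest.raises(NetworkLoadError):
            loads_network(data[: len(data) // 2])

    def test_foreign_stream_raises(self):
        import pickle

        with pytest.raises(NetworkLoadError):
            loads_network(pickle.dumps({"not": "a network"}))

    def test_file_roundtrip(self, tmp_path):
        net = self._trained_net()
        path = tmp_path / "net.pkl"
        ss.save_network(net, path)
        clone = ss.load_network(path)
        np.testing.assert_array_equal(
            clone.connections[("pre", "post")].w,
            net.connections[("pre", "post")].w,
        )


class TestClamp:
    def test_clamped_neurons_spike_every_step(self):
        net = make_two_layer()
        forced = np.array([True, False])
        rec = net.run(time=10.0, clamp={"post": forced})
        assert rec["post"][:, 0].all()
        assert rec["post"][:, 1].sum() == 0
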