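"""Plasticity-rule tests against independent per-step recurrence oracles."""

import numpy as np
import pytest

from spikesim.learning import MSTDP, MSTDPET, Hebbian, PostPre
from spikesim.nodes import InputNodes
from spikesim.topology import Connection
from spikesim.utils import ConfigurationError

TRACE_TAU = 20.0


def drive_pair(rule, pre_rows, post_rows, dt=1.0, w0=0.5, rewards=None,
               n_pre=1, n_post=1, **conn_kwargs):
    """Step a scripted pre/post pair through the normative schedule.

    Returns the connection after presenting all rows (populations step,
    then the rule updates on the current spikes/traces).
    """
    pre = InputNodes(n_pre, trace_tau=TRACE_TAU)
    post = InputNodes(n_post, trace_tau=TRACE_TAU)
    conn = Connection(pre, post, w=np.full((n_pre, n_post), w0),
                      update_rule=rule, **conn_kwargs)
    history = []
    for t, (rp, rq) in enumerate(zip(pre_rows, post_rows)):
        pre.step(np.asarray(rp, dtype=float), dt)
        post.step(np.asarray(rq, dtype=float), dt)
        reward = None if rewards is None else rewards[t]
        conn.update(dt, reward=reward)
        history.append(conn.w.copy())
    return conn, np.array(history)


def pair_rows(t_pre, t_post, length):
    pre = [[1.0] if t == t_pre else [0.0] for t in range(length)]
    post = [[1.0] if t == t_post else [0.0] for t in range(length)]
    return pre, post


class TestPostPre:
    @pytest.mark.parametrize("delta_t", range(1, 11))
    def test_pre_before_post_potentiates(self, delta_t):
        """Isolated pairing: dw = nu_post * exp(-dt_pair / trace_tau)."""
        nu_pre, nu_post = 3e-3, 7e-3
        rows = pair_rows(0, delta_t, delta_t + 1)
        conn, _ = drive_pair(PostPre(nu_pre, nu_post), *rows, w0=0.5)
        dw = conn.w[0, 0] - 0.5
        assert dw > 0
        assert dw == pytest.approx(nu_post * np.exp(-delta_t / TRACE_TAU),
                                   rel=1e-12)

    @pytest.mark.parametrize("delta_t", range(1, 11))
    def test_post_before_pre_depresses(self, delta_t):
        nu_pre, nu_post = 3e-3, 7e-3
        post_first = pair_rows(delta_t, 0, delta_t + 1)
        conn, _ = drive_pair(PostPre(nu_pre, nu_post), *post_first, w0=0.5)
        dw = conn.w[0, 0] - 0.5
        assert dw < 0
        assert dw == pytest.approx(-nu_pre * np.exp(-delta_t / TRACE_TAU),
                                   rel=1e-12)

    def test_simultaneous_spikes_use_decay_then_set_traces(self):
        """Same-step pre and post: traces are 1 (just set), so
        dw = nu_post - nu_pre."""
        nu_pre, nu_post = 2e-3, 5e-3
        conn, _ = drive_pair(PostPre(nu_pre, nu_post), [[1.0]], [[1.0]])
        assert conn.w[0, 0] - 0.5 == pytest.approx(nu_post - nu_pre, rel=1e-12)

    def test_clamped_to_bounds(self):
        conn, _ = drive_pair(PostPre(nu_pre=0.0, nu_post=1.0),
                             *pair_rows(0, 1, 2), w0=0.95, w_max=1.0)
        assert conn.w[0, 0] == 1.0


class TestHebbian:
    def test_no_spikes_no_change(self):
        conn, _ = drive_pair(Hebbian(0.1, 0.1), [[0.0]] * 5, [[0.0]] * 5)
        assert conn.w[0, 0] == 0.5

    def test_pre_before_post_positive(self):
        nu_pre, nu_post = 4e-3, 9e-3
        conn, _ = drive_pair(Hebbian(nu_pre, nu_post), *pair_rows(0, 3, 4))
        assert conn.w[0, 0] - 0.5 == pytest.approx(
            nu_pre * np.exp(-3 / TRACE_TAU), rel=1e-12
        )

    def test_timing_reversal_mirrored_magnitude(self):
        """Post-then-pre gives a positive update of the mirrored magnitude."""
        nu = 5e-3
        fwd, _ = drive_pair(Hebbian(nu, nu), *pair_rows(0, 3, 4))
        rev, _ = drive_pair(Hebbian(nu, nu), *pair_rows(3, 0, 4))
        assert rev.w[0, 0] - 0.5 > 0
        assert rev.w[0, 0] == pytest.approx(fwd.w[0, 0], rel=1e-12)

    def test_coincidence_only_flag(self):
        conn, _ = drive_pair(Hebbian(1e-3, 1e-3, coincidence_only=True),
                             *pair_rows(0, 3, 4))
        assert conn.w[0, 0] == 0.5  # no same-step coincidence, no update


def mstdp_oracle(pre_rows, post_rows, rewards, w0, gamma, tau_plus, tau_minus,
                 dt, tau_z=None):
    """Independent per-step recurrence for MSTDP / MSTDPET (scalars only)."""
    p_plus = p_minus = 0.0
    z = 0.0
    w = [w0]
    for s_pre, s_post, r in zip(pre_rows, post_rows, rewards):
        s_pre, s_post = s_pre[0], s_post[0]
        p_plus = p_plus * np.exp(-dt / tau_plus) + s_pre
        p_minus = p_minus * np.exp(-dt / tau_minus) - s_post
        xi = p_plus * s_post + s_pre * p_minus
        if tau_z is None:
            w.append(w[-1] + gamma * r * xi * dt)
        else:
            z = z * np.exp(-dt / tau_z) + xi
            w.append(w[-1] + gamma * r * z * dt)
    return np.array(w[1:])


class TestMSTDP:
    def test_zero_reward_gates_all_updates(self):
        rng = np.random.default_rng(3)
        pre = (rng.random((20, 1)) < 0.5).astype(float)
        post = (rng.random((20, 1)) < 0.5).astype(float)
        conn, _ = drive_pair(MSTDP(), pre, post, rewards=[0.0] * 20)
        assert conn.w[0, 0] == 0.5

    def test_missing_reward_is_configuration_error(self):
        with pytest.raises(ConfigurationError, match="reward"):
            drive_pair(MSTDP(), [[1.0]], [[1.0]], rewards=None)

    def test_odd_in_reward(self):
        rng = np.random.default_rng(4)
        pre = (rng.random((15, 1)) < 0.4).astype(float)
        post = (rng.random((15, 1)) < 0.4).astype(float)
        rewards = rng.normal(size=15)
        up, _ = drive_pair(MSTDP(), pre, post, rewards=rewards)
        down, _ = drive_pair(MSTDP(), pre, post, rewards=-rewards)
        assert up.w[0, 0] - 0.5 == pytest.approx(-(down.w[0, 0] - 0.5),
                                                 rel=1e-12)

    def test_pre_before_post_sign_follows_reward(self):
        rows = pair_rows(0, 3, 4)
        plus, _ = drive_pair(MSTDP(), *rows, rewards=[1.0] * 4)
        minus, _ = drive_pair(MSTDP(), *rows, rewards=[-1.0] * 4)
        assert plus.w[0, 0] > 0.5
        assert minus.w[0, 0] - 0.5 == pytest.approx(-(plus.w[0, 0] - 0.5))

    def test_scripted_episode_matches_oracle(self):
        rng = np.random.default_rng(11)
        pre = (rng.random((10, 1)) < 0.5).astype(float)
        post = (rng.random((10, 1)) < 0.5).astype(float)
        rewards = rng.normal(size=10)
        rule = MSTDP(gamma=0.2, tau_plus=20.0, tau_minus=15.0)
        _, history = drive_pair(rule, pre, post, rewards=rewards)
        expected = mstdp_oracle(pre, post, rewards, 0.5, 0.2, 20.0, 15.0, 1.0)
        np.testing.assert_array_equal(history[:, 0, 0], expected)


class TestMSTDPET:
    def test_delayed_reward_credit_decays_with_tau_z(self):
        """Reward k steps after a pairing earns exp(-k dt / tau_z) credit."""
        tau_z = 25.0
        base = None
        for k in (0, 3, 6):
            length = 4 + k
            pre = [[1.0] if t == 0 else [0.0] for t in range(length)]
            post = [[1.0] if t == 3 else [0.0] for t in range(length)]
            rewards = [1.0 if t == 3 + k else 0.0 for t in range(length)]
            conn, _ = drive_pair(MSTDPET(tau_z=tau_z), pre, post,
                                 rewards=rewards)
            dw = conn.w[0, 0] - 0.5
            if base is None:
                base = dw
            else:
                assert dw == pytest.approx(base * np.exp(-k / tau_z),
                                           rel=1e-10)

    def test_small_tau_z_approaches_mstdp(self):
        """With tau_z = dt/10 the eligibility barely persists one step."""
        rows = pair_rows(0, 3, 4)
        rewards = [1.0] * 4
        et, _ = drive_pair(MSTDPET(tau_z=0.1), *rows, rewards=rewards)
        plain, _ = drive_pair(MSTDP(), *rows, rewards=rewards)
        assert et.w[0, 0] - 0.5 == pytest.approx(plain.w[0, 0] - 0.5,
                                                 rel=0.05)

    def test_zero_reward_weight_constant_eligibility_evolves(self):
        rule = MSTDPET()
        conn, _ = drive_pair(rule, *pair_rows(0, 2, 5), rewards=[0.0] * 5)
        assert conn.w[0, 0] == 0.5
        assert np.abs(rule.z).sum() > 0

    def test_scripted_episode_matches_oracle(self):
        rng = np.random.default_rng(12)
        pre = (rng.random((10, 1)) < 0.5).astype(float)
        post = (rng.random((10, 1)) < 0.5).astype(float)
        rewards = rng.normal(size=10)
        rule = MSTDPET(gamma=0.1, tau_plus=20.0, tau_minus=20.0, tau_z=25.0)
        _, history = drive_pair(rule, pre, post, rewards=rewards)
        expected = mstdp_oracle(pre, post, rewards, 0.5, 0.1, 20.0, 20.0, 1.0,
                                tau_z=25.0)
        np.testing.assert_array_equal(history[:, 0, 0], expected)


class TestLocality:
    @pytest.mark.parametrize("rule_factory", [
        lambda: Hebbian(1e-2, 1e-2),
        lambda: PostPre(1e-2, 1e-2),
        lambda: MSTDP(),
        lambda: MSTDPET(),
    ])
    def test_unrelated_neurons_do_not_affect_synapse(self, rule_factory):
        """dw(i,j) depends only on neurons i and j (and global reward)."""
        rng = np.random.default_rng(21)
        pre_a = (rng.random((12, 3)) < 0.4).astype(float)
        post_a = (rng.random((12, 3)) < 0.4).astype(float)
        pre_b, post_b = pre_a.copy(), post_a.copy()
        # perturb every neuron except pre 0 and post 0
        pre_b[:, 1:] = (rng.random((12, 2)) < 0.6).astype(float)
        post_b[:, 1:] = (rng.random((12, 2)) < 0.6).astype(float)
        rewards = list(rng.normal(size=12))
        conn_a, _ = drive_pair(rule_factory(), pre_a, post_a, rewards=rewards,
                               n_pre=3, n_post=3)
        conn_b, _ = drive_pair(rule_factory(), pre_b, post_b, rewards=rewards,
                               n_pre=3, n_post=3)
        assert conn_a.w[0, 0] == conn_b.w[0, 0]
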