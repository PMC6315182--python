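"""Plasticity rules attached to connections.

All rules are local: the update to synapse (i, j) depends only on pre-neuron
i's spike/trace, post-neuron j's spike/trace, per-synapse state, and global
scalars (learning rates, reward).  Rules run once per simulation step, after
both populations have stepped, on the current spike vectors and the traces
maintained by the nodes module (decay-then-set schedule).  The connection
clamps weights to bounds and re-applies any structural mask immediately after
each update.

The reward-modulated rules follow the discrete-time formulation of
reward-modulated STDP with (MSTDPET) and without (MSTDP) an eligibility
trace: per-neuron timing trackers ``P+`` (pre) and ``P-`` (post, negative
sign) yield an instantaneous STDP quantity

    xi_ij = P+_i * s_post_j + s_pre_i * P-_j

and the weight change is ``gamma * r * xi * dt`` (MSTDP) or accumulates
``xi`` into a per-synapse eligibility ``z`` with decay ``exp(-dt/tau_z)``
and applies ``gamma * r * z * dt`` (MSTDPET).
"""

from __future__ import annotations

import numpy as np

from .utils import ConfigurationError

__all__ = ["LearningRule", "Hebbian", "PostPre", "MSTDP", "MSTDPET"]


class LearningRule:
    """Base class: per-connection plasticity with optional internal state."""

    def attach(self, connection) -> None:
        """Size any per-synapse/per-neuron state to the connection."""

    def update(self, connection, dt: float, reward=None) -> None:
        raise NotImplementedError

    def reset_state(self) -> None:
        """Clear timing/eligibility state (called on network reset)."""

    @staticmethod
    def _pre_post(connection):
        src, tgt = connection.source, connection.target
        return src.s, src.x, tgt.s, tgt.x


class Hebbian(LearningRule):
    """Symmetric trace-based Hebbian strengthening.

    dw = nu_pre * outer(x_pre, s_post) + nu_post * outer(s_pre, x_post)

    Every near-coincident pre/post pairing potentiates, in either order.
    With ``coincidence_only=True`` the traces are replaced by the current
    spike vectors, so only same-step coincidences contribute.
    """

    def __init__(self, nu_pre=1e-4, nu_post=1e-2, coincidence_only=False):
        if nu_pre < 0 or nu_post < 0:
            raise ValueError("learning rates must be nonnegative")
        self.nu_pre = float(nu_pre)
        self.nu_post = float(nu_post)
        self.coincidence_only = bool(coincidence_only)

    def update(self, connection, dt, reward=None):
        s_pre, x_pre, s_post, x_post = self._pre_post(connection)
        if self.coincidence_only:
            x_pre, x_post = s_pre, s_post
        connection.w += self.nu_pre * np.outer(x_pre, s_post)
        connection.w += self.nu_post * np.outer(s_pre, x_post)


class PostPre(LearningRule):
    """Pair-based STDP with asymmetric learning rates.

    dw = nu_post * outer(x_pre, s_post) - nu_pre * outer(s_pre, x_post)

    A post spike potentiates by the (decayed) pre trace — pre-before-post
    pairings strengthen — and a pre spike depresses by the post trace —
    post-before-pre pairings weaken.
    """

    def __init__(self, nu_pre=1e-4, nu_post=1e-2):
        if nu_pre < 0 or nu_post < 0:
            raise ValueError("learning rates must be nonnegative")
        self.nu_pre = float(nu_pre)
        self.nu_post = float(nu_post)

    def update(self, connection, dt, reward=None):
        s_pre, x_pre, s_post, x_post = self._pre_post(connection)
        connection.w += self.nu_post * np.outer(x_pre, s_post)
        connection.w -= self.nu_pre * np.outer(s_pre, x_post)


class MSTDP(LearningRule):
    """Reward-modulated STDP: the reward scales and signs the STDP update."""

    def __init__(self, gamma=0.1, tau_plus=20.0, tau_minus=20.0):
        if tau_plus <= 0 or tau_minus <= 0:
            raise ValueError("STDP window time constants must be positive")
        self.gamma = float(gamma)
        self.tau_plus = float(tau_plus)
        self.tau_minus = float(tau_minus)
        self.p_plus = None
        self.p_minus = None

    def attach(self, connection):
        self.p_plus = np.zeros(connection.source.n)
        self.p_minus = np.zeros(connection.target.n)

    def _xi(self, connection, dt):
        s_pre, _, s_post, _ = self._pre_post(connection)
        if self.p_plus is None:
            self.attach(connection)
        self.p_plus = self.p_plus * np.exp(-dt / self.tau_plus) + s_pre
        self.p_minus = self.p_minus * np.exp(-dt / self.tau_minus) - s_post
        return np.outer(self.p_plus, s_post) + np.outer(s_pre, self.p_minus)

    def update(self, connection, dt, reward=None):
        if reward is None:
            raise ConfigurationError(
                "MSTDP requires a reward signal; pass reward= to run()"
            )
        connection.w += self.gamma * float(reward) * self._xi(connection, dt) * dt

    def reset_state(self):
        if self.p_plus is not None:
            self.p_plus[:] = 0.0
            self.p_minus[:] = 0.0


class MSTDPET(MSTDP):
    """MSTDP with an eligibility trace: delayed reward credits recent pairings."""

    def __init__(self, gamma=0.1, tau_plus=20.0, tau_minus=20.0, tau_z=25.0):
        super().__init__(gamma=gamma, tau_plus=tau_plus, tau_minus=tau_minus)
        if tau_z <= 0:
            raise ValueError("tau_z must be positive")
        self.tau_z = float(tau_z)
        self.z = None

    def attach(self, connection):
        super().attach(connection)
        self.z = np.zeros((connection.source.n, connection.target.n))

    def update(self, connection, dt, reward=None):
        if reward is None:
            raise ConfigurationError(
                "MSTDPET requires a reward signal; pass reward= to run()"
            )
        if self.z is None:
            self.attach(connection)
        self.z = self.z * np.exp(-dt / self.tau_z) + self._xi(connection, dt)
        connection.w += self.gamma * float(reward) * self.z * dt

    def reset_state(self):
        super().reset_state()
        if self.z is not None:
            self.z[:] = 0.0
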