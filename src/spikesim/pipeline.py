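"""The interaction loop between a network, an encoder, an action function,
and an environment.

Environments follow the de-facto reinforcement-learning API — ``reset()``,
``step(action) -> (observation, reward, done, info)``, ``close()``,
``render()`` plus an ``action_space_n`` attribute — so third-party
environments plug in unmodified.  A dataset wrapper exposes any in-memory
array dataset through the same interface (actions ignored, rewards zero),
and a deterministic scripted toy environment ships for exercising the RL
loop without any external dependency.

Each :meth:`Pipeline.step` runs one four-step cycle:

1. select an action from the output layer's spikes summed over the previous
   observation's simulation window;
2. step the environment with it;
3. preprocess the returned observation, difference it against the history
   buffer, and encode it as a spike train of ``sim_time`` steps;
4. run the network on that train, forwarding the reward to any
   reward-modulated learning rules.

On episode end the environment and the network's dynamic state are reset;
weights persist.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import encoding
from .utils import ensure_rng

__all__ = [
    "DatasetEnvironment",
    "ScriptedEnvironment",
    "HistoryBuffer",
    "PipelineConfig",
    "Pipeline",
    "select_multinomial",
    "select_softmax",
]


# -- environments ------------------------------------------------------

class DatasetEnvironment:
    """Expose an in-memory (images, labels) dataset as an environment.

    Actions are ignored and rewards are zero; each ``step`` serves the next
    example and ``done`` flags the end of one pass.  The current example's
    label travels in ``info["label"]``.
    """

    def __init__(self, images, labels=None):
        self.images = np.asarray(images, dtype=float)
        self.labels = None if labels is None else np.asarray(labels)
        self.action_space_n = 1
        self._index = 0

    def reset(self):
        self._index = 0
        return self.images[0]

    def step(self, action):
        self._index += 1
        if self._index >= len(self.images):
            raise RuntimeError("environment exhausted; call reset()")
        obs = self.images[self._index]
        info = {}
        if self.labels is not None:
            info["label"] = int(self.labels[self._index])
        done = self._index == len(self.images) - 1
        return obs, 0.0, done, info

    def render(self):
        pass

    def close(self):
        pass


class ScriptedEnvironment:
    """Deterministic toy environment with 4 actions for testing the RL loop.

    Observations cycle through fixed frames; reward is +1 when the chosen
    action equals ``rewarded_action``, else 0; episodes last
    ``episode_length`` steps.
    """

    def __init__(self, observations=None, rewarded_action=0, episode_length=10):
        if observations is None:
            eye = np.eye(4)
            observations = [np.outer(eye[i % 4], eye[(i + 1) % 4]) for i in range(4)]
        self.observations = [np.asarray(o, dtype=float) for o in observations]
        self.rewarded_action = int(rewarded_action)
        self.episode_length = int(episode_length)
        self.action_space_n = 4
        self._t = 0
        self._done = True

    def reset(self):
        self._t = 0
        self._done = False
        return self.observations[0]

    def step(self, action):
        if self._done:
            raise RuntimeError("episode finished; call reset()")
        if not 0 <= int(action) < self.action_space_n:
            raise ValueError(f"action {action} outside action space")
        self._t += 1
        reward = 1.0 if int(action) == self.rewarded_action else 0.0
        self._done = self._t >= self.episode_length
        obs = self.observations[self._t % len(self.observations)]
        return obs, reward, self._done, {}

    def render(self):
        pass

    def close(self):
        pass


# -- history -----------------------------------------------------------

class HistoryBuffer:
    """Keeps up to ``history_length`` observations stored every ``delta`` steps.

    Stored step indices always form the arithmetic progression
    ``{k*delta, ..., (k+history_length-1)*delta}``.
    """

    def __init__(self, history_length=0, delta=1):
        if history_length < 0:
            raise ValueError("history_length must be >= 0")
        if delta < 1:
            raise ValueError("delta must be >= 1")
        self.history_length = int(history_length)
        self.delta = int(delta)
        self.observations: list[np.ndarray] = []
        self.indices: list[int] = []

    def update(self, obs, step_index: int) -> None:
        """Store ``obs`` if ``step_index`` falls on the delta grid."""
        if self.history_length == 0:
            return
        if step_index % self.delta != 0:
            return
        self.observations.append(np.asarray(obs, dtype=float))
        self.indices.append(int(step_index))
        if len(self.observations) > self.history_length:
            self.observations.pop(0)
            self.indices.pop(0)

    def clear(self) -> None:
        self.observations = []
        self.indices = []


# -- action selection --------------------------------------------------

def _grouped_sums(spike_sums, n_actions):
    spike_sums = np.asarray(spike_sums, dtype=float).reshape(-1)
    if spike_sums.size == n_actions:
        return spike_sums
    if spike_sums.size % n_actions != 0:
        raise ValueError(
            f"cannot map {spike_sums.size} neurons onto {n_actions} actions"
        )
    return spike_sums.reshape(n_actions, -1).sum(axis=1)


def select_multinomial(spike_sums, n_actions, rng=None) -> int:
    """Sample an action from spike counts treated as a probability vector.

    Output neurons are grouped evenly over actions when they outnumber them.
    All-zero counts fall back to uniform sampling.
    """
    rng = ensure_rng(rng)
    sums = _grouped_sums(spike_sums, n_actions)
    if (sums < 0).any():
        raise ValueError("spike sums must be nonnegative")
    total = sums.sum()
    p = np.full(n_actions, 1.0 / n_actions) if total == 0 else sums / total
    return int(rng.choice(n_actions, p=p))


def select_softmax(spike_sums, n_actions, temperature=1.0, rng=None) -> int:
    """Sample an action from a softmax over (grouped) output spike counts."""
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    rng = ensure_rng(rng)
    sums = _grouped_sums(spike_sums, n_actions)
    logits = sums / temperature
    logits -= logits.max()
    p = np.exp(logits)
    p /= p.sum()
    return int(rng.choice(n_actions, p=p))


# -- the pipeline ------------------------------------------------------

@dataclass
class PipelineConfig:
    """Loop configuration.

    ``sim_time`` is the per-observation simulation duration in time steps;
    ``history_length = 0`` disables observation differencing; ``delta`` is
    the interval (in environment steps) at which observations enter the
    history buffer.
    """

    history_length: int = 0
    delta: int = 1
    sim_time: int = 1
    preprocess_ops: list = field(default_factory=list)
    render_interval: int | None = None

    def __post_init__(self):
        if self.history_length < 0 or self.delta < 1 or self.sim_time < 1:
            raise ValueError("invalid pipeline configuration")


class Pipeline:
    """Couples a network, an environment, an encoder, and an action function.

    Parameters
    ----------
    network : Network
    environment : object with the reset/step/close/render interface
    encoder : callable(data, time, dt, rng) -> SpikeTrain
        e.g. ``spikesim.poisson`` or ``spikesim.bernoulli``.
    action_function : callable(spike_sums, n_actions, rng) -> int, optional
        Defaults to always-0 (appropriate for dataset environments).
    input_layer, output_layer : str
        Names of the layers receiving encoded observations and read for
        action selection.
    """

    def __init__(self, network, environment, encoder, input_layer,
                 output_layer=None, action_function=None,
                 config: PipelineConfig | None = None):
        self.network = network
        self.env = environment
        self.encoder = encoder
        self.input_layer = input_layer
        self.output_layer = output_layer
        self.action_function = action_function
        self.config = config or PipelineConfig()
        self.history = HistoryBuffer(self.config.history_length, self.config.delta)
        self.step_count = 0
        self.episode_reward = 0.0
        self.episode_rewards: list[float] = []
        self.last_output_sums = None
        self.last_info: dict = {}
        self.last_records = None
        self._obs_index = 0
        self.env.reset()

    # -- one four-step cycle -------------------------------------------
    def step(self):
        """Run one cycle; returns (action, reward, done, info)."""
        cfg = self.config
        if self.last_output_sums is None and self.output_layer is not None:
            self.last_output_sums = np.zeros(
                self.network.layers[self.output_layer].n
            )
        if self.action_function is not None:
            action = self.action_function(
                self.last_output_sums, self.env.action_space_n,
                rng=self.network.rng,
            )
        else:
            action = 0
        obs, reward, done, info = self.env.step(action)
        processed = encoding.preprocess(obs, cfg.preprocess_ops)
        delivered = encoding.difference(processed, self.history.observations)
        self.history.update(processed, self._obs_index)
        self._obs_index += 1
        time = cfg.sim_time * self.network.dt
        train = self.encoder(
            delivered, time=time, dt=self.network.dt, rng=self.network.rng
        )
        records = self.network.run(
            inputs={self.input_layer: train}, time=time, reward=reward
        )
        self.last_records = records
        if self.output_layer is not None:
            self.last_output_sums = records[self.output_layer].sum(axis=0).astype(
                float
            )
        self.step_count += 1
        self.episode_reward += reward
        self.last_info = info
        if cfg.render_interval and self.step_count % cfg.render_interval == 0:
            self.env.render()
        if done:
            self.episode_rewards.append(self.episode_reward)
            self.episode_reward = 0.0
            self.env.reset()
            self.network.reset_state()
            self.history.clear()
            self._obs_index = 0
            self.last_output_sums = None
        return action, reward, done, info
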