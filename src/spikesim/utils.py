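"""Small shared helpers: RNG normalization and error types."""

from __future__ import annotations

import numpy as np

__all__ = ["ensure_rng", "NetworkLoadError", "ConfigurationError"]


class NetworkLoadError(RuntimeError):
    """Raised when a serialized network cannot be restored."""


class ConfigurationError(ValueError):
    """Raised when a component is driven with an invalid or missing setting."""


def ensure_rng(seed_or_rng=None) -> np.random.Generator:
    """Return a ``numpy.random.Generator`` from a seed, a Generator, or None."""
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)
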