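"""Random-number plumbing: one place that turns seeds into Generators."""

from __future__ import annotations

import numpy as np

__all__ = ["resolve_rng"]


def resolve_rng(seed) -> np.random.Generator:
    """Return a Generator from a seed, a Generator, or None (fresh entropy)."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)
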