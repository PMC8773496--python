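"""Seed plumbing: every stochastic routine accepts an int, a SeedSequence or None."""

from __future__ import annotations

import numpy as np

__all__ = ["as_seedseq"]


def as_seedseq(seed) -> np.random.SeedSequence:
    if isinstance(seed, np.random.SeedSequence):
        return seed
    if isinstance(seed, np.random.Generator):
        raise TypeError("pass an int or SeedSequence, not a Generator")
    return np.random.SeedSequence(seed)
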