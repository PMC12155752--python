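"""Deterministic seed derivation.

Every stochastic component takes an explicit integer seed; sub-streams are
derived with ``numpy.random.SeedSequence`` so that cohorts, channels and
training steps are reproducible and mutually independent.
"""

from __future__ import annotations

import numpy as np

_MASK31 = (1 << 31) - 1


def derive_seed(*keys: int) -> int:
    """Derive a 31-bit child seed from an ordered tuple of integer keys."""
    ss = np.random.SeedSequence(list(int(k) for k in keys))
    return int(ss.generate_state(1)[0]) & _MASK31


def rng_from(*keys: int) -> np.random.Generator:
    """A fresh PCG64 generator keyed by the given integers."""
    return np.random.default_rng(np.random.SeedSequence([int(k) for k in keys]))
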