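"""Deterministic seed derivation.

All randomness in a run flows from a single root seed.  Independent
consumers (query draws, committee bootstraps, evaluation classifiers, ...)
get their own streams so that, e.g., an active-learning run with tau = 0.5
consumes the query stream identically to a random-learning run with the
same root seed.
"""

from __future__ import annotations

import numpy as np

# stream identifiers; fixed constants so derived seeds are stable
STREAM_QUERY = 101
STREAM_COMMITTEE = 102
STREAM_BOOTSTRAP = 103
STREAM_EVAL = 104
STREAM_POOL = 105


def child_rng(root_seed: int, *keys: int) -> np.random.Generator:
    """A generator seeded deterministically from ``root_seed`` and ``keys``."""
    return np.random.default_rng(np.random.SeedSequence([int(root_seed), *map(int, keys)]))


def child_seed(root_seed: int, *keys: int) -> int:
    """A 31-bit integer seed (usable as sklearn ``random_state``)."""
    ss = np.random.SeedSequence([int(root_seed), *map(int, keys)])
    return int(ss.generate_state(1)[0] % (2**31))
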