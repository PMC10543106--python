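"""Deterministic seed derivation shared across modules."""

from __future__ import annotations

import numpy as np


def subseed(seed: int, k: int) -> int:
    """Independent child seed k of a master seed (stable across runs)."""
    return int(np.random.SeedSequence([int(seed), int(k)]).generate_state(1)[0]
               % (2 ** 31))
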