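"""Seed plumbing: every stage accepts an int, None, or a SeedSequence."""

from __future__ import annotations

import numpy as np


def as_seedseq(seed) -> np.random.SeedSequence:
    """Coerce an int / None / SeedSequence into a SeedSequence."""
    if isinstance(seed, np.random.SeedSequence):
        return seed
    return np.random.SeedSequence(seed)
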