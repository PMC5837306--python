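"""Deterministic random substream derivation.

One master seed governs a whole study; each (scenario, replicate) pair gets
an independent PCG64 stream keyed by ``(seed, stream_key, replicate_index)``
so that any replicate can be regenerated in isolation without running the
ones before it.
"""

from __future__ import annotations

import numpy as np


def replicate_rng(seed: int, stream_key: int, replicate_index: int) -> np.random.Generator:
    """Return the generator for one replicate of one scenario."""
    ss = np.random.SeedSequence((int(seed), int(stream_key), int(replicate_index)))
    return np.random.Generator(np.random.PCG64(ss))
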