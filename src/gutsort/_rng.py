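"""Counter-free deterministic stream splitting.

All randomness in the package flows from one integer seed. Independent
streams for sub-tasks are derived by hashing a tuple of string labels into
the numpy SeedSequence entropy, so modules can be re-run and tested in
isolation without consuming each other's draws.
"""

from __future__ import annotations

import zlib

import numpy as np


def rng_for(seed: int, *labels: str) -> np.random.Generator:
    """Return a Generator for the stream named by ``labels`` under ``seed``."""
    entropy = [int(seed)] + [zlib.crc32(lab.encode()) for lab in labels]
    return np.random.default_rng(np.random.SeedSequence(entropy))
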