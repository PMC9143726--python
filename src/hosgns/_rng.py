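"""Seeded random streams.

Every stochastic routine in the package draws from a named stream derived
from a single integer seed, so a global seed fixes the whole pipeline while
independent stages (initialization, positive sampling, negative sampling,
splits, epidemics) stay decoupled.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["stream"]


def stream(seed: int, name: str = "") -> np.random.Generator:
    """Return a Generator for the stream `name` under the global `seed`."""
    key = zlib.crc32(name.encode("utf-8")) & 0x7FFFFFFF
    return np.random.default_rng(np.random.SeedSequence((int(seed), key)))
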