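"""Deterministic per-stage random substreams.

One master seed drives a whole run; each stage derives an independent
substream keyed by its own name, so reordering stages (or adding a new
one) never perturbs another stage's draws.
"""

from __future__ import annotations

import zlib

import numpy as np


def substream(seed: int, name: str) -> np.random.Generator:
    """Return a Generator for stage `name` derived from the master `seed`."""
    tag = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, tag]))
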