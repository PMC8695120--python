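"""Named random substreams derived from a single session seed.

Every stochastic component (plant noise, schedule layout, training draws)
pulls its generator from here so that modules are independently reproducible
while still being controlled by one top-level seed.
"""

from __future__ import annotations

import hashlib

import numpy as np


def substream(seed: int, name: str) -> np.random.Generator:
    """Return a Generator for the named substream of ``seed``.

    The substream key is a stable 32-bit hash of ``name``, so the mapping
    never depends on Python's randomized ``hash()``.
    """
    digest = hashlib.blake2s(name.encode("utf-8"), digest_size=4).digest()
    key = int.from_bytes(digest, "little")
    return np.random.default_rng(np.random.SeedSequence([int(seed), key]))


def substream_seed(seed: int, name: str) -> int:
    """A derived integer seed (< 2**31) for APIs that want a plain int."""
    digest = hashlib.blake2s(f"{int(seed)}:{name}".encode("utf-8"), digest_size=8).digest()
    return int.from_bytes(digest, "little") % (2**31 - 1)
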