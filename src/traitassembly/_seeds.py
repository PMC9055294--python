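"""Counter-free seed fan-out.

Every stochastic component derives its generator from the master seed plus
a tuple of string tags via ``SeedSequence`` spawn keys, so adding one
component never shifts another component's stream.
"""

from __future__ import annotations

import zlib

import numpy as np


def _key(tags: tuple) -> tuple[int, ...]:
    return tuple(zlib.crc32(str(t).encode("utf8")) for t in tags)


def child_rng(master_seed: int, *tags) -> np.random.Generator:
    """Deterministic child generator for a named component."""
    ss = np.random.SeedSequence(int(master_seed), spawn_key=_key(tags))
    return np.random.default_rng(ss)


def child_seed(master_seed: int, *tags) -> int:
    """Deterministic 31-bit child seed for APIs that take plain integers."""
    ss = np.random.SeedSequence(int(master_seed), spawn_key=_key(tags))
    return int(ss.generate_state(1, np.uint32)[0] & 0x7FFFFFFF)
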