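"""Deterministic substream management.

A single user seed fans out into independent substreams keyed by stage name
and entity index, so that e.g. adding traits to a simulation does not
perturb the genotypes, and results are reproducible bit-for-bit for a
given seed regardless of call order.
"""

from __future__ import annotations

import zlib

import numpy as np


def _key_to_ints(key) -> list[int]:
    out = []
    for part in key:
        if isinstance(part, str):
            out.append(zlib.crc32(part.encode("utf-8")))
        elif isinstance(part, (int, np.integer)):
            out.append(int(part) & 0xFFFFFFFF)
        else:
            raise TypeError(f"substream key parts must be str or int, got {type(part)}")
    return out


def substream(seed: int, *key) -> np.random.Generator:
    """Return a Generator for the substream identified by ``(seed, *key)``."""
    seq = np.random.SeedSequence(entropy=int(seed) & 0x7FFFFFFF, spawn_key=tuple(_key_to_ints(key)))
    return np.random.default_rng(seq)
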