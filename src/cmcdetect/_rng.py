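"""Seeding helpers: all randomness flows from one master seed via named substreams."""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream", "child_seed"]


def _name_key(name: str) -> int:
    # stable across processes/platforms (hash() is salted, so not usable here)
    return zlib.crc32(name.encode("utf-8"))


def substream(master_seed: int, name: str) -> np.random.Generator:
    """Return an independent generator for the named substream of a master seed."""
    ss = np.random.SeedSequence([int(master_seed), _name_key(name)])
    return np.random.default_rng(ss)


def child_seed(master_seed: int, name: str) -> int:
    """A derived integer seed (< 2**31) for APIs that want a plain int."""
    ss = np.random.SeedSequence([int(master_seed), _name_key(name)])
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))
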