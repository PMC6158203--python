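"""Seeding discipline: every stochastic stage draws from a named substream.

All randomness in a run flows from one integer seed. A stage asks for its own
generator via :func:`substream`, keyed by a stable string name, so adding or
reordering stages never perturbs the draws of another stage and two runs with
the same config are bit-identical.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream"]


def substream(seed: int, name: str) -> np.random.Generator:
    """Return a deterministic PCG64 generator for stage ``name``.

    The stream key is CRC32(name), combined with the run seed through
    :class:`numpy.random.SeedSequence` spawn keys.
    """
    if not isinstance(seed, (int, np.integer)):
        raise TypeError(f"seed must be an integer, got {type(seed).__name__}")
    key = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence(int(seed), spawn_key=(key,)))
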