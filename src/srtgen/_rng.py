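"""Deterministic random-stream management.

A single user-facing seed is expanded into independent substreams keyed by a
path of labels (stage name, gene index, ...). Streams are derived with
``numpy.random.SeedSequence`` so that adding genes or stages never perturbs
the draws of existing ones, which keeps regression tests stable.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["spawn_rng", "key_ints"]


def key_ints(*path) -> list[int]:
    """Map a label path to a stable list of 32-bit ints."""
    out = []
    for p in path:
        if isinstance(p, (int, np.integer)):
            out.append(int(p) & 0x7FFFFFFF)
        else:
            out.append(zlib.crc32(str(p).encode("utf-8")))
    return out


def spawn_rng(seed: int, *path) -> np.random.Generator:
    """Return a Generator for substream ``path`` of the global ``seed``.

    The same (seed, path) always yields the same stream; distinct paths give
    statistically independent streams.
    """
    ss = np.random.SeedSequence([int(seed) & 0x7FFFFFFF, *key_ints(*path)])
    return np.random.default_rng(ss)
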