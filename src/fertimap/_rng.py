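"""Named random substreams.

All randomness in a run flows from one integer seed.  Stages (and strata
within stages) draw from child generators keyed by name, so rerunning a
single stage reproduces its stream exactly regardless of what ran before.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["child_rng", "child_seed"]


def child_seed(seed: int, *keys: str | int) -> list[int]:
    """Deterministic SeedSequence entropy for a named substream."""
    ent: list[int] = [int(seed)]
    for k in keys:
        ent.append(zlib.crc32(str(k).encode("utf-8")))
    return ent


def child_rng(seed: int, *keys: str | int) -> np.random.Generator:
    """Generator for the substream named by ``keys`` under a root ``seed``."""
    return np.random.Generator(np.random.PCG64(np.random.SeedSequence(child_seed(seed, *keys))))
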