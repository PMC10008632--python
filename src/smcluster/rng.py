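"""Seeded random-number substreams.

One master seed determines every random draw in a run.  Each modality
(hole widths, axis noise, count noise, angles, speckle) draws from its own
named substream, so adding a new modality never shifts the draws of the
existing ones and equal configurations produce byte-identical outputs.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream"]


def substream(seed: int, name: str) -> np.random.Generator:
    """Return a Generator for the named substream of ``seed``.

    The substream key is a CRC32 of the name, combined with the master
    seed through a SeedSequence, so streams are independent and stable
    across sessions and platforms.
    """
    key = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed), key]))
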