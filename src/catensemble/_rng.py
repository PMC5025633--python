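"""Seed handling.

A single integer seed determines every random draw in the package. Streams
are numpy PCG64 generators. Named stages (CLI subcommands, study cells)
derive independent substreams from the global seed via
``SeedSequence([seed, crc32(stage_name)])``, so adding a stage never
perturbs the draws of an existing one.
"""

from __future__ import annotations

import zlib

import numpy as np


def as_rng(seed_or_rng) -> np.random.Generator:
    """Coerce an int seed, ``None`` or an existing Generator to a Generator."""
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    # duck-typed generators (e.g. test stubs) pass through untouched
    if hasattr(seed_or_rng, "integers") and hasattr(seed_or_rng, "choice"):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Substream for a named stage, derived from the global integer seed."""
    key = zlib.crc32(stage.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed), key]))
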