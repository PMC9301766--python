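"""Named random substreams derived from a single master seed.

Every stochastic stage of the pipeline draws from its own named stream, so
enabling or disabling one stage never perturbs the draws of another.
"""
from __future__ import annotations

import zlib

import numpy as np


def seed_sequence(master_seed: int, name: str) -> np.random.SeedSequence:
    """SeedSequence for the substream ``name`` under ``master_seed``."""
    return np.random.SeedSequence(
        [int(master_seed) & 0x7FFFFFFF, zlib.crc32(name.encode("utf-8"))]
    )


def substream(master_seed: int, name: str) -> np.random.Generator:
    """Independent, reproducible generator for a named stage."""
    return np.random.default_rng(seed_sequence(master_seed, name))


def child_int_seed(master_seed: int, name: str) -> int:
    """A plain integer seed (< 2**31) for libraries that take one."""
    return int(substream(master_seed, name).integers(2**31))
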