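"""Shared helpers: seeded random substreams and small sequence utilities."""

from __future__ import annotations

import zlib

import numpy as np

DNA = "ACGT"


def substream(seed: int, label: str) -> np.random.Generator:
    """Return a Generator for a named substream of the run-level seed.

    Every source of randomness in the package draws from a substream keyed by
    a stage/cell label, so adding a stage or reordering calls never perturbs
    the draws of another stage. The label is hashed with CRC32, which is
    stable across platforms and Python versions (unlike ``hash``).
    """
    return np.random.default_rng(
        np.random.SeedSequence([int(seed) & 0x7FFFFFFF, zlib.crc32(label.encode())])
    )


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(DNA[i] for i in rng.integers(0, 4, size=int(length)))


def rna_to_dna(seq: str) -> str:
    return seq.upper().replace("U", "T")


def dna_to_rna(seq: str) -> str:
    return seq.upper().replace("T", "U")
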