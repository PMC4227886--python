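"""Shared sequence helpers and the per-operation random-stream policy."""

from __future__ import annotations

import zlib

import numpy as np

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

VALID_BASES = frozenset("ACGTN")


def normalize_seq(seq: str) -> str:
    """Uppercase a nucleotide string and convert RNA U to DNA T.

    Raises ValueError on characters outside A/C/G/T/U/N.
    """
    s = seq.upper().replace("U", "T")
    if not set(s) <= VALID_BASES:
        bad = sorted(set(s) - VALID_BASES)
        raise ValueError(f"non-nucleotide characters in sequence: {bad}")
    return s


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def to_rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


def stream(seed: int, name: str) -> np.random.Generator:
    """Named random substream.

    Every operation derives its generator from (seed, name) so that adding or
    reordering operations never perturbs the draws of another one.
    """
    return np.random.default_rng([seed & 0x7FFFFFFF, zlib.crc32(name.encode())])
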