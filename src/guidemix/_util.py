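"""Small shared helpers: sequence alphabet checks, complements, seeded RNG."""

from __future__ import annotations

import hashlib

import numpy as np

DNA_ALPHABET = frozenset("ACGT")

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (case preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


def gc_fraction(seq: str) -> float:
    if not seq:
        raise ValueError("empty sequence")
    s = seq.upper()
    return (s.count("G") + s.count("C")) / len(s)


def check_dna(seq: str, name: str = "sequence") -> str:
    s = seq.upper()
    bad = set(s) - DNA_ALPHABET
    if bad:
        raise ValueError(f"{name} contains non-ACGT characters: {sorted(bad)}")
    return s


def rna(seq: str) -> str:
    """DNA-letter string to RNA letters (T -> U)."""
    return seq.upper().replace("T", "U")


def derive_seed(seed: int, *tags: str) -> int:
    """Stable stream-specific seed below 2**31 derived from a master seed."""
    h = hashlib.sha256(("%d:" % seed + ":".join(tags)).encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31 - 1)


def rng_for(seed: int, *tags: str) -> np.random.Generator:
    return np.random.default_rng(derive_seed(seed, *tags))
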