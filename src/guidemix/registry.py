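"""Canonical feature registry for CRISPRi guide-efficiency models.

The model consumes 138 features per observation, split into a fixed-effect
block describing the guide itself (129 columns, usable at design time with
nothing but the target sequence) and a random-effect block describing the
targeted gene and the source screen (9 columns, absorbed by the per-gene
linear model during training and not needed for prediction).

Fixed block layout
------------------
* 120 one-hot sequence indicators over the 30-nt target context
  (4 nt upstream, the 20-nt protospacer G1..G20, the PAM P1..P3, 3 nt
  downstream), position-major with channel order A, C, G, T;
* 4 minimum-free-energy features (guide:target DNA hybrid, 8-nt seed
  hybrid, guide homodimer, guide monomer fold);
* absolute and relative distance to the start codon, distance to the
  transcription-unit start, longest homopolymer run in the spacer, and an
  indicator for targeting the first gene of its operon.

Random block: min/max expression over growth, gene GC content and length,
the number of downstream genes and of downstream essential genes in the
operon, codon adaptation index, and two treatment-coded dataset indicators.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

CONTEXT_POSITIONS: tuple[str, ...] = (
    tuple(f"-{i}" for i in range(4, 0, -1))
    + tuple(f"G{i}" for i in range(1, 21))
    + ("P1", "P2", "P3")
    + tuple(f"+{i}" for i in range(1, 4))
)

CHANNELS: tuple[str, ...] = ("A", "C", "G", "T")

THERMO_NAMES: tuple[str, ...] = (
    "mfe_hybrid",
    "mfe_seed_hybrid",
    "mfe_homodimer",
    "mfe_monomer",
)

SCALAR_GUIDE_NAMES: tuple[str, ...] = (
    "dist_start_codon",
    "rel_dist",
    "dist_tu_start",
    "homopolymer",
    "targets_first_gene",
)

RANDOM_NAMES: tuple[str, ...] = (
    "expr_min",
    "expr_max",
    "gene_gc",
    "gene_length",
    "n_downstream_genes",
    "n_downstream_essential",
    "cai",
    "dataset_ind_1",
    "dataset_ind_2",
)


def one_hot_names() -> list[str]:
    return [f"{pos}_{ch}" for pos in CONTEXT_POSITIONS for ch in CHANNELS]


@dataclass(frozen=True)
class FeatureRegistry:
    """Ordered names of the fixed (guide) and random (gene) feature blocks."""

    fixed_names: tuple[str, ...] = field(
        default_factory=lambda: tuple(one_hot_names())
        + THERMO_NAMES
        + SCALAR_GUIDE_NAMES
    )
    random_names: tuple[str, ...] = RANDOM_NAMES

    def __post_init__(self) -> None:
        if len(self.fixed_names) != 129:
            raise ValueError(
                f"fixed block must have 129 features, got {len(self.fixed_names)}"
            )
        if len(self.random_names) != 9:
            raise ValueError(
                f"random block must have 9 features, got {len(self.random_names)}"
            )

    @property
    def n_fixed(self) -> int:
        return len(self.fixed_names)

    @property
    def n_random(self) -> int:
        return len(self.random_names)

    @property
    def n_total(self) -> int:
        return self.n_fixed + self.n_random

    def content_hash(self) -> str:
        import hashlib

        payload = "|".join(self.fixed_names) + "||" + "|".join(self.random_names)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def one_hot_context(context30: str) -> np.ndarray:
    """One-hot encode a 30-nt target context into a 120-vector.

    Layout is position-major: entry ``4*pos + channel`` with channels in
    A, C, G, T order, so each consecutive 4-block is the indicator for one
    position and sums to exactly 1.
    """
    s = context30.upper()
    if len(s) != 30:
        raise ValueError(f"context must be 30 nt, got {len(s)}")
    vec = np.zeros(120, dtype=float)
    for pos, base in enumerate(s):
        try:
            ch = CHANNELS.index(base)
        except ValueError:
            raise ValueError(
                f"non-ACGT base {base!r} at context position {pos} "
                f"({CONTEXT_POSITIONS[pos]})"
            ) from None
        vec[4 * pos + ch] = 1.0
    return vec


def decode_one_hot(vec: np.ndarray) -> str:
    """Invert :func:`one_hot_context` (used as a round-trip check)."""
    arr = np.asarray(vec, dtype=float).reshape(30, 4)
    if not np.all(arr.sum(axis=1) == 1.0):
        raise ValueError("not a valid one-hot context encoding")
    return "".join(CHANNELS[int(i)] for i in arr.argmax(axis=1))
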