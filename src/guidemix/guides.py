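"""Candidate-guide enumeration for CRISPRi with dCas9 (NGG PAM).

Effective silencing inside an ORF requires the guide to anneal to the
coding (non-template) strand, so the protospacer-plus-PAM is read on the
template strand. On the mRNA-sense sequence this appears as a CCN motif
followed by the 20-nt target: for CCN at sense offset ``p`` the spacer is
the reverse complement of sense ``[p+3, p+23)`` and the PAM (NGG) the
reverse complement of sense ``[p, p+3)``. The 30-nt context (4 nt upstream,
protospacer, PAM, 3 nt downstream) is reported in protospacer orientation.

Distances to the start codon are anchored at the left edge of the 20-nt
target on the sense strand (the protospacer's PAM-distal end), so a guide
whose target 20-mer starts at the first base of the start codon has
distance 0. Any consistent anchor differs only by a constant offset.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from ._util import check_dna, gc_fraction, revcomp
from .annotation import GeneAnnotation

logger = logging.getLogger(__name__)

BBSI_MOTIFS = ("GAAGAC", "GTCTTC")


@dataclass(frozen=True)
class GuideFilters:
    """Library-design filters: spacer GC bounds (inclusive) and forbidden
    restriction motifs screened on both strands of the spacer."""

    gc_min: float = 0.30
    gc_max: float = 0.85
    forbidden_motifs: tuple[str, ...] = BBSI_MOTIFS


@dataclass(frozen=True)
class GuideSite:
    """One candidate guide target site within a gene."""

    spacer: str
    context30: str
    pam: str
    gene_id: str
    dist_start_codon: int
    rel_dist: float
    dist_tu_start: int
    targets_first_gene: bool

    def __post_init__(self) -> None:
        if len(self.spacer) != 20:
            raise ValueError("spacer must be 20 nt")
        if len(self.context30) != 30:
            raise ValueError("context must be 30 nt")
        if self.context30[25:27] != "GG":
            raise ValueError("context positions P2,P3 must be GG")
        if self.context30[4:24] != self.spacer:
            raise ValueError("context[4:24] must equal the spacer")

    @property
    def guide_id(self) -> str:
        return f"{self.gene_id}_{self.dist_start_codon}"

    @property
    def seed(self) -> str:
        """8-nt PAM-proximal seed region of the spacer (G13..G20)."""
        return self.spacer[12:20]


def homopolymer(spacer: str) -> int:
    """Length of the longest single-nucleotide run in the spacer."""
    s = check_dna(spacer, "spacer")
    best = run = 1
    for prev, cur in zip(s, s[1:]):
        run = run + 1 if cur == prev else 1
        best = max(best, run)
    return best


def enumerate_guides(
    gene: GeneAnnotation,
    genome_context: str,
    filters: GuideFilters = GuideFilters(),
    cds_offset: int | None = None,
) -> list[GuideSite]:
    """Enumerate every coding-strand-targeting NGG guide within a gene.

    ``genome_context`` is the mRNA-sense sequence of the CDS with flanking
    genomic sequence on both sides (>= 7 nt recommended so that boundary
    sites keep their full 30-nt context). ``cds_offset`` locates the first
    CDS base within it; if omitted the CDS is located by exact match.

    Sites whose 30-nt context would run off the available sequence are
    skipped with a warning; spacers outside the GC bounds or containing a
    forbidden motif (on either strand) are excluded. Results are sorted by
    distance to the start codon.
    """
    sense = check_dna(genome_context, f"genome context of {gene.gene_id}")
    cds = gene.coding_sequence
    if cds_offset is None:
        cds_offset = sense.find(cds)
        if cds_offset < 0:
            raise ValueError(f"CDS of {gene.gene_id} not found in genome context")
    elif sense[cds_offset : cds_offset + len(cds)] != cds:
        raise ValueError(f"cds_offset does not align CDS of {gene.gene_id}")

    sites: list[GuideSite] = []
    L = gene.length_nt
    # CCN at CDS offset p; protospacer occupies sense [p+3, p+23) and must
    # lie fully within the CDS.
    for p in range(-3, L - 22):
        a = cds_offset + p
        if a < 0:
            continue
        if sense[a : a + 2] != "CC":
            continue
        lo, hi = a - 3, a + 27
        if lo < 0 or hi > len(sense):
            logger.warning(
                "%s: site at CDS offset %d skipped (flank too short for 30-nt context)",
                gene.gene_id,
                p + 3,
            )
            continue
        window = sense[lo:hi]
        context30 = revcomp(window)
        spacer = context30[4:24]
        gc = gc_fraction(spacer)
        if gc < filters.gc_min or gc > filters.gc_max:
            continue
        if any(
            m.upper() in spacer or revcomp(m.upper()) in spacer
            for m in filters.forbidden_motifs
        ):
            continue
        dist = p + 3
        sites.append(
            GuideSite(
                spacer=spacer,
                context30=context30,
                pam=context30[24:27],
                gene_id=gene.gene_id,
                dist_start_codon=dist,
                rel_dist=dist / L,
                dist_tu_start=gene.tu_offset_nt + dist,
                targets_first_gene=gene.targets_first_gene,
            )
        )
    sites.sort(key=lambda s: s.dist_start_codon)
    return sites


def distance_features(site: GuideSite, gene: GeneAnnotation) -> dict[str, float]:
    """Distance-derived features of a site, recomputed from its gene."""
    if not (0 <= site.dist_start_codon <= gene.length_nt - 20):
        raise ValueError(
            f"site at {site.dist_start_codon} outside CDS of {gene.gene_id}"
        )
    return {
        "dist_start_codon": float(site.dist_start_codon),
        "rel_dist": site.dist_start_codon / gene.length_nt,
        "dist_tu_start": float(gene.tu_offset_nt + site.dist_start_codon),
        "targets_first_gene": float(gene.targets_first_gene),
    }
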