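"""Gene-level annotation: the per-gene record consumed by the featurizer,
plus readers for the standard file dialects (FASTA genome, GFF3 genes,
transcription-unit TSV, expression-by-OD TSV, essential-gene list, codon
weight table) and the codon adaptation index.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._util import check_dna, gc_fraction

logger = logging.getLogger(__name__)

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
# Met and Trp are encoded by a single codon; they carry no information about
# codon preference and are excluded from the CAI geometric mean, as are stops.
SINGLE_CODON = frozenset({"ATG", "TGG"})


@dataclass
class GeneAnnotation:
    """One protein-coding gene with its operon and expression context.

    ``tu_offset_nt`` is the distance (nt, in transcription direction) from
    the transcription-unit start to the gene's start codon; guide distances
    to the TU start are derived from it.
    """

    gene_id: str
    coding_sequence: str
    genomic_start: int
    genomic_end: int
    strand: str
    tu_id: str
    index_in_tu: int
    n_downstream_genes: int
    n_downstream_essential: int
    is_essential: bool
    expression_by_od: dict[float, float]
    cai: float
    tu_offset_nt: int = 0
    gc_content: float = field(default=None)  # type: ignore[assignment]
    length_nt: int = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.coding_sequence = check_dna(self.coding_sequence, f"CDS of {self.gene_id}")
        computed_len = len(self.coding_sequence)
        computed_gc = gc_fraction(self.coding_sequence)
        if self.length_nt is None:
            self.length_nt = computed_len
        elif self.length_nt != computed_len:
            raise ValueError(
                f"{self.gene_id}: length_nt={self.length_nt} but CDS has "
                f"{computed_len} nt"
            )
        if self.gc_content is None:
            self.gc_content = computed_gc
        elif abs(self.gc_content - computed_gc) > 1e-9:
            raise ValueError(f"{self.gene_id}: gc_content inconsistent with CDS")
        if self.strand not in {"+", "-"}:
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")
        if self.index_in_tu < 0 or self.n_downstream_genes < 0:
            raise ValueError(f"{self.gene_id}: negative TU bookkeeping")

    @property
    def targets_first_gene(self) -> bool:
        return self.index_in_tu == 0


def compute_cai(cds: str, weights: dict[str, float]) -> float:
    """Codon adaptation index: geometric mean of relative adaptiveness.

    ``weights`` maps each sense codon to its relative adaptiveness in
    [0, 1] (1 for the preferred codon of each amino acid). Stop codons and
    the single-codon amino acids (ATG, TGG) are excluded from the mean.
    """
    s = check_dna(cds, "CDS")
    if len(s) % 3 != 0:
        raise ValueError(f"CDS length {len(s)} not divisible by 3")
    logs = []
    for i in range(0, len(s), 3):
        codon = s[i : i + 3]
        if codon in STOP_CODONS or codon in SINGLE_CODON:
            continue
        if codon not in weights:
            raise ValueError(f"unknown codon {codon!r} at position {i}")
        w = weights[codon]
        if w <= 0:
            raise ValueError(f"non-positive weight for codon {codon!r}")
        logs.append(np.log(w))
    if not logs:
        return 1.0
    return float(np.exp(np.mean(logs)))


def uniform_codon_weights() -> dict[str, float]:
    """All-ones weight table (CAI == 1 for every CDS); useful as a default."""
    bases = "ACGT"
    return {
        a + b + c: 1.0
        for a in bases
        for b in bases
        for c in bases
        if a + b + c not in STOP_CODONS
    }


# ---------------------------------------------------------------------------
# File readers
# ---------------------------------------------------------------------------


def read_genome_fasta(path: str) -> dict[str, str]:
    """Read a FASTA file into {record id: uppercase sequence}."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}


def read_gene_gff(path: str) -> pd.DataFrame:
    """Read gene features from a GFF3 file.

    Returns a frame with columns gene_id, seqid, start, end, strand
    (1-based inclusive coordinates, as in the file).
    """
    import gffutils

    db = gffutils.create_db(
        path, ":memory:", merge_strategy="create_unique", keep_order=True
    )
    rows = []
    for feat in db.features_of_type("gene"):
        gene_id = feat.attributes.get("ID", [feat.id])[0]
        rows.append(
            {
                "gene_id": gene_id,
                "seqid": feat.seqid,
                "start": feat.start,
                "end": feat.end,
                "strand": feat.strand,
            }
        )
    if not rows:
        raise ValueError(f"no gene features found in {path}")
    return pd.DataFrame(rows)


def read_tu_table(path: str) -> pd.DataFrame:
    """Transcription-unit table: TSV with columns tu_id, gene_id, rank."""
    df = pd.read_csv(path, sep="\t")
    required = {"tu_id", "gene_id", "rank"}
    if not required.issubset(df.columns):
        raise ValueError(f"TU table must have columns {sorted(required)}")
    return df


def read_expression_table(path: str) -> dict[str, dict[float, float]]:
    """Wide expression TSV: gene_id column plus one numeric column per OD."""
    df = pd.read_csv(path, sep="\t")
    if "gene_id" not in df.columns:
        raise ValueError("expression table must have a gene_id column")
    od_cols = [c for c in df.columns if c != "gene_id"]
    ods = [float(c) for c in od_cols]
    out: dict[str, dict[float, float]] = {}
    for _, row in df.iterrows():
        out[row["gene_id"]] = {od: float(row[c]) for od, c in zip(ods, od_cols)}
    return out


def read_essential_list(path: str) -> set[str]:
    with open(path) as fh:
        return {line.strip() for line in fh if line.strip()}


def read_codon_weights(path: str) -> dict[str, float]:
    """Codon weight TSV with columns codon, weight."""
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df["codon"].str.upper(), df["weight"].astype(float)))


def assemble_annotations(
    genome: dict[str, str],
    genes: pd.DataFrame,
    tu: pd.DataFrame,
    expression: dict[str, dict[float, float]],
    essential: set[str],
    codon_weights: dict[str, float] | None = None,
) -> dict[str, GeneAnnotation]:
    """Join the individual tables into per-gene :class:`GeneAnnotation`.

    TU bookkeeping (rank within operon, downstream gene and essential-gene
    counts, offset from the TU start) is derived from the TU table and
    genomic coordinates; genes absent from the TU table are treated as
    single-gene operons.
    """
    from ._util import revcomp

    codon_weights = codon_weights or uniform_codon_weights()
    tu_groups = {
        tu_id: grp.sort_values("rank")["gene_id"].tolist()
        for tu_id, grp in tu.groupby("tu_id")
    }
    gene_to_tu = {g: tu_id for tu_id, gs in tu_groups.items() for g in gs}
    coords = genes.set_index("gene_id")

    out: dict[str, GeneAnnotation] = {}
    for gene_id in genes["gene_id"]:
        row = coords.loc[gene_id]
        seq = genome[row["seqid"]][row["start"] - 1 : row["end"]]
        if row["strand"] == "-":
            seq = revcomp(seq)
        tu_id = gene_to_tu.get(gene_id, f"TU_{gene_id}")
        members = tu_groups.get(tu_id, [gene_id])
        idx = members.index(gene_id)
        downstream = members[idx + 1 :]
        expr = expression.get(gene_id, {0.0: 0.0})
        # TU start = start codon of the first gene of the operon, measured in
        # transcription direction.
        first = coords.loc[members[0]]
        if row["strand"] == "+":
            tu_offset = int(row["start"] - first["start"])
        else:
            tu_offset = int(first["end"] - row["end"])
        out[gene_id] = GeneAnnotation(
            gene_id=gene_id,
            coding_sequence=seq,
            genomic_start=int(row["start"]),
            genomic_end=int(row["end"]),
            strand=row["strand"],
            tu_id=tu_id,
            index_in_tu=idx,
            n_downstream_genes=len(downstream),
            n_downstream_essential=sum(g in essential for g in downstream),
            is_essential=gene_id in essential,
            expression_by_od=expr,
            cai=compute_cai(seq, codon_weights),
            tu_offset_nt=max(tu_offset, 0),
        )
    return out
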