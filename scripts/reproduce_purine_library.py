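"""Reproduce the saturating purine-pathway guide library from a reference
genome (optional; requires the E. coli K-12 MG1655 genome, NCBI accession
NC_000913.3, downloaded by the user).

Enumerates all 20-nt NGG guides targeting the coding strand of the nine
purine biosynthesis genes, with spacer GC between 30 and 85% and no BbsI
site (GAAGAC/GTCTTC) on either strand, and prints per-gene and total
counts. The published library built under these rules contains 750 guides
with 35-223 guides per gene.

Usage:
    python scripts/reproduce_purine_library.py \
        --fasta NC_000913.3.fasta --gff NC_000913.3.gff3
"""

from __future__ import annotations

import argparse

from guidemix._util import revcomp
from guidemix.annotation import GeneAnnotation, read_gene_gff, read_genome_fasta
from guidemix.guides import GuideFilters, enumerate_guides

PURINE_GENES = ("purA", "purC", "purD", "purE", "purF", "purH", "purK", "purL", "purM")


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--fasta", required=True)
    ap.add_argument("--gff", required=True)
    ap.add_argument("--genes", default=",".join(PURINE_GENES),
                    help="comma-separated gene names to enumerate")
    ap.add_argument("--flank", type=int, default=10)
    args = ap.parse_args()

    genome = read_genome_fasta(args.fasta)
    genes = read_gene_gff(args.gff)
    wanted = args.genes.split(",")

    total = 0
    counts = {}
    for name in wanted:
        hit = genes[genes["gene_id"].str.contains(name, case=False)]
        if hit.empty:
            print(f"{name}: not found in GFF, skipped")
            continue
        row = hit.iloc[0]
        seq = genome[row["seqid"]]
        lo = max(0, row["start"] - 1 - args.flank)
        hi = min(len(seq), row["end"] + args.flank)
        ctx = seq[lo:hi]
        cds = seq[row["start"] - 1 : row["end"]]
        if row["strand"] == "-":
            ctx, cds = revcomp(ctx), revcomp(cds)
        gene = GeneAnnotation(
            gene_id=name, coding_sequence=cds, genomic_start=int(row["start"]),
            genomic_end=int(row["end"]), strand=row["strand"], tu_id=name,
            index_in_tu=0, n_downstream_genes=0, n_downstream_essential=0,
            is_essential=True, expression_by_od={0.2: 0.0}, cai=1.0,
        )
        sites = enumerate_guides(gene, ctx, GuideFilters())
        counts[name] = len(sites)
        total += len(sites)
        print(f"{name}: {len(sites)} guides")
    print(f"total: {total} guides across {len(counts)} genes "
          f"(per-gene range {min(counts.values())}-{max(counts.values())})")


if __name__ == "__main__":
    main()
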