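"""Readers/writers for the pipeline's file dialects and run manifests."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path

import pandas as pd

from .fusion import ScreenObservation
from .guides import GuideSite
from .sim import SimGenome


def write_guides_tsv(sites: dict[str, GuideSite], path: str | Path) -> None:
    rows = [
        {
            "guide_id": s.guide_id,
            "spacer": s.spacer,
            "context30": s.context30,
            "pam": s.pam,
            "gene_id": s.gene_id,
            "dist_start_codon": s.dist_start_codon,
            "rel_dist": s.rel_dist,
            "dist_tu_start": s.dist_tu_start,
            "targets_first_gene": int(s.targets_first_gene),
        }
        for s in sites.values()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_guides_tsv(path: str | Path) -> dict[str, GuideSite]:
    df = pd.read_csv(path, sep="\t")
    out = {}
    for _, r in df.iterrows():
        s = GuideSite(
            spacer=r["spacer"],
            context30=r["context30"],
            pam=r["pam"],
            gene_id=r["gene_id"],
            dist_start_codon=int(r["dist_start_codon"]),
            rel_dist=float(r["rel_dist"]),
            dist_tu_start=int(r["dist_tu_start"]),
            targets_first_gene=bool(r["targets_first_gene"]),
        )
        out[s.guide_id] = s
    return out


def write_observations_tsv(obs: list[ScreenObservation], path: str | Path) -> None:
    pd.DataFrame([asdict(o) for o in obs]).to_csv(path, sep="\t", index=False)


def read_observations_tsv(path: str | Path) -> list[ScreenObservation]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for _, r in df.iterrows():
        out.append(
            ScreenObservation(
                guide_id=str(r["guide_id"]),
                gene_id=str(r["gene_id"]),
                dataset=str(r["dataset"]),
                logfc=float(r["logfc"]),
                scaled_logfc=None
                if pd.isna(r.get("scaled_logfc"))
                else float(r["scaled_logfc"]),
                activity_score=None
                if pd.isna(r.get("activity_score"))
                else float(r["activity_score"]),
            )
        )
    return out


def write_simulated_genome(genome: SimGenome, outdir: str | Path) -> None:
    """Emit the simulated genome in the dialects the real-data readers
    consume: FASTA (one contig of concatenated gene contexts), GFF3 gene
    features, TU/expression/essential tables."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    contig = "".join(genome.contexts[g] for g in genome.genes)
    with open(outdir / "genome.fasta", "w") as fh:
        fh.write(">sim_contig\n")
        for i in range(0, len(contig), 70):
            fh.write(contig[i : i + 70] + "\n")
    with open(outdir / "genes.gff3", "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genome.genes.values():
            fh.write(
                "\t".join(
                    [
                        "sim_contig", "guidemix_sim", "gene",
                        str(g.genomic_start), str(g.genomic_end), ".", g.strand,
                        ".", f"ID={g.gene_id}",
                    ]
                )
                + "\n"
            )
    pd.DataFrame(
        [
            {"tu_id": g.tu_id, "gene_id": g.gene_id, "rank": g.index_in_tu}
            for g in genome.genes.values()
        ]
    ).to_csv(outdir / "tu.tsv", sep="\t", index=False)
    ods = sorted(next(iter(genome.genes.values())).expression_by_od)
    pd.DataFrame(
        [
            {"gene_id": g.gene_id, **{str(od): g.expression_by_od[od] for od in ods}}
            for g in genome.genes.values()
        ]
    ).to_csv(outdir / "expression.tsv", sep="\t", index=False)
    with open(outdir / "essential.txt", "w") as fh:
        for g in genome.genes.values():
            if g.is_essential:
                fh.write(g.gene_id + "\n")


def file_checksum(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def write_manifest(path: str | Path, config: dict, inputs: list[str | Path]) -> None:
    """Run manifest: config echo, input checksums, package version."""
    from . import __version__

    manifest = {
        "package_version": __version__,
        "config": config,
        "inputs": {
            str(p): file_checksum(p) for p in inputs if Path(p).is_file()
        },
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
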