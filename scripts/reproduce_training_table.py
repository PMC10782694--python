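"""Reproduce the fused cross-screen training table from the published
screens' supplementary tables (optional; requires user-supplied files).

Expects three observation TSVs with columns guide_id, gene_id, dataset,
logfc — two from screens sharing a guide library (averaged guide-wise
onto the shared scale) and one independent screen (mapped by OLS on its
overlapping guides, which are then dropped). After the >= 5 guides-per-
gene filter the published fusion yields a 7400-row training table (1618
guides from the shared-library screens plus 4164 from the third, each
shared-library guide contributing one row per screen) over 301 genes,
drawn from 8099 coding-strand guides targeting essential genes.

Usage:
    python scripts/reproduce_training_table.py \
        --shared e75_rousset.tsv --shared e18_cui.tsv --mapped wang.tsv \
        --out training_table.tsv
"""

from __future__ import annotations

import argparse
from dataclasses import replace

from guidemix import fusion as fu
from guidemix.io import read_observations_tsv


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--shared", action="append", required=True,
                    help="observation TSV of a shared-library screen (repeatable)")
    ap.add_argument("--mapped", required=True,
                    help="observation TSV of the independent screen")
    ap.add_argument("--min-guides", type=int, default=5)
    ap.add_argument("--out", required=True)
    args = ap.parse_args()

    screens = [read_observations_tsv(p) for p in args.shared]
    print(f"input guides: {sum(len(s) for s in screens)} shared-library + "
          f"{len(read_observations_tsv(args.mapped))} independent")

    maps = [{o.guide_id: o.logfc for o in s} for s in screens]
    avg = maps[0]
    for m in maps[1:]:
        avg = fu.average_shared_library(avg, m)
    scaled_ref = [
        replace(o, scaled_logfc=avg[o.guide_id])
        for s in screens for o in s if o.guide_id in avg
    ]
    mapped = read_observations_tsv(args.mapped)
    overlap = {o.guide_id for o in mapped} & avg.keys()
    mp = {o.guide_id: o.logfc for o in mapped}
    scaling = fu.fit_scaling([(mp[g], avg[g]) for g in sorted(overlap)])
    print(f"overlap: {len(overlap)} guides; scaling slope {scaling.slope:.3f}, "
          f"intercept {scaling.intercept:.3f}")
    mapped_scaled = fu.apply_scaling_and_drop_overlap(mapped, scaling, overlap)

    scored = fu.activity_scores(scaled_ref + mapped_scaled,
                                min_guides=args.min_guides)
    by_key = {(o.guide_id, o.dataset): o for o in scored}
    datasets = [
        [by_key[(o.guide_id, o.dataset)] for o in ds
         if (o.guide_id, o.dataset) in by_key]
        for ds in ([scaled_ref, mapped_scaled])
    ]
    table = fu.assemble_training_table(datasets)
    table.to_csv(args.out, sep="\t", index=False)
    print(f"training table: {len(table)} rows, "
          f"{table['cluster_id'].nunique()} gene clusters -> {args.out}")


if __name__ == "__main__":
    main()
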