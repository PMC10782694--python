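"""Cross-screen data fusion.

Depletion logFCs from independent screens live on different scales (dCas9
expression level, growth regime and sequencing depth all shift them). Two
screens sharing a guide library are averaged guide-wise; a third screen is
mapped onto that shared scale by ordinary least squares on its overlapping
guides, which are then dropped from the mapped screen to avoid duplicate
measurements. Per-guide activity scores (scaled logFC minus the gene's
median scaled logFC) provide a gene-normalized efficiency proxy for
baseline models; the mixed-effect model itself consumes raw logFCs, since
its per-gene random intercept absorbs scale differences.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ScreenObservation:
    """One (guide, gene, dataset) depletion measurement."""

    guide_id: str
    gene_id: str
    dataset: str
    logfc: float
    scaled_logfc: float | None = None
    activity_score: float | None = None


@dataclass(frozen=True)
class ScalingFit:
    slope: float
    intercept: float


def average_shared_library(
    lfc_a: dict[str, float], lfc_b: dict[str, float]
) -> dict[str, float]:
    """Guide-wise mean of two screens sharing a library (the shared scale)."""
    shared = lfc_a.keys() & lfc_b.keys()
    if not shared:
        raise ValueError("no shared guides between the two screens")
    only = (lfc_a.keys() | lfc_b.keys()) - shared
    if only:
        logger.info("%d guides present in only one screen are dropped", len(only))
    return {g: 0.5 * (lfc_a[g] + lfc_b[g]) for g in shared}


def fit_scaling(pairs: list[tuple[float, float]]) -> ScalingFit:
    """OLS fit of shared-scale logFC (y) on the foreign screen's logFC (x).

    Applied as scaled = slope * x + intercept.
    """
    if len(pairs) < 2:
        raise ValueError("need at least 2 pairs to fit a scaling")
    x = np.array([p[0] for p in pairs], dtype=float)
    y = np.array([p[1] for p in pairs], dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("degenerate fit: no variance in x")
    slope, intercept = np.polyfit(x, y, 1)
    return ScalingFit(slope=float(slope), intercept=float(intercept))


def apply_scaling_and_drop_overlap(
    wang_obs: list[ScreenObservation],
    scaling: ScalingFit,
    overlap_ids: set[str],
) -> list[ScreenObservation]:
    """Scale every observation of the foreign screen onto the shared scale
    and drop guides already represented there."""
    out = [
        replace(o, scaled_logfc=scaling.slope * o.logfc + scaling.intercept)
        for o in wang_obs
        if o.guide_id not in overlap_ids
    ]
    if not out and wang_obs:
        logger.warning("all %d observations were overlap; empty result", len(wang_obs))
    return out


def activity_scores(
    obs: list[ScreenObservation],
    min_guides: int = 5,
    pool_datasets: bool = True,
) -> list[ScreenObservation]:
    """Gene-normalized activity scores from scaled logFCs.

    Genes with fewer than ``min_guides`` guides in any contributing dataset
    are removed (median estimates for such genes are unstable). The score
    is scaled logFC minus the gene's median scaled logFC, with the median
    pooled over datasets by default.
    """
    if any(o.scaled_logfc is None for o in obs):
        raise ValueError("scaled_logfc must be set before activity scoring")
    df = pd.DataFrame(
        {
            "guide_id": [o.guide_id for o in obs],
            "gene_id": [o.gene_id for o in obs],
            "dataset": [o.dataset for o in obs],
            "scaled_logfc": [o.scaled_logfc for o in obs],
        }
    )
    counts = df.groupby(["gene_id", "dataset"])["guide_id"].nunique()
    bad_genes = set(counts[counts < min_guides].index.get_level_values(0))
    if bad_genes:
        logger.info(
            "dropping %d genes with < %d guides in some dataset", len(bad_genes), min_guides
        )
    kept = [o for o in obs if o.gene_id not in bad_genes]
    sub = df[~df["gene_id"].isin(bad_genes)]
    if pool_datasets:
        med = sub.groupby("gene_id")["scaled_logfc"].median()
        return [
            replace(o, activity_score=o.scaled_logfc - med[o.gene_id]) for o in kept
        ]
    med2 = sub.groupby(["gene_id", "dataset"])["scaled_logfc"].median()
    return [
        replace(o, activity_score=o.scaled_logfc - med2[(o.gene_id, o.dataset)])
        for o in kept
    ]


def assemble_training_table(
    datasets: list[list[ScreenObservation]],
) -> pd.DataFrame:
    """Stack per-dataset observations into one training table.

    One row per (guide, dataset); a guide measured in two screens yields
    two rows sharing the same cluster id (its gene). Duplicate
    (guide, dataset) rows are an input error.
    """
    rows = []
    for ds in datasets:
        for o in ds:
            rows.append(
                {
                    "guide_id": o.guide_id,
                    "gene_id": o.gene_id,
                    "dataset": o.dataset,
                    "logfc": o.logfc,
                    "scaled_logfc": o.scaled_logfc,
                    "activity_score": o.activity_score,
                }
            )
    df = pd.DataFrame(rows)
    if df.empty:
        raise ValueError("no observations supplied")
    dup = df.duplicated(subset=["guide_id", "dataset"])
    if dup.any():
        raise ValueError(
            f"duplicate (guide, dataset) rows: {df[dup][['guide_id', 'dataset']].values[:5]}"
        )
    df["cluster_id"] = df["gene_id"]
    return df.reset_index(drop=True)
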