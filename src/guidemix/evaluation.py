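"""Cross-validation splitters, screen-evaluation metrics, and train/test
sequence-distance diagnostics.

Because true guide efficiency is never observed directly, models are
evaluated gene-wise: all guides of a held-out gene are withheld together,
and predictions are scored by their within-gene agreement with measured
depletion (rank order within a gene reflects relative guide efficiency
even though between-gene depletion levels are confounded by the gene).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FoldSpec:
    fold_id: int
    held_out_units: tuple[str, ...]
    mode: str = "gene_wise"


def split_genewise(gene_ids, k: int = 10, seed: int = 0) -> list[FoldSpec]:
    """Deal shuffled genes into k near-equal folds; all guides of a
    held-out gene leave the training set together."""
    uniq = sorted(set(gene_ids))
    if k > len(uniq):
        raise ValueError(f"k={k} exceeds number of genes ({len(uniq)})")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(uniq))
    folds = np.array_split(order, k)
    return [
        FoldSpec(fold_id=i, held_out_units=tuple(uniq[j] for j in f))
        for i, f in enumerate(folds)
    ]


def split_guidewise(guide_ids, k: int = 10, seed: int = 0) -> list[FoldSpec]:
    """Fold split on unique guide sequences (depletion-prediction setting)."""
    uniq = sorted(set(guide_ids))
    if k > len(uniq):
        raise ValueError(f"k={k} exceeds number of guides ({len(uniq)})")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(uniq))
    return [
        FoldSpec(
            fold_id=i,
            held_out_units=tuple(uniq[j] for j in f),
            mode="guide_wise",
        )
        for i, f in enumerate(np.array_split(order, k))
    ]


def per_gene_spearman(
    pred, obs, gene_of
) -> tuple[dict[str, float], float]:
    """Spearman rank correlation (average-rank ties) between predictions
    and measured depletion within each gene, plus the median over genes.

    Genes with fewer than two guides, or with a constant vector on either
    side, cannot be ranked and are skipped with a log message.
    """
    df = pd.DataFrame({"pred": pred, "obs": obs, "gene": list(gene_of)})
    out: dict[str, float] = {}
    for gene, grp in df.groupby("gene", sort=True):
        if len(grp) < 2:
            logger.info("gene %s skipped: fewer than 2 guides", gene)
            continue
        if grp["pred"].nunique() == 1 or grp["obs"].nunique() == 1:
            logger.info("gene %s skipped: constant values", gene)
            continue
        rho = spearmanr(grp["pred"], grp["obs"]).statistic
        out[gene] = float(rho)
    median = float(np.median(list(out.values()))) if out else float("nan")
    return out, median


def _top_fraction_idx(values: np.ndarray, ids: np.ndarray, frac: float) -> set:
    """Indices of the most-negative ``frac`` of values; size ceil(frac*n),
    ties broken by id for determinism."""
    n = len(values)
    size = math.ceil(frac * n)
    order = np.lexsort((ids, values))
    return set(order[:size])


def enrichment_top20(
    pred, obs, gene_of, frac: float = 0.2, per_gene: bool = False
) -> float:
    """Enrichment of truly efficient guides among predicted-efficient ones.

    Within each gene, the most strongly depleted ``frac`` of guides by
    observation are "efficient" and the top ``frac`` by prediction are
    "predicted efficient"; the pooled overlap over the pooled predicted-set
    size is returned as a percentage. Genes with fewer than 5 guides are
    skipped. Invariant to monotone transforms of the predictions.
    """
    df = pd.DataFrame({"pred": pred, "obs": obs, "gene": list(gene_of)})
    inter_tot = 0
    pred_tot = 0
    fracs = []
    for gene, grp in df.groupby("gene", sort=True):
        if len(grp) < 5:
            logger.info("gene %s skipped in enrichment: < 5 guides", gene)
            continue
        ids = grp.index.to_numpy()
        top_obs = _top_fraction_idx(grp["obs"].to_numpy(), ids, frac)
        top_pred = _top_fraction_idx(grp["pred"].to_numpy(), ids, frac)
        inter = len(top_obs & top_pred)
        inter_tot += inter
        pred_tot += len(top_pred)
        fracs.append(100.0 * inter / len(top_pred))
    if pred_tot == 0:
        return float("nan")
    if per_gene:
        return float(np.mean(fracs))
    return 100.0 * inter_tot / pred_tot


def ppv_topk(
    pred, obs, gene_of, k: int = 3, fold_n: float = 2.0
) -> float:
    """Positive predictive value of picking each gene's top-k predictions.

    A predicted guide counts as a true positive if its measured logFC is
    within ``fold_n``-fold of the gene's strongest depletion, i.e.
    logFC <= min(logFC) + log2(fold_n). PPV = TP / (TP + FP) pooled over
    genes; genes with fewer than k guides are skipped.
    """
    df = pd.DataFrame({"pred": pred, "obs": obs, "gene": list(gene_of)})
    tp = fp = 0
    for gene, grp in df.groupby("gene", sort=True):
        if len(grp) < k:
            logger.info("gene %s skipped in PPV: < %d guides", gene, k)
            continue
        threshold = grp["obs"].min() + np.log2(fold_n)
        order = np.lexsort((grp.index.to_numpy(), grp["pred"].to_numpy()))
        picked = grp.iloc[order[:k]]
        hits = int((picked["obs"] <= threshold).sum())
        tp += hits
        fp += k - hits
    if tp + fp == 0:
        return float("nan")
    return tp / (tp + fp)


def hamming_diagnostics(
    train_contexts: list[str], test_contexts: list[str]
) -> dict[str, float]:
    """Min and median pairwise Hamming distance between the train and test
    context sequences (a leakage / novelty diagnostic)."""
    if not train_contexts or not test_contexts:
        raise ValueError("both context sets must be nonempty")
    lengths = {len(s) for s in train_contexts} | {len(s) for s in test_contexts}
    if len(lengths) != 1:
        raise ValueError(f"contexts have mixed lengths: {sorted(lengths)}")
    a = np.frombuffer("".join(train_contexts).encode(), dtype=np.uint8).reshape(
        len(train_contexts), -1
    )
    b = np.frombuffer("".join(test_contexts).encode(), dtype=np.uint8).reshape(
        len(test_contexts), -1
    )
    d = (a[:, None, :] != b[None, :, :]).sum(axis=2)
    return {"min": float(d.min()), "median": float(np.median(d))}
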