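"""Feature attribution and design-rule analysis for the fixed-effect forest.

Attributions are Shapley values per (guide, feature): negative values push
the predicted logFC down (stronger depletion, i.e. a more efficient
guide). On top of the per-feature attributions sit two screen-specific
analyses: a median-based comparison of observed vs additively-expected
attributions for feature pairs (detecting non-additive sequence
interactions), and a profile of the distance feature's attribution near
vs far from the start codon.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .treeshap import forest_shap_values, permutation_shap_values

logger = logging.getLogger(__name__)

COMBOS = ("-/-", "+/-", "-/+", "+/+")


@dataclass
class AttributionMatrix:
    """Per-sample, per-feature additive contributions."""

    values: np.ndarray
    base_value: float
    feature_names: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.values.ndim != 2 or self.values.shape[1] != len(self.feature_names):
            raise ValueError("values shape does not match feature names")

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.feature_names.index(name)]


def attribute(
    forest,
    X: np.ndarray,
    feature_names: tuple[str, ...] | None = None,
    method: str = "exact_tree",
    n_permutations: int = 32,
    seed: int = 0,
) -> AttributionMatrix:
    """Shapley attributions for a fitted tree model on rows of X.

    ``exact_tree`` runs the deterministic polynomial-time tree algorithm;
    ``permutation`` is the model-agnostic sampling fallback.
    """
    X = np.asarray(X, dtype=float)
    if not hasattr(forest, "estimators_") and not hasattr(forest, "tree_"):
        raise TypeError(
            f"unsupported model type {type(forest).__name__}; need a sklearn "
            "tree or forest regressor"
        )
    if method == "exact_tree":
        phi, base = forest_shap_values(forest, X)
    elif method == "permutation":
        phi, base = permutation_shap_values(
            forest, X, n_permutations=n_permutations, seed=seed
        )
    else:
        raise ValueError(f"unknown attribution method {method!r}")
    names = (
        tuple(feature_names)
        if feature_names is not None
        else tuple(f"f{i}" for i in range(X.shape[1]))
    )
    return AttributionMatrix(values=phi, base_value=base, feature_names=names)


def mean_abs_importance(attr: AttributionMatrix) -> list[tuple[str, float]]:
    """Global importance ranking: mean |attribution| per feature, descending."""
    if attr.values.shape[0] == 0:
        raise ValueError("empty attribution matrix")
    scores = np.abs(attr.values).mean(axis=0)
    order = np.argsort(-scores, kind="stable")
    return [(attr.feature_names[i], float(scores[i])) for i in order]


def interaction_combination_table(
    attr_f1: np.ndarray,
    attr_f2: np.ndarray,
    present_f1: np.ndarray,
    present_f2: np.ndarray,
) -> dict:
    """Observed vs additively-expected joint attribution for a feature pair.

    Samples are stratified by presence of the two features (-/-, +/-, -/+,
    +/+). The observed score of a stratum is the median of the summed
    attributions; the expectation for +/+ adds the median F1 attribution
    among +/- samples to the median F2 attribution among -/+ samples (and
    symmetrically for -/-). A nonzero observed-minus-expected deviation
    flags a non-additive interaction. Empty strata are reported in
    ``missing`` and excluded from deviations.
    """
    a1 = np.asarray(attr_f1, dtype=float)
    a2 = np.asarray(attr_f2, dtype=float)
    p1 = np.asarray(present_f1, dtype=bool)
    p2 = np.asarray(present_f2, dtype=bool)
    if not (len(a1) == len(a2) == len(p1) == len(p2)):
        raise ValueError("inputs must have equal length")

    masks = {
        "-/-": ~p1 & ~p2,
        "+/-": p1 & ~p2,
        "-/+": ~p1 & p2,
        "+/+": p1 & p2,
    }
    observed = {
        c: (float(np.median(a1[m] + a2[m])) if m.any() else None)
        for c, m in masks.items()
    }
    missing = [c for c, v in observed.items() if v is None]

    def med(arr, mask):
        return float(np.median(arr[mask])) if mask.any() else None

    exp_pp = None
    if masks["+/-"].any() and masks["-/+"].any():
        exp_pp = med(a1, masks["+/-"]) + med(a2, masks["-/+"])
    exp_mm = None
    if masks["-/+"].any() and masks["+/-"].any():
        exp_mm = med(a1, masks["-/+"]) + med(a2, masks["+/-"])
    expected = {"+/+": exp_pp, "-/-": exp_mm}
    deviation = {
        c: (observed[c] - expected[c])
        if observed[c] is not None and expected[c] is not None
        else None
        for c in expected
    }
    return {
        "observed": observed,
        "expected": expected,
        "deviation": deviation,
        "missing": missing,
        "n": {c: int(m.sum()) for c, m in masks.items()},
    }


def rank_interacting_pairs(
    attr: AttributionMatrix,
    presence: np.ndarray,
    feature_pairs: list[tuple[str, str]] | None = None,
    cap: int = 5000,
):
    """Iterate feature pairs ranked by |+/+ deviation| of the combination
    table (largest first), up to ``cap`` pairs.

    ``presence`` is the 0/1 matrix aligned with ``attr`` columns; pairs
    default to all pairs of one-hot (binary) columns.
    """
    presence = np.asarray(presence, dtype=bool)
    names = attr.feature_names
    if feature_pairs is None:
        binary = [i for i in range(len(names)) if set(np.unique(presence[:, i])) <= {0, 1}]
        feature_pairs = [
            (names[i], names[j]) for ai, i in enumerate(binary) for j in binary[ai + 1 :]
        ]
    scored = []
    for f1, f2 in feature_pairs[: cap * 4]:
        i, j = names.index(f1), names.index(f2)
        tab = interaction_combination_table(
            attr.values[:, i], attr.values[:, j], presence[:, i], presence[:, j]
        )
        dev = tab["deviation"]["+/+"]
        if dev is not None:
            scored.append((abs(dev), f1, f2, tab))
    scored.sort(key=lambda t: -t[0])
    for _, f1, f2, tab in scored[:cap]:
        yield (f1, f2), tab


def distance_effect_profile(
    attr: AttributionMatrix,
    dist: np.ndarray,
    first_gene: np.ndarray | None = None,
    window: int = 60,
    dist_feature: str = "dist_start_codon",
) -> dict:
    """Mean attribution of the distance feature inside vs outside a window
    from the start codon, optionally stratified by the first-gene-in-operon
    indicator. A negative inside-minus-outside difference means proximity
    to the start codon promotes depletion (more efficient silencing)."""
    if dist_feature not in attr.feature_names:
        raise ValueError(f"{dist_feature!r} not in the attribution registry")
    col = attr.column(dist_feature)
    dist = np.asarray(dist)
    inside = dist < window

    def stratum(mask):
        if not mask.any():
            return {"mean": None, "n": 0}
        return {"mean": float(col[mask].mean()), "n": int(mask.sum())}

    out = {
        "inside": stratum(inside),
        "outside": stratum(~inside),
        "window": window,
    }
    if out["inside"]["mean"] is not None and out["outside"]["mean"] is not None:
        out["difference"] = out["inside"]["mean"] - out["outside"]["mean"]
    else:
        out["difference"] = None
        logger.info("empty distance stratum; difference unavailable")
    if first_gene is not None:
        fg = np.asarray(first_gene, dtype=bool)
        out["first_gene"] = {
            "inside": stratum(inside & fg),
            "outside": stratum(~inside & fg),
        }
        out["not_first_gene"] = {
            "inside": stratum(inside & ~fg),
            "outside": stratum(~inside & ~fg),
        }
    return out
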