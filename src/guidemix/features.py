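"""Assembly of model-ready feature matrices.

Each screen observation (one guide measured in one dataset) contributes a
row: a 129-column fixed block describing the guide (one-hot context,
thermodynamics, distances, homopolymer, first-gene indicator) and a
9-column random block describing the targeted gene and dataset. The random
block is standardized column-wise (zero mean, unit variance, population
convention) as the per-gene linear model expects.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.preprocessing import StandardScaler

from .annotation import GeneAnnotation
from .guides import GuideSite, distance_features, homopolymer
from .registry import FeatureRegistry, one_hot_context
from .thermo import ThermoEngine, thermo_features

logger = logging.getLogger(__name__)

DEFAULT_DATASETS: tuple[str, ...] = ("E75", "E18", "Wang")

# Growth stage at harvest per screen: expression min/max are taken over ODs
# up to this cap (inf = whole growth curve).
DEFAULT_OD_CAPS: dict[str, float] = {"E75": np.inf, "E18": np.inf, "Wang": 1.4}


@dataclass
class FeatureMatrix:
    """Fixed and random feature blocks in registry order, one row per
    observation."""

    fixed: np.ndarray
    random: np.ndarray
    fixed_names: tuple[str, ...]
    random_names: tuple[str, ...]
    index: list[str]
    clusters: list[str]

    def __post_init__(self) -> None:
        n = len(self.index)
        if self.fixed.shape != (n, len(self.fixed_names)):
            raise ValueError("fixed block shape mismatch")
        if self.random.shape != (n, len(self.random_names)):
            raise ValueError("random block shape mismatch")

    @property
    def n_obs(self) -> int:
        return len(self.index)

    def fixed_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.fixed, index=self.index, columns=self.fixed_names)

    def random_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.random, index=self.index, columns=self.random_names)


def guide_feature_vector(
    site: GuideSite,
    gene: GeneAnnotation,
    engine: ThermoEngine,
    registry: FeatureRegistry | None = None,
) -> np.ndarray:
    """The 129 fixed-effect features of one guide, in registry order."""
    registry = registry or FeatureRegistry()
    th = thermo_features(site.spacer, site.context30, engine)
    dist = distance_features(site, gene)
    scalars = {
        **th.as_dict(),
        **dist,
        "homopolymer": float(homopolymer(site.spacer)),
    }
    vec = np.empty(registry.n_fixed)
    vec[:120] = one_hot_context(site.context30)
    for j, name in enumerate(registry.fixed_names[120:], start=120):
        vec[j] = scalars[name]
    return vec


def gene_feature_vector(
    gene: GeneAnnotation,
    dataset_label: str,
    od_cap: float = np.inf,
    datasets: tuple[str, ...] = DEFAULT_DATASETS,
) -> np.ndarray:
    """The 9 gene/dataset features of one observation (unstandardized).

    Expression min/max are taken over ODs up to ``od_cap`` (the growth
    stage at which the screen was harvested). The dataset enters as two
    treatment-coded indicators with the first configured dataset as the
    reference level.
    """
    if dataset_label not in datasets:
        raise ValueError(f"unknown dataset {dataset_label!r}; configured: {datasets}")
    ods = sorted(od for od in gene.expression_by_od if od <= od_cap)
    if not ods:
        raise ValueError(
            f"{gene.gene_id}: no expression measurement at OD <= {od_cap}"
        )
    values = [gene.expression_by_od[od] for od in ods]
    level = datasets.index(dataset_label)
    return np.array(
        [
            min(values),
            max(values),
            gene.gc_content,
            float(gene.length_nt),
            float(gene.n_downstream_genes),
            float(gene.n_downstream_essential),
            gene.cai,
            1.0 if level == 1 else 0.0,
            1.0 if level == 2 else 0.0,
        ]
    )


def build_feature_matrix(
    sites: dict[str, GuideSite],
    genes: dict[str, GeneAnnotation],
    observations: list,
    engine: ThermoEngine,
    registry: FeatureRegistry | None = None,
    datasets: tuple[str, ...] = DEFAULT_DATASETS,
    od_caps: dict[str, float] | None = None,
) -> FeatureMatrix:
    """Build the (n x 129) fixed and standardized (n x 9) random blocks.

    ``observations`` are screen observations with guide_id, gene_id and
    dataset attributes; row order follows observation order. Guide-level
    features are computed once per unique guide and reused across
    observations of the same guide in different datasets.
    """
    registry = registry or FeatureRegistry()
    od_caps = od_caps if od_caps is not None else dict(DEFAULT_OD_CAPS)

    missing = sorted(
        {o.gene_id for o in observations if o.gene_id not in genes}
    )
    if missing:
        raise KeyError(f"observations reference unknown genes: {missing}")
    missing_g = sorted({o.guide_id for o in observations if o.guide_id not in sites})
    if missing_g:
        raise KeyError(f"observations reference unknown guides: {missing_g[:10]}")

    guide_cache: dict[str, np.ndarray] = {}
    n = len(observations)
    X = np.empty((n, registry.n_fixed))
    Zraw = np.empty((n, registry.n_random))
    index, clusters = [], []
    for i, obs in enumerate(observations):
        site = sites[obs.guide_id]
        gene = genes[obs.gene_id]
        if obs.guide_id not in guide_cache:
            guide_cache[obs.guide_id] = guide_feature_vector(
                site, gene, engine, registry
            )
        X[i] = guide_cache[obs.guide_id]
        Zraw[i] = gene_feature_vector(
            gene,
            obs.dataset,
            od_cap=od_caps.get(obs.dataset, np.inf),
            datasets=datasets,
        )
        index.append(f"{obs.guide_id}|{obs.dataset}")
        clusters.append(obs.gene_id)

    Z = StandardScaler().fit_transform(Zraw)
    # Constant columns (e.g. a dataset indicator absent from a simulated
    # screen) standardize to all-zero rather than dividing by ~0.
    const = Zraw.std(axis=0) == 0
    Z[:, const] = 0.0
    return FeatureMatrix(
        fixed=X,
        random=Z,
        fixed_names=registry.fixed_names,
        random_names=registry.random_names,
        index=index,
        clusters=clusters,
    )
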