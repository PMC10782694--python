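"""Shared fixtures: toy genes, small simulated screens, and one fitted
mixed-effect model on the default simulator preset (session-scoped; it is
the expensive object several suites share)."""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pytest

from guidemix.annotation import GeneAnnotation
from guidemix.features import build_feature_matrix
from guidemix.merf import Hyperparams, fit_merf, with_intercept
from guidemix.sim import PRESETS, design_guides, simulate_genome, simulate_screen


def make_gene(
    seq: str,
    gene_id: str = "toy",
    index_in_tu: int = 0,
    tu_offset_nt: int = 0,
    n_downstream_genes: int = 0,
    n_downstream_essential: int = 0,
    expression: dict | None = None,
) -> GeneAnnotation:
    return GeneAnnotation(
        gene_id=gene_id,
        coding_sequence=seq,
        genomic_start=1,
        genomic_end=len(seq),
        strand="+",
        tu_id=f"TU_{gene_id}",
        index_in_tu=index_in_tu,
        n_downstream_genes=n_downstream_genes,
        n_downstream_essential=n_downstream_essential,
        is_essential=True,
        expression_by_od=expression or {0.2: 5.0, 1.0: 5.0},
        cai=1.0,
        tu_offset_nt=tu_offset_nt,
    )


@pytest.fixture
def gene_factory():
    return make_gene


@pytest.fixture(scope="session")
def small_screen():
    """30-gene screen with full ground truth (fast; used by many suites)."""
    cfg = replace(PRESETS["small"], n_genes=30)
    genome = simulate_genome(cfg)
    guides = design_guides(genome, cfg)
    obs, truth = simulate_screen(genome, guides, cfg)
    return cfg, genome, guides, obs, truth


@pytest.fixture(scope="session")
def default_screen_fit():
    """The default simulator preset (300 genes x 10 guides, effect SDs
    2.0/1.0/0.5, seed 7) featurized with the production thermodynamic
    engine and fit with the mixed-effect forest (150 trees: a forest large
    enough for stable recovery while keeping the suite fast)."""
    from guidemix.thermo import default_engine

    cfg = PRESETS["default"]
    genome = simulate_genome(cfg)
    guides = design_guides(genome, cfg)
    obs, truth = simulate_screen(genome, guides, cfg)
    fm = build_feature_matrix(
        guides, genome.genes, obs, default_engine(),
        datasets=("sim", "_u1", "_u2"), od_caps={},
    )
    y = np.array([o.logfc for o in obs])
    state = fit_merf(
        fm.fixed, with_intercept(fm.random), fm.clusters, y,
        hp=Hyperparams(n_estimators=150), max_iter=30, tol=1e-3, seed=7,
    )
    return genome, guides, obs, truth, fm, y, state
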