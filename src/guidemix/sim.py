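"""Synthetic CRISPRi depletion screens with known effect decomposition.

The simulator emulates a pooled essentiality screen: genes organized into
transcription units with expression levels and essentiality labels,
saturating guide sets with full 30-nt contexts, a gene-level depletion
effect coupled to expression and to downstream essential genes (polar
effects), a guide-level effect driven by a known function of
PAM-proximal sequence and distance to the start codon, Gaussian logFC
noise, and negative-binomial sequencing counts anchored by non-targeting
controls. Every observed logFC decomposes exactly, by construction, into

    logFC = gene_effect + guide_effect + noise

with all three recorded in the emitted ground truth, so recovery of each
component can be asserted in tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np

from ._util import rng_for
from .annotation import GeneAnnotation, uniform_codon_weights, compute_cai
from .fusion import ScreenObservation
from .guides import GuideFilters, GuideSite, enumerate_guides

logger = logging.getLogger(__name__)

# Qualitative sequence preferences: C at the PAM's variable position and
# directly after the PAM favor silencing (negative = more depletion);
# G after the PAM and A/G at guide position 20 disfavor it.
DEFAULT_SEQ_WEIGHTS: dict[tuple[str, str], float] = {
    ("P1", "C"): -0.4,
    ("+1", "C"): -0.3,
    ("+1", "G"): 0.3,
    ("G20", "A"): 0.4,
    ("G20", "G"): 0.2,
    ("G20", "C"): -0.2,
    ("G20", "T"): -0.2,
}


@dataclass(frozen=True)
class SimConfig:
    n_genes: int = 300
    genes_per_tu: int = 2
    guides_per_gene: int = 10
    cds_length: int = 450
    sd_gene_effect: float = 2.0
    sd_guide_effect: float = 1.0
    sd_noise: float = 0.5
    expression_coupling: float = 1.0
    distance_bonus: float = 0.5
    distance_window: int = 60
    seq_weights: tuple = tuple(sorted(DEFAULT_SEQ_WEIGHTS.items()))
    essential_fraction: float = 0.3
    downstream_essential_penalty: float = 0.3
    nb_dispersion: float = 0.01
    library_size: int = 1_000_000
    n_nontargeting: int = 50
    replicate_scale: float = 1.25
    seed: int = 7

    def __post_init__(self) -> None:
        for name in ("sd_gene_effect", "sd_guide_effect", "sd_noise"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.guides_per_gene < 5:
            raise ValueError("guides_per_gene must be >= 5 (activity-score filter)")

    @property
    def seq_weight_map(self) -> dict[tuple[str, str], float]:
        return dict(self.seq_weights)


PRESETS: dict[str, SimConfig] = {
    "default": SimConfig(),
    "small": SimConfig(n_genes=60, guides_per_gene=8, seed=7),
    "no_gene_effect": SimConfig(sd_gene_effect=0.0, expression_coupling=0.0,
                                downstream_essential_penalty=0.0),
}


@dataclass
class SimTruth:
    gene_effects: dict[str, float]
    guide_effects: dict[str, float]
    noise: dict[str, float]
    config: dict = field(default_factory=dict)


@dataclass
class SimGenome:
    genes: dict[str, GeneAnnotation]
    contexts: dict[str, str]  # gene_id -> sense CDS with flanks
    flank: int


def simulate_genome(cfg: SimConfig) -> SimGenome:
    """Generate genes with TU structure, expression and essentiality.

    CDS sequences have uniform base composition; per-gene expression is a
    log-normal level measured at ten ODs with mild jitter; essentiality is
    a Bernoulli label; TU membership is consecutive blocks of
    ``genes_per_tu`` genes. Deterministic per seed.
    """
    rng = rng_for(cfg.seed, "genome")
    flank = 10
    ods = [round(0.2 * i, 1) for i in range(1, 11)]
    weights = uniform_codon_weights()

    essential = rng.random(cfg.n_genes) < cfg.essential_fraction
    genes: dict[str, GeneAnnotation] = {}
    contexts: dict[str, str] = {}
    pos = 1
    for g in range(cfg.n_genes):
        gene_id = f"g{g:04d}"
        tu_idx = g // cfg.genes_per_tu
        idx_in_tu = g % cfg.genes_per_tu
        n_down = cfg.genes_per_tu - idx_in_tu - 1
        down_ess = sum(
            essential[g + 1 : g + 1 + n_down]
        )
        seq = "".join(rng.choice(list("ACGT"), size=cfg.cds_length))
        level = float(rng.lognormal(mean=2.0, sigma=1.0))
        expr = {od: level * float(rng.lognormal(0.0, 0.1)) for od in ods}
        genes[gene_id] = GeneAnnotation(
            gene_id=gene_id,
            coding_sequence=seq,
            genomic_start=pos + flank,
            genomic_end=pos + flank + cfg.cds_length - 1,
            strand="+",
            tu_id=f"TU{tu_idx:04d}",
            index_in_tu=idx_in_tu,
            n_downstream_genes=n_down,
            n_downstream_essential=int(down_ess),
            is_essential=bool(essential[g]),
            expression_by_od=expr,
            cai=compute_cai(seq[: 3 * (cfg.cds_length // 3)], weights),
            tu_offset_nt=idx_in_tu * (cfg.cds_length + 2 * flank),
        )
        contexts[gene_id] = (
            "".join(rng.choice(list("ACGT"), size=flank))
            + seq
            + "".join(rng.choice(list("ACGT"), size=flank))
        )
        pos += cfg.cds_length + 2 * flank
    return SimGenome(genes=genes, contexts=contexts, flank=flank)


def design_guides(
    genome: SimGenome, cfg: SimConfig
) -> dict[str, GuideSite]:
    """Enumerate guides on the simulated genes and subsample to
    ``guides_per_gene`` per gene (seeded; genes with too few sites keep
    all of theirs)."""
    rng = rng_for(cfg.seed, "design")
    filters = GuideFilters()
    out: dict[str, GuideSite] = {}
    for gene_id, gene in genome.genes.items():
        sites = enumerate_guides(gene, genome.contexts[gene_id], filters)
        if len(sites) > cfg.guides_per_gene:
            keep = sorted(
                rng.choice(len(sites), size=cfg.guides_per_gene, replace=False)
            )
            sites = [sites[i] for i in keep]
        elif len(sites) < 5:
            logger.warning("gene %s has only %d sites", gene_id, len(sites))
        for s in sites:
            out[s.guide_id] = s
    return out


def _context_base(site: GuideSite, position_label: str) -> str:
    from .registry import CONTEXT_POSITIONS

    return site.context30[CONTEXT_POSITIONS.index(position_label)]


def simulate_screen(
    genome: SimGenome,
    guides: dict[str, GuideSite],
    cfg: SimConfig,
    dataset: str = "sim",
) -> tuple[list[ScreenObservation], SimTruth]:
    """Draw one screen's logFCs with known gene/guide decomposition.

    gene effect  = -|coupling * z(log max expression)|
                   - penalty * n_downstream_essential + N(0, sd_gene^2)
    guide effect = sum of sequence weights over the context
                   - distance_bonus * 1[dist < window] + N(0, sd_guide^2)
    logFC        = gene + guide + N(0, sd_noise^2)
    """
    rng = rng_for(cfg.seed, "screen", dataset)
    sw = cfg.seq_weight_map

    expr = np.log(
        [max(genome.genes[g].expression_by_od.values()) for g in genome.genes]
    )
    z = (expr - expr.mean()) / (expr.std() or 1.0)
    gene_effects = {}
    for (gene_id, gene), zg in zip(genome.genes.items(), z):
        gene_effects[gene_id] = float(
            -abs(cfg.expression_coupling * zg)
            - cfg.downstream_essential_penalty * gene.n_downstream_essential
            + rng.normal(0.0, cfg.sd_gene_effect)
        )

    guide_effects = {}
    for gid, site in guides.items():
        seq_term = sum(
            w for (pos, base), w in sw.items() if _context_base(site, pos) == base
        )
        bonus = (
            -cfg.distance_bonus if site.dist_start_codon < cfg.distance_window else 0.0
        )
        guide_effects[gid] = float(
            seq_term + bonus + rng.normal(0.0, cfg.sd_guide_effect)
        )

    observations = []
    noise = {}
    for gid, site in guides.items():
        eps = float(rng.normal(0.0, cfg.sd_noise))
        noise[gid] = eps
        observations.append(
            ScreenObservation(
                guide_id=gid,
                gene_id=site.gene_id,
                dataset=dataset,
                logfc=gene_effects[site.gene_id] + guide_effects[gid] + eps,
            )
        )
    truth = SimTruth(
        gene_effects=gene_effects,
        guide_effects=guide_effects,
        noise=noise,
        config=asdict(cfg),
    )
    return observations, truth


def simulate_counts(
    observations: list[ScreenObservation],
    cfg: SimConfig,
):
    """Guide x sample count matrix for one screen.

    Input counts are negative-binomial around ``library_size / n_guides``;
    output means are input means scaled by 2^logFC; non-targeting controls
    have logFC 0 by construction; two replicates differ by a multiplicative
    depth factor. Returns a :class:`guidemix.counts.CountMatrix`.
    """
    import pandas as pd

    from .counts import CountMatrix

    rng = rng_for(cfg.seed, "counts")
    guide_ids = [o.guide_id for o in observations] + [
        f"NT{i:03d}" for i in range(cfg.n_nontargeting)
    ]
    gene_ids = [o.gene_id for o in observations] + ["-"] * cfg.n_nontargeting
    is_nt = [False] * len(observations) + [True] * cfg.n_nontargeting
    logfc = np.array([o.logfc for o in observations] + [0.0] * cfg.n_nontargeting)

    n_guides = len(guide_ids)
    mu_in = cfg.library_size / n_guides

    def draw(mean_vec: np.ndarray) -> np.ndarray:
        mean_vec = np.maximum(mean_vec, 1e-9)
        if cfg.nb_dispersion < 1e-8:
            return rng.poisson(mean_vec)
        r = 1.0 / cfg.nb_dispersion
        p = r / (r + mean_vec)
        return rng.negative_binomial(r, p)

    cols = {}
    meta = []
    for rep, scale in ((1, 1.0), (2, cfg.replicate_scale)):
        cols[f"input_r{rep}"] = draw(np.full(n_guides, mu_in * scale))
        meta.append(
            {"sample": f"input_r{rep}", "timepoint": "input", "replicate": rep,
             "is_input": True}
        )
        cols[f"out_r{rep}"] = draw(mu_in * scale * np.power(2.0, logfc))
        meta.append(
            {"sample": f"out_r{rep}", "timepoint": "t1", "replicate": rep,
             "is_input": False}
        )
    counts = pd.DataFrame(cols, index=guide_ids)
    sample_meta = pd.DataFrame(meta).set_index("sample")
    guide_meta = pd.DataFrame(
        {"gene_id": gene_ids, "is_nontargeting": is_nt}, index=guide_ids
    )
    return CountMatrix(counts=counts, sample_meta=sample_meta, guide_meta=guide_meta)
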