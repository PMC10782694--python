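# Methods

## The problem

A pooled CRISPRi depletion screen measures, for every guide RNA, the log2
fold-change (logFC) of its abundance between an input library and samples
collected after growth. For guides targeting genes whose silencing costs
fitness, that logFC mixes two signals: the fitness effect of knocking the
gene down, and how efficiently the particular guide silences it. Guide
design only controls the second, but the first dominates the variance, so
a model trained naively on logFC mostly learns properties of genes, not
guides.

## The model

guidemix separates the two signals with a mixed-effect random forest. For
observation *j* (one guide measured in one screen) of gene cluster *i*:

    y_ij = f(X_ij) + Z_ij · b_i + ε_ij,   b_i ~ N(0, D),   ε_ij ~ N(0, σ²)

* `f` — a random-forest regressor over 129 guide-level fixed-effect
  features: 120 one-hot indicators over the 30-nt target context (4 nt
  upstream, protospacer positions G1–G20, PAM P1–P3, 3 nt downstream;
  channels A/C/G/T), four minimum-free-energy features (guide:DNA hybrid,
  8-nt PAM-proximal seed hybrid, guide homodimer, guide monomer fold),
  absolute and relative distance to the start codon, distance to the
  transcription-unit start, longest homopolymer run, and a first-gene-in-
  operon indicator.
* `Z_ij · b_i` — a per-gene linear random effect over an intercept plus 9
  standardized gene/dataset features (min/max expression over growth, gene
  GC and length, downstream gene and downstream essential-gene counts in
  the operon, codon adaptation index, two treatment-coded dataset
  indicators). The random intercept absorbs per-gene and per-screen
  depletion scale, which is what lets raw logFCs from different screens be
  fused without explicit normalization.

Fitting alternates until the generalized log-likelihood (GLL) stabilizes:
refit the forest on `y` with current cluster effects removed; update each
cluster's coefficients by their best linear unbiased predictor (BLUP),
`b_i = D Z_i' V_i⁻¹ (y_i − f(X_i))` with `V_i = Z_i D Z_i' + σ² I`; update
`σ²` and `D` by their closed-form EM expressions. Initialization is
`b = 0`, `D = I`, `σ² = 1`; convergence is a relative GLL change below
1e-3 with a 50-iteration cap (the simulator presets converge in ~10–30);
the forest is refit with the same seed each iteration so the fitted state
is a deterministic function of (data, hyperparameters, seed). A singular
`D` during the GLL evaluation is ridge-regularized with logged jitter.
Prediction for new guides — including guides for genes never seen in
training — uses the fixed effect only.

Default forest hyperparameters (n_estimators 500, max_depth 15,
min_samples_leaf 5, max_features 0.3, bootstrap on) are midpoints of the
supported search space; `tune_hyperparameters` runs a seeded random search
over that space against a user-supplied objective (typically median
per-gene Spearman under gene-wise cross-validation). Test and acceptance
runs use 150-tree forests: recovery statistics are indistinguishable from
500 trees on the simulated screens and the fits run three times faster.

## Guide enumeration and features

CRISPRi inside an ORF requires the guide to anneal to the coding
(non-template) strand, so candidate sites appear on the mRNA-sense
sequence as CCN followed by the 20-nt target; the spacer and its 30-nt
context are reported in protospacer orientation. Distances anchor at the
left edge of the 20-nt target in sense coordinates (a guide whose target
starts at the first base of the start codon has distance 0); any
consistent anchor differs by a constant ≤ 23 nt. Library filters are
inclusive spacer GC bounds (default 30–85%) and forbidden motifs screened
on both strands of the spacer (default BbsI, GAAGAC/GTCTTC, the cloning
enzyme of typical pooled-library protocols).

Thermodynamics go through an injectable engine: ViennaRNA (python
bindings) for RNA folding and RNA:RNA duplexes in production; a
self-contained nearest-neighbor table engine as fallback; a constant stub
for tests. RNA:DNA hybrid energies are computed in every backend from the
Sugimoto 1995 RNA/DNA nearest-neighbor parameters on the
perfect-complement on-target duplex — this makes the invariant
`mfe_seed_hybrid ≥ mfe_hybrid` exact by construction, since the 8-nt seed
duplex is a sub-sum of the 20-nt duplex with all stacks stabilizing. The
nearest-neighbor engine's monomer and homodimer energies come from a
best-contiguous-stem scan (Xia 1998 stacks, hairpin loop ≥ 3 nt): crude
relative to full folding, monotone in duplex stability, and exactly 0
when no Watson-Crick self-pairing exists.

The codon adaptation index is the geometric mean of relative codon
adaptiveness over the CDS, excluding stops and the single-codon amino
acids (ATG, TGG).

## Cross-screen fusion

Two screens sharing a guide library are averaged guide-wise to form the
shared scale; an independent screen is mapped onto it by OLS on the
overlapping guides (`scaled = slope·x + intercept`), and those overlap
guides are dropped from the mapped screen to avoid duplicate
measurements. Activity scores (scaled logFC minus the gene's median
scaled logFC, median pooled across datasets, midpoint interpolation at
even counts) are produced for baseline models and diagnostics; genes with
fewer than 5 guides in any contributing dataset are removed first because
their medians are unstable. The mixed model itself consumes raw logFCs.
In cross-validation the scaling must be refit inside each training fold;
the `cv` command operates on featurized tables and therefore expects
fusion to have been run per fold when activity scores are the target.

## Count processing

Guide×sample count matrices are filtered at ≥ 1 count-per-million in ≥ 4
samples (inclusive; CPM on raw column sums). Per-sample normalization
factors are a trimmed mean of M-values computed on the non-targeting
control guides only (30% M-trim, 5% A-trim, precision weights, reference
= first input sample, factors rescaled to geometric mean 1), while
library sizes come from full column sums. Depletion is estimated as the
replicate-averaged normalized log-ratio with pseudo-count 0.5; the
control guides' median logFC is reported as a calibration statistic
(~0 when normalization is adequate). This estimator replaces a
count-model GLM deliberately: downstream modelling consumes logFC point
estimates only, and the log-ratio estimator is fully specified, exactly
testable, and recovers simulated truth with RMSE ≈ 0.15 at the default
library size. Significance testing of per-guide depletion is out of
scope.

## Evaluation

True guide efficiency is never observed, so models are scored gene-wise:
`split_genewise` shuffles genes with a seed and deals them into k folds,
holding out every guide of a held-out gene together. Metrics:

* median per-gene Spearman (average-rank ties; genes with < 2 guides or
  constant vectors are skipped with a log message);
* top-20% enrichment — per gene, the most-depleted 20% by observation
  (set size ⌈0.2·n⌉, ties broken by index) versus the top 20% by
  prediction, pooled overlap over pooled predicted-set size, as a
  percentage; a per-gene-mean variant is available by flag; genes with
  < 5 guides are skipped;
* top-k PPV — predicted positives are each gene's k best-predicted
  guides; true positives are guides with logFC ≤ min(logFC) + log2(N)
  ("within N-fold of the strongest depletion", on the fold-change scale);
  TP/(TP+FP) pooled over genes;
* Hamming diagnostics — min and median pairwise Hamming distance between
  train and test context sequences, as a leakage/novelty check.

Both ranking metrics are invariant to monotone transforms of the
predictions; under permuted predictions enrichment is calibrated at ~20%.

## Attribution

Per-guide, per-feature attributions are exact Shapley values for the tree
ensemble under path-dependent conditional expectations, computed by the
polynomial-time tree-traversal algorithm (numba-compiled kernel with a
pure-python reference implementation cross-checked in the tests;
brute-force subset enumeration is the oracle on small trees). Inputs are
rounded through float32 before traversal because that is the precision at
which the underlying forest compares values with split thresholds;
without it, knife-edge feature values can be attributed along branches
the model never takes. Local accuracy (base value + row sum = prediction)
holds to ~1e-15. A model-agnostic permutation sampler is available as a
fallback; it converges to the same values but satisfies local accuracy
only approximately at finite sample sizes.

On top of raw attributions: mean-|value| global importance ranking; a
median-based interaction table that compares the observed joint
attribution of a feature pair in +/+ samples against the additive
expectation from +/− and −/+ strata (nonzero deviation flags
non-additivity; empty strata are reported as missing); and a distance
profile contrasting mean attribution of the start-codon-distance feature
within versus beyond a 60-nt window, optionally stratified by the
first-gene-in-operon indicator. "Present" for one-hot features means the
indicator is 1; continuous features require a user-supplied threshold.
Full pairwise Shapley-interaction matrices are not computed; the ranked
pair iterator orders candidate pairs by the interaction table's |+/+
deviation| instead.

## The screen simulator

The simulator is the package's ground-truthed test bed. It emulates a
pooled essentiality screen: genes in consecutive transcription units
(default 2 genes/TU), uniform-composition CDS sequences (default 450 nt),
log-normal expression measured at ten ODs with 10% jitter, Bernoulli
essentiality (default 30%). Effects are additive on the log2 scale with
depletion negative:

    gene_effect  = −|coupling · z(log max expr)| − 0.3 · n_downstream_essential + N(0, sd_gene²)
    guide_effect = Σ seq_weights(position, base) − bonus · 1[dist < 60 nt] + N(0, sd_guide²)
    logFC        = gene_effect + guide_effect + N(0, sd_noise²)

The default preset is 300 genes × 10 guides with effect SDs 2.0 (gene),
1.0 (guide), 0.5 (noise), expression coupling 1.0, distance bonus 0.5,
seed 7. The sequence weights qualitatively mirror the sequence
preferences reported for dCas9 silencing (C favorable at the PAM's
variable position and directly after the PAM, G unfavorable after the
PAM, A/G unfavorable at guide position 20), so attribution tests can
assert sign recovery. Counts are negative-binomial (dispersion 0.01,
typical of deeply sequenced plasmid amplicon libraries) around
library_size/n_guides, output means scaled by 2^logFC, two replicates
with a 1.25× depth factor, and 50 non-targeting controls with logFC 0 by
construction. Observed logFC equals gene + guide + noise exactly, by
construction, and all three components are emitted.

What the simulator does not emulate: realistic sequence composition and
codon structure, off-target effects, PCR/sequencing error, growth-phase
dynamics across multiple timepoints, or guide-position effects beyond the
additive sequence-weight model. Passing recovery tests therefore shows
the estimation machinery is correct under the generative model, not that
the learned design rules transfer to any particular organism.

## Design choices that were genuinely open

* **Gene-effect recovery metric.** The generator deliberately couples
  gene effects to expression and operon context, so the EM attributes
  that share of the effect to the corresponding random slopes. The
  model's estimate of a gene's effect is therefore the full per-gene
  random effect `Z_g·b̂_g` (measured r ≈ 0.99 against truth on the
  default preset), not the intercept alone (r ≈ 0.90); recovery is
  asserted on the former.
* **Intercept in Z.** The random design includes an intercept; it is the
  component that replaces explicit between-screen normalization.
* **Distance anchor.** Left edge of the target 20-mer in sense
  coordinates; a PAM anchor would shift every distance by a constant.
* **Pooled medians and pooled PPV.** Per-gene medians for activity
  scores pool datasets; PPV pools TP/FP across genes rather than
  averaging per-gene ratios. Both have per-gene variants by flag.
* **Even-count medians** use midpoint interpolation.
* **Degenerate inputs.** Constant prediction vectors within a gene are
  skipped (rank correlation undefined); genes below the guide-count
  floors are dropped with log messages rather than scored on unstable
  sets; an all-+/+ interaction stratum reports missing cells rather than
  fabricating expectations.

## Known limitations

* The nearest-neighbor fallback engine underestimates monomer/homodimer
  structure relative to a full folding engine (contiguous stems only).
* The EM's GLL can creep below the relative tolerance very slowly on
  tiny, weakly identified problems; variance-component estimates are
  already stable when it does.
* Guide-wise (as opposed to gene-wise) cross-validation of the fixed
  effect is intentionally unsupported as a headline metric: with gene
  effects removed there is no guide-level ground truth to validate
  against outside simulation.
* Model archives serialize the fitted sklearn forest with joblib and are
  not portable across major sklearn versions; the archive records the
  feature-registry hash and refuses to predict on a mismatched registry.
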