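# guidemix

Mixed-effect modelling of bacterial CRISPRi depletion screens: design
guides, fuse screens, and learn guide efficiency that transfers to new
genes.

## Why

Pooled CRISPRi fitness screens are the largest available source of guide-
efficiency information in bacteria, but they measure it only indirectly:
a guide's depletion (log2 fold-change vs the input library, anchored by
non-targeting controls) mixes the fitness cost of silencing the targeted
gene with the efficiency of the guide itself — and the gene term
dominates. guidemix separates the two with a mixed-effect random forest

    y_ij = f(X_ij) + Z_ij · b_i + ε_ij,   b_i ~ N(0, D),   ε_ij ~ N(0, σ²)

where the cluster structure is "guides targeting the same gene": a
per-gene linear random effect `Z·b` (intercept + 9 standardized gene and
dataset features) absorbs gene-level depletion scale and confounders,
while a random forest `f` over 129 guide-sequence features (one-hot
30-nt target context, hybridization energies, distances, homopolymer,
operon position) learns guide efficiency. The two are fit jointly by EM
with BLUP updates for `b_i` and closed-form variance-component updates;
prediction for new guides uses `f` alone, so it needs nothing but the
target sequence context. The per-gene random intercept doubles as an
automatic between-screen normalizer, letting raw logFCs from independent
screens be fused directly.

The package is a complete working environment for this class of model:
guide enumeration and featurization from FASTA/GFF, cross-screen scaling
and activity scores, count filtering and control-guide TMM normalization,
gene-wise cross-validation with the screen-appropriate metrics (median
per-gene Spearman, top-20% enrichment, top-k PPV), exact tree-Shapley
attribution with interaction and distance analyses, and a fully
ground-truthed screen simulator that makes every stage testable without
external data.

## Worked example

Simulate a screen with known truth, estimate logFCs from counts, fit the
mixed model, and check what it learned:

```bash
$ guidemix simulate --preset small --seed 11 --outdir screen
simulated 480 guides over 60 genes -> screen
$ guidemix counts --counts screen/counts.tsv --samples screen/samples.tsv \
    --guide-meta screen/guide_meta.tsv --out logfc.tsv
logFCs for 530 guides -> logfc.tsv
$ guidemix featurize --guides screen/guides.tsv \
    --observations screen/observations.tsv --genome-dir screen \
    --engine auto --out-prefix feat
feature blocks -> feat.fixed.tsv / .random.tsv / .table.tsv
$ guidemix train --features-prefix feat --seed 5 --n-estimators 150 \
    --out model.joblib
fit in 49 EM iterations (converged=True, sigma2=0.624) -> model.joblib
```

The simulator wrote the true decomposition to `screen/truth.json`, so the
claim that the fixed effect isolates *guide* efficiency is checkable:

```python
import json, numpy as np, pandas as pd, joblib
from scipy.stats import spearmanr
from guidemix.merf import predict_fixed

state = joblib.load("model.joblib")["state"]
X = pd.read_csv("feat.fixed.tsv", sep="\t", index_col=0)
truth = json.load(open("screen/truth.json"))

scores = predict_fixed(state, X.to_numpy())
true_guide = np.array(
    [truth["guide_effects"][i.rsplit("|", 1)[0]] for i in X.index]
)
print(f"Spearman(fixed-effect score, true guide effect) = "
      f"{spearmanr(scores, true_guide).statistic:.3f}")
```

```
Spearman(fixed-effect score, true guide effect) = 0.800
```

Raw depletion ranks true guide efficiency at only ρ = 0.49 on the same
screen (gene effects drown the guide signal); the fixed effect recovers
it at ρ = 0.80, even though the model never saw the decomposition. Gene-wise cross-validation, attribution and the other
commands follow the same pattern — `guidemix --help` lists them
(`design`, `featurize`, `fuse`, `counts`, `train`, `cv`, `predict`,
`evaluate`, `explain`, `simulate`); every command writes a manifest JSON
(config echo, input checksums, package version) and takes explicit seeds.

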