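# molopt

Conditional transformer molecular optimization beyond matched molecular
pairs: mine molecular-pair datasets from a publication-grouped corpus under
six pairing criteria, train a property-change-conditioned SMILES
encoder-decoder on them, and evaluate generated molecules against property
and structure constraints.

## The problem

Medicinal chemists improve a starting molecule by applying structural
transformations that shift its property profile — logD, solubility,
metabolic clearance — while staying in familiar chemical space. Matched
molecular pairs (MMPs, two molecules differing by a single localized
transformation) are the classic formalization, but many useful edits go
beyond a single transformation: several simultaneous modifications, or
rebuilding the molecule around the same scaffold.

`molopt` treats optimization as sequence translation. From a corpus of
molecules grouped by publication (one publication ≈ one optimization
project), it extracts pairs (X, Y, Z): source molecule X, target molecule Y
reported in the same publication, and the property change Z between them,
encoded as three discrete tokens —

```
LogD_change_(0.1, 0.3]   Solubility_low->high   Clearance_no_change
```

(logD changes in 0.2-wide bins over (−6.9, 6.9] plus two open end bins;
solubility and clearance as low/high category moves with thresholds at
1.7 log10 µM and 1.3 log10 µL/min/mg). Which pairs are mined is governed by
one of six criteria: single-cut MMP with an R-group heavy-atom ratio ≤ 0.33,
Tanimoto (ECFP4) ≥ 0.5 / [0.5, 0.7) / ≥ 0.7, identical Murcko scaffold, or
identical generic (all-carbon, single-bond) scaffold. A transformer
encoder-decoder is trained per dataset on `[Z tokens] + [X SMILES] → Y
SMILES` and sampled multinomially at test time; the training criterion
shapes the kind of edit the model proposes.

Generated molecules are scored on **successful property constraints** (all
three properties inside error-adjusted bands: |ΔlogD from target| ≤ 0.4,
solubility low ≤ 2.3 / high ≥ 1.1, clearance low ≤ 1.65 / high ≥ 0.95) and
**successful structure constraints** (the training criterion holds between
start and generated molecule). Baselines: the identical network trained
without property tokens (Transformer-U) and random draws from the
structure-satisfying test pool (Random; 100% structure success by
construction).

Everything runs on synthetic, fully enumerable corpora built by the package
itself (scaffold-template families with substituent grammars and a
deterministic property oracle), so the full pipeline is testable on one CPU
without external data. The transformer runs on a small NumPy autograd
included in the package.

## Worked example

```python
from dataclasses import replace

from molopt import (
    Criterion, FixtureConfig, DESK_CONFIG,
    generate_corpus, prepare_corpus, extract_pairs,
    train, train_unconditional, sample, evaluate_run, random_baseline,
)

# synthetic publication-structured corpus and scaffold-pair dataset
records, _ = generate_corpus(FixtureConfig(n_publications=200, seed=1))
dataset = extract_pairs(prepare_corpus(records), Criterion.SCAFFOLD)
print(dataset.sizes())

# property-conditioned transformer vs the unconditional variant
config = replace(DESK_CONFIG, epochs=6, warmup_steps=400, seed=1)
model = train(dataset, config)
model_u = train_unconditional(dataset, config)

# sample 10 unique molecules per test input and score the run
inputs = dataset.test[:25]
metrics = evaluate_run(
    [sample(model, p.source, p.change, n_unique=10, seed=1) for p in inputs],
    Criterion.SCAFFOLD,
)
print(metrics.property_pct, metrics.structure_pct, metrics.combined_pct)
print(random_baseline(dataset.test, Criterion.SCAFFOLD, seed=1).property_pct_mean)
```

One run of this pipeline (the numbers move by several points with training
and sampling seeds; the small models have substantial seed variance):

```
{'train': 18530, 'valid': 914, 'test': 1608}
40.4  98.4  40.0     # conditional: property / structure / combined %
33.5                 # Random baseline property success %
```

The conditional model keeps the scaffold constraint essentially always and
places 40-70% of its generations (depending on training seed) inside all
three property bands; random draws from the structure-satisfying test pool
sit at the pool's base rate of ~30-34%. A command-line
interface wraps the same steps (`molopt simulate`, `molopt build-pairs`,
`molopt train`, `molopt sample`, `molopt evaluate`,
`molopt baseline-random`).

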