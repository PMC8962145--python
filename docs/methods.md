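# Methods

## The task

Molecular optimization starts from a molecule with a known liability — too
lipophilic, poorly soluble, cleared too fast — and asks for structural
analogs that fix it. `molopt` treats this as conditional sequence
translation: a transformer encoder-decoder is trained on *molecular pairs*
(X, Y, Z), where X and Y are two molecules reported in the same publication
(a proxy for "same optimization project") and Z encodes how three ADMET
properties — logD, solubility (log10 µM) and intrinsic clearance
(log10 µL/min/mg) — change from X to Y. At inference the model receives a
starting molecule plus a requested property change and samples candidate
targets.

The pairing criterion used to mine the training set shapes what kind of
edit the model learns. Six criteria are implemented:

| criterion | predicate |
|---|---|
| `mmp` | single-cut matched molecular pair, R-group/molecule heavy-atom ratio ≤ 0.33 on both sides |
| `sim05` | ECFP4 Tanimoto ≥ 0.5 |
| `sim0507` | Tanimoto in [0.5, 0.7) |
| `sim07` | Tanimoto ≥ 0.7 |
| `scaffold` | identical Murcko scaffold |
| `scaffold-generic` | identical all-carbon single-bond (generic) scaffold |

MMP matching enumerates every acyclic single-bond cut of both molecules and
compares the constant parts by canonical SMILES; a hydrogen counts as an
R-group with zero heavy atoms, so H→CH3 transformations are pairs. Double
and triple cuts are out of scope — a single cut is the ordinary notion of
"one transformation".

## Corpus filters

Molecules are standardized (largest fragment, neutralized, sanitized,
explicit hydrogens removed, stereochemistry kept) and kept when they have
10–50 heavy atoms, at least one ring, and every property within 3 standard
deviations of the corpus mean. Publications must be from year ≥ 2000 and
contribute 10–60 molecules. Mined unordered pairs are deduplicated on the
canonical SMILES pair, keeping the earliest reporting year (ties broken by
publication id), then expanded with the reverse pair (Y, X, invert(Z)).
Datasets are split by publication year: train 2000–2017, validation 2018,
test 2019–2020; reverse pairs stay in their forward pair's split.

## Property-change encoding

Solubility and clearance changes are categorical: low/high thresholds at
1.7 (50 µM) and 1.3 (20 µL/min/mg) on the log10 scale, "low" inclusive of
the threshold, giving three tokens per property (`low->high`, `high->low`,
`no_change`). The logD change is binned into left-open/right-closed
intervals of width 0.2 tiling (−6.9, 6.9], plus two open end bins — 71
tokens, enumerated programmatically. A delta exactly on an edge belongs to
the bin whose right edge it is. Token strings use one fixed ASCII rendering
(`->`, single space after the comma) and double as vocabulary entries.

## Model

A standard post-norm transformer: token embeddings scaled by √width plus
sinusoidal positional encodings; stacks of identical encoder and decoder
layers with multi-head attention and ReLU feed-forward sublayers; teacher
forcing with token cross-entropy (padding masked); Adam with the
inverse-square-root schedule (linear warmup to the peak at `warmup_steps`,
then ∝ step^−1/2 decay); the checkpoint with the lowest validation loss is
kept. Generation is autoregressive multinomial sampling from the full
next-token distribution, repeated until 10 unique valid molecules distinct
from the start are collected or a `max_attempts` cap (default 10 × the
requested count) is reached; sampled strings are validity-filtered before
deduplication.

The tensor backend is a small reverse-mode autograd over NumPy written for
this package (`molopt.autograd`): broadcast-aware arithmetic, batched
matmul, fused softmax / layer-norm / cross-entropy kernels, embedding
scatter, Adam. Everything is float32, CPU, single-device; with a fixed seed
two runs produce identical loss traces.

The unconditional baseline ("Transformer-U") is the identical network
trained on the same pairs with the three property tokens stripped from the
source sequence. The Random baseline draws, for each test input, 10
molecules satisfying the structure constraint from the unique molecules of
the test set (five draws with different seeds, averaged); its structure
success is 100% by construction.

Desk-scale defaults (`DESK_CONFIG`): 2 layers, width 64, feed-forward 128,
4 heads, dropout 0.1, batch 64, peak learning rate reached after a few
hundred steps. All architecture numbers are config; a full-scale profile
(more layers/width, batch 128, 4000 warmup steps) is a `ModelConfig` away
but is not exercised by the test suite.

## Evaluation

A generated molecule fulfils the *property constraint* when all three
properties land in error-adjusted bands around the targets implied by the
input: |logD − target| ≤ 0.4, where the point target is the start logD plus
the midpoint of the requested bin (open bins use edge ∓ 0.1 — the bin
conditions on an interval, the metric needs a point); solubility "low"
means ≤ 2.3 and "high" means ≥ 1.1 (threshold 1.7 widened by a property
-predictor error of 0.6); clearance analogously 1.3 ± 0.35. The bands are
configuration (`ErrorBands`), since they derive from the error of whatever
property predictor is plugged in; the boundary values are stored as exact
decimals so success flags flip exactly at them. The *structure constraint*
re-applies the training criterion between start and generated molecule;
similarity bands exclude 1.0 because generated molecules must differ from
the start. Identical-to-start generations are filtered during sampling.

Analytics: the cross-constraint heatmap takes each model's combined
successes (rows) and reports the fraction also satisfying every other
criterion (columns) — its diagonal is 1 by construction and containment
relations (`sim07` ⊆ `sim05`, `scaffold` ⊆ `scaffold-generic`) force unit
columns; and Tanimoto similarity histograms compare training pairs with
generated pairs split by success category.

## Synthetic corpus and property oracle

Real corpora for this task come from literature databases with property
values from trained predictors; neither is available at desk scale, so the
package generates its own study system.

*Chemistry.* Three template families, each a parent two-ring scaffold and a
heteroatom-swapped sibling sharing its generic scaffold, with three marked
substitution positions filled from a nine-fragment alphabet (H, C, CC, F,
Cl, O, OC, N, C#N) — between ~800 and ~1500 molecules per family after
canonicalization, all passing the corpus filters by construction. The full
library is enumerable, so for any start molecule and requested change the
exact set of reachable targets (`grammar_truth`) can be computed by brute
force.

*Properties.* The default oracle is deterministic and descriptor-additive:
pseudo-logD rises with carbon/halogen counts and falls with N/O counts;
pseudo-solubility is anti-correlated with pseudo-logD; pseudo-clearance
uses a distinct combination (size and halogens up, nitrogens down). Weights
(`ORACLE_WEIGHTS`) are chosen so drug-sized molecules populate both sides
of the 1.7/1.3 category thresholds and one substituent edit moves logD by
roughly one to a few encoder bins. Any `molecule -> PropertyProfile`
callable can replace it, which is also how a trained predictor would be
plugged in.

*Publications.* Each publication picks one family (sometimes using both the
parent and the heteroatom-swapped template, so generic-scaffold-only pairs
occur) and draws 10–14 molecules from a contiguous pseudo-logD window of
0.8 log units — one project optimizing in a local property region, which is
the rationale for mining same-publication pairs in the first place. A small
fraction (0.1) of publications draw from the whole family instead, keeping
pairs with large property changes a minority, as in literature corpora.
Years are uniform over 2000–2020 so all three splits are populated. The
window span and family size matter: the window sets how property-local the
mined pairs are, and the family size keeps molecule reuse across
publications low (~1.5 occurrences per molecule), so the test-set pool the
Random baseline draws from is property-diverse while each start molecule's
training partners are property-close.

*What the generator does not emulate.* Activity cliffs, assay noise,
non-additive substituent interactions, realistic ADMET value distributions,
and chemistry beyond two-ring systems with acyclic substituents. Passing
the benchmark shows the pipeline mines pairs correctly and that
conditioning on property-change tokens steers generation on a learnable
structure-property landscape — it does not certify performance on real
project data.

## Benchmark problem sizes

The package's own experiments (tests and `scripts/acceptance.py`) run the
scaffold-criterion benchmark on a 120-publication corpus (~11k directed
training pairs), the desk-scale model for a few epochs (several hundred
optimizer steps), 25–30 test inputs with 10 unique samples each, and the
Random baseline at five repeats; the model-ordering check averages three
training/sampling seeds over a fixed mined dataset, mirroring a fixed
corpus with stochastic training. These sizes were chosen so the whole
pipeline — mining through evaluation — reruns from scratch in minutes on
one CPU core while leaving the qualitative ordering of the three models
(conditional > unconditional > random) resolvable above seed noise.

## Known limitations

* Similarity uses one fixed fingerprint configuration (binary, 2048-bit,
  radius 2); counted fingerprints or other radii would shift the Tanimoto
  bands.
* MMP matching is single-cut only; transformations that require double cuts
  (linker replacements) are never paired.
* The NumPy backend is deliberately minimal: no GPU, no mixed precision, no
  beam search or nucleus sampling; sampling recomputes the decoder per
  step (no key-value cache), which is fine at sequence length ~40.
* Validation splits of small synthetic corpora can be tiny for sparse
  criteria (`sim07`, `mmp`); when a split is empty the trainer falls back
  to the last training loss for checkpoint selection.
* The success bands are wide relative to the synthetic oracle's dynamic
  range, so absolute success percentages are not comparable to any real
  study; only orderings and invariants are meaningful at this scale.
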