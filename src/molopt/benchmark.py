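"""End-to-end desk-scale benchmark: corpus -> pairs -> models -> metrics.

Runs the whole method on a synthetic corpus for one pairing criterion:
mine the pair dataset, train the conditional transformer and the
unconditional variant, sample candidates for test inputs, and score
property / structure / combined success together with the Random baseline.
This is the scaled-down replication of the full-corpus experiment and the
basis of the package's acceptance checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .dataset_builder import Criterion, PairDataset, extract_pairs, prepare_corpus
from .evaluation import (
    DEFAULT_BANDS,
    BaselineMetrics,
    ErrorBands,
    RunMetrics,
    evaluate_run,
    random_baseline,
)
from .fixtures import FixtureConfig, generate_corpus
from .property_encoding import PropertyOracle, synthetic_oracle
from .transformer import DESK_CONFIG, ModelConfig, TrainedModel, sample, train


@dataclass(frozen=True)
class BenchmarkConfig:
    criterion: Criterion = Criterion.SCAFFOLD
    fixture: FixtureConfig = field(default_factory=lambda: FixtureConfig(n_publications=60))
    model: ModelConfig = DESK_CONFIG
    bands: ErrorBands = DEFAULT_BANDS
    n_unique: int = 10
    max_test_inputs: int = 30
    seed: int = 0


@dataclass
class BenchmarkResult:
    criterion: Criterion
    dataset_sizes: dict[str, int]
    transformer: RunMetrics
    transformer_u: RunMetrics
    random: BaselineMetrics
    transformer_model: TrainedModel | None = None
    transformer_u_model: TrainedModel | None = None
    dataset: PairDataset | None = None


def build_dataset(
    config: BenchmarkConfig, oracle: PropertyOracle = synthetic_oracle
) -> PairDataset:
    fixture = replace(config.fixture, seed=config.seed)
    records, _library = generate_corpus(fixture, oracle)
    corpus = prepare_corpus(records)
    return extract_pairs(corpus, config.criterion)


def sample_test_inputs(
    dataset: PairDataset, max_inputs: int, rng: np.random.Generator
) -> list:
    """A deterministic subsample of test pairs used as (start, constraint) inputs."""
    pairs = dataset.test
    if len(pairs) <= max_inputs:
        return list(pairs)
    idx = rng.choice(len(pairs), size=max_inputs, replace=False)
    return [pairs[int(i)] for i in sorted(idx)]


def generate_for_inputs(
    trained: TrainedModel,
    inputs,
    n_unique: int,
    rng: np.random.Generator,
) -> list:
    results = []
    for pair in inputs:
        results.append(
            sample(trained, pair.source, pair.change, n_unique=n_unique, seed=rng)
        )
    return results


@dataclass
class SeedOutcome:
    """Metrics of one training/sampling seed on a fixed pair dataset."""

    seed: int
    transformer: RunMetrics
    transformer_u: RunMetrics
    random: BaselineMetrics


@dataclass
class OrderingResult:
    """Multi-seed comparison of the three models on one dataset."""

    criterion: Criterion
    dataset_sizes: dict[str, int]
    outcomes: list[SeedOutcome]

    def mean(self, which: str) -> float:
        """Mean property-success %% over seeds for transformer / transformer_u / random."""
        values = []
        for o in self.outcomes:
            if which == "random":
                values.append(o.random.property_pct_mean)
            else:
                values.append(getattr(o, which).property_pct)
        return float(np.mean(values))

    def mean_structure(self, which: str) -> float:
        values = [
            o.random.structure_pct if which == "random" else getattr(o, which).structure_pct
            for o in self.outcomes
        ]
        return float(np.mean(values))


def ordering_benchmark(
    dataset: PairDataset,
    model_config: ModelConfig,
    seeds=(0, 1, 2),
    n_inputs: int = 25,
    n_unique: int = 10,
    bands: ErrorBands = DEFAULT_BANDS,
    oracle: PropertyOracle = synthetic_oracle,
) -> OrderingResult:
    """Score conditional vs unconditional vs random over several sampling seeds.

    Mirrors the full-scale protocol: the pair dataset and the two trained
    models are fixed, while generation (multinomial sampling) and the Random
    baseline's draws are repeated with different seeds.  Returns per-seed
    metrics over a common set of test inputs.
    """
    conditional = train(dataset, model_config, conditional=True)
    unconditional = train(dataset, model_config, conditional=False)
    input_rng = np.random.default_rng(model_config.seed + 500)
    inputs = sample_test_inputs(dataset, n_inputs, input_rng)

    outcomes = []
    for seed in seeds:
        rng = np.random.default_rng(seed + 1000)
        results_c = generate_for_inputs(conditional, inputs, n_unique, rng)
        results_u = generate_for_inputs(unconditional, inputs, n_unique, rng)
        outcomes.append(
            SeedOutcome(
                seed=seed,
                transformer=evaluate_run(results_c, dataset.criterion, bands, oracle),
                transformer_u=evaluate_run(results_u, dataset.criterion, bands, oracle),
                random=random_baseline(
                    dataset.test,
                    dataset.criterion,
                    bands,
                    oracle,
                    fraction=max(0.01, len(inputs) / max(len(dataset.test), 1)),
                    repeats=5,
                    n=n_unique,
                    seed=seed + 900,
                ),
            )
        )
    return OrderingResult(
        criterion=dataset.criterion,
        dataset_sizes=dataset.sizes(),
        outcomes=outcomes,
    )


def run_benchmark(
    config: BenchmarkConfig,
    oracle: PropertyOracle = synthetic_oracle,
    keep_models: bool = False,
) -> BenchmarkResult:
    """Run the full pipeline for one criterion and score all three models."""
    dataset = build_dataset(config, oracle)
    if not dataset.train or not dataset.test:
        raise ValueError(
            f"benchmark corpus produced empty splits for {config.criterion}: "
            f"{dataset.sizes()}"
        )
    model_cfg = replace(config.model, seed=config.seed)
    conditional = train(dataset, model_cfg, conditional=True)
    unconditional = train(dataset, model_cfg, conditional=False)

    rng = np.random.default_rng(config.seed + 10_000)
    inputs = sample_test_inputs(dataset, config.max_test_inputs, rng)
    results_c = generate_for_inputs(conditional, inputs, config.n_unique, rng)
    results_u = generate_for_inputs(unconditional, inputs, config.n_unique, rng)

    metrics_c = evaluate_run(results_c, config.criterion, config.bands, oracle)
    metrics_u = evaluate_run(results_u, config.criterion, config.bands, oracle)
    metrics_r = random_baseline(
        dataset.test,
        config.criterion,
        config.bands,
        oracle,
        fraction=max(0.01, len(inputs) / max(len(dataset.test), 1)),
        repeats=5,
        n=config.n_unique,
        seed=config.seed + 20_000,
    )
    return BenchmarkResult(
        criterion=config.criterion,
        dataset_sizes=dataset.sizes(),
        transformer=metrics_c,
        transformer_u=metrics_u,
        random=metrics_r,
        transformer_model=conditional if keep_models else None,
        transformer_u_model=unconditional if keep_models else None,
        dataset=dataset if keep_models else None,
    )
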