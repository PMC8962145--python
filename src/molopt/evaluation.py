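"""Success metrics for generated molecules, baselines and dataset analytics.

A generated molecule succeeds on *properties* when its (predicted) logD,
solubility and clearance simultaneously fall inside error-adjusted bands
around the requested targets: |logD - target| <= 0.4; solubility counts as
"low" up to 2.3 and as "high" from 1.1 (the 1.7 threshold widened by the
property predictor's test error 0.6); clearance analogously 1.3 +/- 0.35.
It succeeds on *structure* when its relation to the starting molecule
satisfies the training dataset's pairing criterion (MMP / Tanimoto band /
scaffold equality).

Also here: the Random baseline (structure-satisfying molecules drawn from
the test pool — 100% structure success by construction), the
cross-constraint heatmap (which other structure constraints the combined
successes of each model satisfy), and Tanimoto similarity distributions of
training vs generated pairs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .chem_ops import CanonicalMolecule, MoleculeError, standardize, tanimoto
from .dataset_builder import Criterion, MoleculeRecord, MolecularPair, is_mmp, pair_predicate
from .property_encoding import (
    HIGH,
    HIGH_TO_LOW,
    LOW,
    LOW_TO_HIGH,
    PropertyChange,
    PropertyOracle,
    PropertyProfile,
    categorize,
    logd_bin_bounds,
    synthetic_oracle,
)
from .transformer import GenerationResult

#: Half-width added to the logD target and to the 1.7 / 1.3 category
#: thresholds; these derive from a property predictor's test RMSE, so they
#: are configuration, not constants of the method.
DEFAULT_LOGD_TOLERANCE = 0.4
DEFAULT_SOLUBILITY_ERROR = 0.6
DEFAULT_CLEARANCE_ERROR = 0.35


@dataclass(frozen=True)
class ErrorBands:
    """Error-adjusted acceptance bands for the three properties.

    ``solubility_band`` and ``clearance_band`` are (low_max, high_min):
    a value passes a "low" target iff value <= low_max and a "high" target
    iff value >= high_min.  low_max > high_min (overlapping acceptance) is
    deliberate — the predictor error makes the middle zone pass either way.
    """

    logd_tolerance: float = DEFAULT_LOGD_TOLERANCE
    # 1.7 -/+ 0.6 and 1.3 -/+ 0.35, written as the exact decimal boundary
    # values so the flags flip exactly at them (no float-sum artifacts)
    solubility_band: tuple[float, float] = (2.3, 1.1)
    clearance_band: tuple[float, float] = (1.65, 0.95)


DEFAULT_BANDS = ErrorBands()


@dataclass(frozen=True)
class TargetSpec:
    """Desired point logD and categories implied by (start profile, change)."""

    logd_target: float
    solubility_category: str  # "low" / "high"
    clearance_category: str


def logd_point_target(start_logd: float, logd_token: str) -> float:
    """Point logD target: start + requested-bin midpoint (open bins: edge ∓ 0.1)."""
    lo, hi = logd_bin_bounds(logd_token)
    if math.isinf(lo):
        delta = hi - 0.1
    elif math.isinf(hi):
        delta = lo + 0.1
    else:
        delta = (lo + hi) / 2.0
    return start_logd + delta


def _target_category(property_name: str, start_value: float, token: str) -> str:
    if token.endswith(LOW_TO_HIGH):
        return HIGH
    if token.endswith(HIGH_TO_LOW):
        return LOW
    return categorize(property_name, start_value)


def make_target_spec(start: PropertyProfile, change: PropertyChange) -> TargetSpec:
    """Resolve a property-change constraint into concrete targets."""
    return TargetSpec(
        logd_target=logd_point_target(start.logd, change.logd_token),
        solubility_category=_target_category(
            "solubility", start.solubility, change.solubility_token
        ),
        clearance_category=_target_category(
            "clearance", start.clearance, change.clearance_token
        ),
    )


def _category_pass(value: float, target: str, band: tuple[float, float]) -> bool:
    low_max, high_min = band
    return value <= low_max if target == LOW else value >= high_min


def property_success(
    generated: PropertyProfile,
    target: TargetSpec,
    bands: ErrorBands = DEFAULT_BANDS,
) -> tuple[bool, dict[str, bool]]:
    """Do all three properties fall in their error-adjusted bands?"""
    flags = {
        "logd": abs(generated.logd - target.logd_target) <= bands.logd_tolerance,
        "solubility": _category_pass(
            generated.solubility, target.solubility_category, bands.solubility_band
        ),
        "clearance": _category_pass(
            generated.clearance, target.clearance_category, bands.clearance_band
        ),
    }
    return all(flags.values()), flags


def structure_success(
    start: CanonicalMolecule, generated_smiles: str, criterion: Criterion
) -> bool:
    """Does (start, generated) satisfy the training criterion's constraint?

    Similarity criteria use [0.5, 1.0) / [0.5, 0.7) / [0.7, 1.0): similarity
    1.0 is excluded since generated molecules must differ from the start.
    An unparsable generated SMILES is a failure, not an error.
    """
    try:
        generated = standardize(generated_smiles)
    except MoleculeError:
        return False
    if generated.smiles == start.smiles:
        return False
    if criterion in (Criterion.SIM05, Criterion.SIM07):
        t = tanimoto(start, generated)
        lo = 0.5 if criterion == Criterion.SIM05 else 0.7
        return lo <= t < 1.0
    if (
        criterion in (Criterion.SCAFFOLD, Criterion.SCAFFOLD_GENERIC)
        and generated.ring_count == 0
    ):
        return False  # ring-free generations cannot share a scaffold
    return pair_predicate(
        criterion,
        _bare_record(start),
        _bare_record(generated),
    )


def _bare_record(mol: CanonicalMolecule) -> MoleculeRecord:
    return MoleculeRecord(mol, "", 2000, PropertyProfile(0.0, 0.0, 0.0))


@dataclass
class SuccessRecord:
    """Per-generated-molecule outcome."""

    start_smiles: str
    generated_smiles: str
    property_success: bool
    structure_success: bool
    property_flags: dict[str, bool] = field(default_factory=dict)

    @property
    def combined(self) -> bool:
        return self.property_success and self.structure_success


@dataclass
class RunMetrics:
    """Aggregate percentages over all generated molecules of a run."""

    property_pct: float
    structure_pct: float
    combined_pct: float
    n_generated: int
    records: list[SuccessRecord] = field(default_factory=list)


def evaluate_run(
    results: Sequence[GenerationResult],
    criterion: Criterion,
    bands: ErrorBands = DEFAULT_BANDS,
    oracle: PropertyOracle = synthetic_oracle,
) -> RunMetrics:
    """Score every generated molecule of a sampling run.

    The property constraint of each result's input is resolved against the
    start molecule's oracle profile; generated molecules are scored with the
    same oracle.
    """
    if not results:
        raise ValueError("no generation results to evaluate")
    records: list[SuccessRecord] = []
    for result in results:
        start = result.start
        target = make_target_spec(start.properties, result.constraint)
        for smiles in result.samples:
            generated = standardize(smiles)
            ok_prop, flags = property_success(oracle(generated), target, bands)
            ok_struct = structure_success(start.molecule, generated.smiles, criterion)
            records.append(
                SuccessRecord(start.smiles, generated.smiles, ok_prop, ok_struct, flags)
            )
    n = len(records)
    if n == 0:
        return RunMetrics(0.0, 0.0, 0.0, 0, [])
    return RunMetrics(
        property_pct=100.0 * sum(r.property_success for r in records) / n,
        structure_pct=100.0 * sum(r.structure_success for r in records) / n,
        combined_pct=100.0 * sum(r.combined for r in records) / n,
        n_generated=n,
        records=records,
    )


# --------------------------------------------------------------------------
# Random baseline
# --------------------------------------------------------------------------

@dataclass
class BaselineMetrics:
    property_pct_mean: float
    property_pct_sd: float
    structure_pct: float  # always 100.0 by construction
    combined_pct_mean: float
    combined_pct_sd: float
    n_inputs: int
    short_pool_inputs: int  # inputs with fewer than n structure-satisfying molecules


def random_baseline(
    test_pairs: Sequence[MolecularPair],
    criterion: Criterion,
    bands: ErrorBands = DEFAULT_BANDS,
    oracle: PropertyOracle = synthetic_oracle,
    fraction: float = 0.01,
    repeats: int = 5,
    n: int = 10,
    seed: int = 0,
) -> BaselineMetrics:
    """Random draws from the structure-satisfying test pool.

    For a random ``fraction`` of test inputs (repeated ``repeats`` times
    with different seeds), ``n`` molecules satisfying the structure
    constraint w.r.t. the start are drawn from the unique molecules of the
    test set; property success is averaged over repeats.  Structure success
    is 100% by construction.  Inputs whose pool holds fewer than ``n``
    eligible molecules contribute what exists and are counted in
    ``short_pool_inputs``.
    """
    if not test_pairs:
        raise ValueError("empty test set")
    pool_records: dict[str, MoleculeRecord] = {}
    for pair in test_pairs:
        pool_records.setdefault(pair.source.smiles, pair.source)
        pool_records.setdefault(pair.target.smiles, pair.target)
    pool = [pool_records[s] for s in sorted(pool_records)]

    n_inputs = max(1, int(round(fraction * len(test_pairs))))
    prop_pcts, short_total = [], 0
    for rep in range(repeats):
        rng = np.random.default_rng(seed + rep)
        chosen = rng.choice(len(test_pairs), size=n_inputs, replace=False)
        hits = total = 0
        for idx in chosen:
            pair = test_pairs[int(idx)]
            start = pair.source
            target = make_target_spec(start.properties, pair.change)
            eligible = [
                rec
                for rec in pool
                if rec.smiles != start.smiles
                and pair_predicate(criterion, start, rec)
            ]
            if len(eligible) < n:
                short_total += 1
                drawn = eligible
            else:
                drawn = [eligible[int(i)] for i in rng.choice(len(eligible), size=n, replace=False)]
            for rec in drawn:
                ok, _ = property_success(oracle(rec.molecule), target, bands)
                hits += ok
                total += 1
        prop_pcts.append(100.0 * hits / total if total else 0.0)
    mean = float(np.mean(prop_pcts))
    sd = float(np.std(prop_pcts))
    return BaselineMetrics(
        property_pct_mean=mean,
        property_pct_sd=sd,
        structure_pct=100.0,
        combined_pct_mean=mean,  # structure always satisfied
        combined_pct_sd=sd,
        n_inputs=n_inputs,
        short_pool_inputs=short_total,
    )


# --------------------------------------------------------------------------
# Large-property-change slice
# --------------------------------------------------------------------------

def is_large_change(change: PropertyChange) -> bool:
    """Does the constraint ask for a big shift in any property?

    Big means: |logD change| above 1 (the requested bin lies entirely beyond
    ±1), or a solubility or clearance category flip (low->high / high->low).
    """
    lo, hi = logd_bin_bounds(change.logd_token)
    big_logd = lo >= 1.0 or hi <= -1.0
    flip = not change.solubility_token.endswith("no_change") or not (
        change.clearance_token.endswith("no_change")
    )
    return bool(big_logd or flip)


def large_change_pairs(pairs: Sequence[MolecularPair]) -> list[MolecularPair]:
    """The subset of pairs whose property change is large (see above)."""
    return [p for p in pairs if is_large_change(p.change)]


# --------------------------------------------------------------------------
# Cross-constraint heatmap and similarity distributions
# --------------------------------------------------------------------------

def cross_constraint_heatmap(
    records_by_criterion: Mapping[Criterion, Sequence[SuccessRecord]],
    columns: Sequence[Criterion] | None = None,
) -> pd.DataFrame:
    """Fraction of each row's combined successes satisfying each column's constraint.

    Row r = model trained under criterion r (its combined-successful
    generated molecules); entry (r, c) = fraction of those that also satisfy
    criterion c's structure constraint against their starting molecule.
    The diagonal is 1 by construction; empty rows give NaN.
    """
    rows = list(records_by_criterion)
    columns = list(columns) if columns is not None else rows
    matrix = np.full((len(rows), len(columns)), np.nan)
    for i, row_crit in enumerate(rows):
        successes = [r for r in records_by_criterion[row_crit] if r.combined]
        if not successes:
            continue
        for j, col_crit in enumerate(columns):
            hits = sum(
                structure_success(
                    standardize(r.start_smiles), r.generated_smiles, col_crit
                )
                for r in successes
            )
            matrix[i, j] = hits / len(successes)
    return pd.DataFrame(
        matrix,
        index=[c.value for c in rows],
        columns=[c.value for c in columns],
    )


def training_pair_heatmap(
    datasets: Mapping[Criterion, Sequence[MolecularPair]],
) -> pd.DataFrame:
    """Entry (r, c): fraction of criterion-r training pairs also satisfying c."""
    rows = list(datasets)
    matrix = np.full((len(rows), len(rows)), np.nan)
    for i, row_crit in enumerate(rows):
        pairs = list(datasets[row_crit])
        if not pairs:
            continue
        for j, col_crit in enumerate(rows):
            hits = sum(
                pair_predicate(col_crit, p.source, p.target) for p in pairs
            )
            matrix[i, j] = hits / len(pairs)
    names = [c.value for c in rows]
    return pd.DataFrame(matrix, index=names, columns=names)


def similarity_distribution(
    train_pairs: Sequence[MolecularPair],
    records: Sequence[SuccessRecord] = (),
    bins: int = 20,
    plot_path=None,
) -> pd.DataFrame:
    """Normalized Tanimoto histograms of training vs generated pairs.

    Series: training pairs; generated pairs that meet the property
    constraint, split into those also meeting the structure constraint and
    those that do not.  Each series sums to 1 (when non-empty).
    """
    edges = np.linspace(0.0, 1.0, bins + 1)
    series: dict[str, np.ndarray] = {}

    def hist(values):
        if not values:
            return np.zeros(bins)
        counts, _ = np.histogram(values, bins=edges)
        return counts / counts.sum()

    series["train"] = hist([tanimoto(p.source.molecule, p.target.molecule) for p in train_pairs])
    prop = [r for r in records if r.property_success]
    series["generated_property"] = hist(
        [tanimoto(standardize(r.start_smiles), standardize(r.generated_smiles)) for r in prop]
    )
    series["generated_property_structure"] = hist(
        [
            tanimoto(standardize(r.start_smiles), standardize(r.generated_smiles))
            for r in prop
            if r.structure_success
        ]
    )
    series["generated_property_not_structure"] = hist(
        [
            tanimoto(standardize(r.start_smiles), standardize(r.generated_smiles))
            for r in prop
            if not r.structure_success
        ]
    )
    frame = pd.DataFrame(series, index=pd.IntervalIndex.from_breaks(edges.round(3)))
    if plot_path is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(7, 4))
        centers = (edges[:-1] + edges[1:]) / 2
        for name, values in series.items():
            ax.plot(centers, values, label=name)
        ax.set_xlabel("Tanimoto similarity")
        ax.set_ylabel("fraction of pairs")
        ax.legend(fontsize=8)
        fig.tight_layout()
        fig.savefig(plot_path, dpi=120)
        plt.close(fig)
    return frame
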