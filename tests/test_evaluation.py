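"""Success bands, baselines, heatmaps and similarity distributions."""

import numpy as np
import pytest

from molopt.chem_ops import standardize
from molopt.dataset_builder import Criterion, extract_pairs
from molopt.evaluation import (
    DEFAULT_BANDS,
    SuccessRecord,
    TargetSpec,
    cross_constraint_heatmap,
    evaluate_run,
    logd_point_target,
    make_target_spec,
    property_success,
    random_baseline,
    similarity_distribution,
    structure_success,
    training_pair_heatmap,
)
from molopt.property_encoding import PropertyChange, PropertyProfile
from molopt.transformer import GenerationResult


def spec(logd=2.0, sol="high", clr="low"):
    return TargetSpec(logd, sol, clr)


class TestPropertySuccess:
    def test_logd_boundary(self):
        ok, _ = property_success(PropertyProfile(2.0, 1.5, 1.0), spec(logd=2.4))
        assert ok
        bad, flags = property_success(PropertyProfile(2.0, 1.5, 1.0), spec(logd=2.41))
        assert not bad and not flags["logd"]

    @pytest.mark.parametrize(
        "value, target, passes",
        [(1.1, "high", True), (1.09, "high", False), (2.3, "low", True), (2.31, "low", False)],
    )
    def test_solubility_band(self, value, target, passes):
        _, flags = property_success(
            PropertyProfile(2.0, value, 1.0), spec(sol=target)
        )
        assert flags["solubility"] == passes

    @pytest.mark.parametrize(
        "value, target, passes",
        [(1.65, "low", True), (1.66, "low", False), (0.95, "high", True), (0.94, "high", False)],
    )
    def test_clearance_band(self, value, target, passes):
        _, flags = property_success(
            PropertyProfile(2.0, 1.5, value), spec(clr=target)
        )
        assert flags["clearance"] == passes

    def test_overall_is_conjunction(self):
        ok, flags = property_success(PropertyProfile(2.0, 1.5, 1.0), spec())
        assert ok and all(flags.values())
        bad, flags = property_success(PropertyProfile(9.0, 1.5, 1.0), spec())
        assert not bad and flags["solubility"] and flags["clearance"]


class TestTargetSpec:
    def test_midpoint_convention(self):
        assert logd_point_target(1.0, "LogD_change_(0.1, 0.3]") == pytest.approx(1.2)
        assert logd_point_target(1.0, "LogD_change_(-0.1, 0.1]") == pytest.approx(1.0)

    def test_open_bins_use_edge_offset(self):
        assert logd_point_target(0.0, "LogD_change_(6.9, inf]") == pytest.approx(7.0)
        assert logd_point_target(0.0, "LogD_change_(-inf, -6.9]") == pytest.approx(-7.0)

    def test_categories_resolved_from_start(self):
        start = PropertyProfile(1.0, 1.0, 1.0)  # solubility low, clearance low
        change = PropertyChange(
            "LogD_change_(-0.1, 0.1]", "Solubility_low->high", "Clearance_no_change"
        )
        target = make_target_spec(start, change)
        assert target.solubility_category == "high"
        assert target.clearance_category == "low"


class TestStructureSuccess:
    def test_invalid_generated_is_false(self):
        start = standardize("CCCOc1ccccc1")
        assert not structure_success(start, "C(C", Criterion.SCAFFOLD)

    def test_identical_is_false(self):
        start = standardize("CCCOc1ccccc1")
        assert not structure_success(start, start.smiles, Criterion.SIM05)

    def test_scaffold_vs_generic(self):
        start = standardize("CCCOc1ccccc1")
        hetero = "CCCOc1ccncc1"  # same topology, pyridine ring
        assert not structure_success(start, hetero, Criterion.SCAFFOLD)
        assert structure_success(start, hetero, Criterion.SCAFFOLD_GENERIC)

    def test_band_membership(self, corpus):
        import itertools

        from molopt.chem_ops import tanimoto

        start = corpus[0].molecule
        for rec in corpus[1:40]:
            t = tanimoto(start, rec.molecule)
            if rec.smiles == start.smiles:
                continue
            assert structure_success(start, rec.smiles, Criterion.SIM05_07) == (
                0.5 <= t < 0.7
            )
            assert structure_success(start, rec.smiles, Criterion.SIM07) == (
                0.7 <= t < 1.0
            )


def _result(start_rec, change, samples):
    return GenerationResult(start=start_rec, constraint=change, samples=samples, attempts=len(samples))


class TestEvaluateRun:
    def test_perfect_run(self, corpus):
        ds = extract_pairs(corpus, Criterion.SCAFFOLD)
        pairs = ds.all_pairs()[:10]
        results = [
            _result(p.source, p.change, [p.target.smiles]) for p in pairs
        ]
        metrics = evaluate_run(results, Criterion.SCAFFOLD)
        # actual pair targets satisfy both constraints by construction
        assert metrics.property_pct == 100.0
        assert metrics.structure_pct == 100.0
        assert metrics.combined_pct == 100.0

    def test_conjunction_bound(self, corpus):
        ds = extract_pairs(corpus, Criterion.SIM05)
        pairs = ds.all_pairs()[:20]
        results = [_result(p.source, p.change, [p.target.smiles]) for p in pairs]
        metrics = evaluate_run(results, Criterion.SIM07)  # mismatched criterion
        assert metrics.combined_pct <= min(metrics.property_pct, metrics.structure_pct)

    def test_empty_results_rejected(self):
        with pytest.raises(ValueError):
            evaluate_run([], Criterion.MMP)


@pytest.fixture(scope="module")
def test_pairs(corpus):
    return extract_pairs(corpus, Criterion.SCAFFOLD_GENERIC).all_pairs()


class TestRandomBaseline:

    def test_structure_always_100(self, test_pairs):
        metrics = random_baseline(test_pairs, Criterion.SCAFFOLD_GENERIC, seed=1)
        assert metrics.structure_pct == 100.0

    def test_seeded_determinism(self, test_pairs):
        a = random_baseline(test_pairs, Criterion.SCAFFOLD_GENERIC, seed=7)
        b = random_baseline(test_pairs, Criterion.SCAFFOLD_GENERIC, seed=7)
        assert a == b

    def test_tracks_pool_base_rate(self, test_pairs):
        """Random success approximates the pool's constraint-satisfying rate."""
        from molopt.evaluation import make_target_spec, property_success
        from molopt.dataset_builder import pair_predicate
        from molopt.property_encoding import synthetic_oracle

        metrics = random_baseline(
            test_pairs, Criterion.SCAFFOLD_GENERIC, fraction=0.2, repeats=5, seed=3
        )
        pool = {}
        for p in test_pairs:
            pool.setdefault(p.source.smiles, p.source)
            pool.setdefault(p.target.smiles, p.target)
        rng = np.random.default_rng(0)
        pairs = [test_pairs[int(i)] for i in rng.choice(len(test_pairs), 40)]
        hits = total = 0
        for pair in pairs:
            target = make_target_spec(pair.source.properties, pair.change)
            for rec in pool.values():
                if rec.smiles == pair.source.smiles:
                    continue
                if not pair_predicate(Criterion.SCAFFOLD_GENERIC, pair.source, rec):
                    continue
                hits += property_success(synthetic_oracle(rec.molecule), target)[0]
                total += 1
        base_rate = 100 * hits / total
        assert metrics.property_pct_mean == pytest.approx(base_rate, abs=15)


@pytest.fixture(scope="module")
def records_by_criterion(corpus):
    out = {}
    for criterion in Criterion:
        ds = extract_pairs(corpus, criterion)
        out[criterion] = [
            SuccessRecord(p.source.smiles, p.target.smiles, True, True)
            for p in ds.all_pairs()[:25]
        ]
    return out


class TestHeatmaps:

    def test_diagonal_is_one(self, records_by_criterion):
        frame = cross_constraint_heatmap(records_by_criterion)
        for c in records_by_criterion:
            assert frame.loc[c.value, c.value] == pytest.approx(1.0)

    def test_containment_columns(self, records_by_criterion):
        frame = cross_constraint_heatmap(records_by_criterion)
        assert frame.loc[Criterion.SIM07.value, Criterion.SIM05.value] == pytest.approx(1.0)
        assert frame.loc[
            Criterion.SCAFFOLD.value, Criterion.SCAFFOLD_GENERIC.value
        ] == pytest.approx(1.0)

    def test_entries_are_fractions(self, records_by_criterion):
        frame = cross_constraint_heatmap(records_by_criterion)
        values = frame.values[~np.isnan(frame.values)]
        assert ((0.0 <= values) & (values <= 1.0)).all()

    def test_training_heatmap_matches_pattern(self, corpus):
        datasets = {c: extract_pairs(corpus, c).all_pairs()[:40] for c in Criterion}
        frame = training_pair_heatmap(datasets)
        assert frame.loc[Criterion.SIM07.value, Criterion.SIM05.value] == pytest.approx(1.0)
        assert frame.loc[
            Criterion.SCAFFOLD.value, Criterion.SCAFFOLD_GENERIC.value
        ] == pytest.approx(1.0)
        assert frame.loc[Criterion.SIM05_07.value, Criterion.SIM07.value] == pytest.approx(0.0)


class TestSimilarityDistribution:
    def test_train_mass_respects_band(self, corpus):
        from molopt.chem_ops import tanimoto

        ds = extract_pairs(corpus, Criterion.SIM07)
        assert min(
            tanimoto(p.source.molecule, p.target.molecule) for p in ds.all_pairs()
        ) >= 0.7
        frame = similarity_distribution(ds.all_pairs())
        # bins lying entirely below the 0.7 training cutoff carry no mass
        below = frame.loc[[iv for iv in frame.index if iv.right <= 0.7 - 1e-9], "train"]
        assert below.sum() == pytest.approx(0.0)

    def test_series_normalized(self, corpus, tmp_path):
        ds = extract_pairs(corpus, Criterion.SCAFFOLD)
        records = [
            SuccessRecord(p.source.smiles, p.target.smiles, True, i % 2 == 0)
            for i, p in enumerate(ds.all_pairs()[:20])
        ]
        plot = tmp_path / "sim.png"
        frame = similarity_distribution(ds.all_pairs()[:50], records, plot_path=plot)
        for name, series in frame.items():
            if series.sum() > 0:
                assert series.sum() == pytest.approx(1.0)
        assert plot.exists()


class TestLargeChangeSlice:
    def test_flip_or_big_logd_selected(self):
        from molopt.evaluation import is_large_change

        big = PropertyChange(
            "LogD_change_(1.1, 1.3]", "Solubility_no_change", "Clearance_no_change"
        )
        flip = PropertyChange(
            "LogD_change_(-0.1, 0.1]", "Solubility_low->high", "Clearance_no_change"
        )
        small = PropertyChange(
            "LogD_change_(0.9, 1.1]", "Solubility_no_change", "Clearance_no_change"
        )
        assert is_large_change(big)
        assert is_large_change(flip)
        assert not is_large_change(small)  # bin straddles 1: not entirely beyond

    def test_slice_is_minority_of_windowed_corpus(self, corpus):
        from molopt.evaluation import large_change_pairs

        pairs = extract_pairs(corpus, Criterion.SCAFFOLD).all_pairs()
        slice_ = large_change_pairs(pairs)
        assert 0 < len(slice_) < len(pairs)
        for p in slice_:
            from molopt.evaluation import is_large_change

            assert is_large_change(p.change)
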