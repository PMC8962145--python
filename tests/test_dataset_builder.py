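"""Corpus filters, MMP semantics, pair predicates and pair extraction."""

import itertools

import pytest

from molopt.chem_ops import standardize, tanimoto
from molopt.dataset_builder import (
    Criterion,
    MoleculeRecord,
    extract_pairs,
    filter_molecules,
    filter_publications,
    is_mmp,
    pair_predicate,
    prepare_corpus,
    read_pairs,
    write_pairs,
)
from molopt.property_encoding import PropertyProfile, synthetic_oracle


def _record(smiles, pub="P1", year=2005, props=None):
    mol = standardize(smiles)
    return MoleculeRecord(mol, pub, year, props or synthetic_oracle(mol))


class TestFilterMolecules:
    def test_size_and_ring_rules(self):
        records = [
            _record("CCOc1ccccc1"),  # 9 heavy atoms -> removed
            _record("CCCOc1ccccc1"),  # 10 heavy atoms -> kept
            _record("CCCCCCCCCCCC"),  # acyclic -> removed
            _record("CCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCc1ccccc1"),  # 51 -> removed
        ]
        kept = filter_molecules(records)
        assert [r.smiles for r in kept] == [records[1].smiles]

    def test_property_outlier_removed(self):
        base = [
            _record("CCCOc1ccccc1", props=PropertyProfile(1.0 + 0.01 * i, 1.5, 1.0))
            for i in range(20)
        ]
        outlier = _record("CCCCOc1ccccc1", props=PropertyProfile(25.0, 1.5, 1.0))
        kept = filter_molecules(base + [outlier])
        assert outlier.smiles not in {r.smiles for r in kept}
        assert len(kept) == 20

    def test_extra_filter_hook(self):
        records = [_record("CCCOc1ccccc1"), _record("CCCNc1ccccc1")]
        kept = filter_molecules(records, extra_filters=[lambda r: "N" not in r.smiles])
        assert [r.smiles for r in kept] == [records[0].smiles]

    def test_empty_input(self):
        assert filter_molecules([]) == []


class TestFilterPublications:
    @staticmethod
    def _pub(pub, year, n):
        return [_record(f"{'C' * (i + 3)}Oc1ccccc1", pub, year) for i in range(n)]

    def test_year_and_size_rules(self):
        records = (
            self._pub("OLD", 1999, 12)  # pre-2000 -> removed
            + self._pub("BIG", 2005, 61)  # 61 molecules -> removed
            + self._pub("OK", 2000, 10)  # boundary: kept
        )
        kept = filter_publications(records)
        assert {r.publication_id for r in kept} == {"OK"}
        assert len(kept) == 10


class TestIsMMP:
    def test_methyl_analog_accepted(self):
        a = standardize("CCCCc1ccccc1C")
        b = standardize("CCCCc1ccccc1CC")  # methyl -> ethyl at one position
        assert is_mmp(a, b)

    def test_hydrogen_replacement_accepted(self):
        assert is_mmp(standardize("CCCCCCc1ccccc1"), standardize("CCCCCCc1ccccc1C"))

    def test_two_site_change_rejected(self):
        # simultaneous edits at two disconnected positions: no single shared cut
        assert not is_mmp(standardize("Cc1cc(F)ccc1CCN"), standardize("CCc1cc(Cl)ccc1CCN"))

    def test_identical_rejected(self):
        m = standardize("CCOc1ccccc1")
        assert not is_mmp(m, m)

    def test_rgroup_ratio_boundary(self):
        # differing R-groups have 3 heavy atoms; 3/9 = 0.333 > 0.33 rejected,
        # 3/10 = 0.30 accepted once a methyl pads the molecules
        assert not is_mmp(standardize("c1ccccc1OCC"), standardize("c1ccccc1NCC"))
        assert is_mmp(standardize("Cc1ccccc1OCC"), standardize("Cc1ccccc1NCC"))

    def test_symmetric(self):
        a, b = standardize("CCCCc1ccccc1C"), standardize("CCCCc1ccccc1CC")
        assert is_mmp(a, b) == is_mmp(b, a)


class TestPairPredicate:
    def test_sim_band_semantics(self, corpus):
        # find pairs spanning the similarity range and check band membership
        found_any = False
        for a, b in itertools.combinations(corpus[:40], 2):
            t = tanimoto(a.molecule, b.molecule)
            assert pair_predicate(Criterion.SIM05, a, b) == (t >= 0.5 and a.smiles != b.smiles)
            assert pair_predicate(Criterion.SIM05_07, a, b) == (0.5 <= t < 0.7 and a.smiles != b.smiles)
            assert pair_predicate(Criterion.SIM07, a, b) == (t >= 0.7 and a.smiles != b.smiles)
            found_any = True
        assert found_any

    def test_scaffold_equality(self):
        a = _record("CCCOc1ccccc1")
        b = _record("CCCCOc1ccccc1")
        c = _record("CCCOc1ccncc1")  # pyridine: different scaffold, same generic
        assert pair_predicate(Criterion.SCAFFOLD, a, b)
        assert not pair_predicate(Criterion.SCAFFOLD, a, c)
        assert pair_predicate(Criterion.SCAFFOLD_GENERIC, a, c)

    def test_unknown_criterion(self):
        a, b = _record("CCCOc1ccccc1"), _record("CCCCOc1ccccc1")
        with pytest.raises(ValueError):
            pair_predicate("nonsense", a, b)


def brute_force_pairs(corpus, criterion):
    """Independent oracle: naive all-pairs filter, no dedup shortcuts."""
    best = {}
    for a, b in itertools.combinations(corpus, 2):
        if a.publication_id != b.publication_id or a.smiles == b.smiles:
            continue
        if not pair_predicate(criterion, a, b):
            continue
        key = frozenset((a.smiles, b.smiles))
        year = min(a.year, b.year)
        if key not in best or year < best[key]:
            best[key] = year
    return best


class TestExtractPairs:
    def test_three_molecule_publication_gives_six_directed_pairs(self):
        records = [
            _record("CCCOc1ccccc1", "P", 2005),
            _record("CCCCOc1ccccc1", "P", 2005),
            _record("CCCCCOc1ccccc1", "P", 2005),
        ]
        ds = extract_pairs(records, Criterion.SCAFFOLD)
        assert len(ds.train) == 6
        directed = {(p.source.smiles, p.target.smiles) for p in ds.train}
        assert len(directed) == 6

    def test_earliest_year_dedup(self):
        early = [_record("CCCOc1ccccc1", "A", 2005), _record("CCCCOc1ccccc1", "A", 2005)]
        late = [_record("CCCOc1ccccc1", "B", 2012), _record("CCCCOc1ccccc1", "B", 2012)]
        ds = extract_pairs(early + late, Criterion.SCAFFOLD)
        assert len(ds.all_pairs()) == 2  # one structure pair, kept once + reverse
        assert all(p.year == 2005 for p in ds.all_pairs())

    def test_matches_brute_force_oracle(self, corpus):
        small = corpus[:30]
        for criterion in Criterion:
            ds = extract_pairs(small, criterion)
            mined = {
                frozenset((p.source.smiles, p.target.smiles)) for p in ds.all_pairs()
            }
            oracle = brute_force_pairs(small, criterion)
            assert mined == set(oracle)
            years = {
                frozenset((p.source.smiles, p.target.smiles)): p.year
                for p in ds.all_pairs()
            }
            for key, year in oracle.items():
                assert years[key] == year

    def test_every_pair_satisfies_its_predicate(self, corpus):
        for criterion in Criterion:
            ds = extract_pairs(corpus[:60], criterion)
            for pair in ds.all_pairs():
                assert pair_predicate(criterion, pair.source, pair.target)


@pytest.fixture(scope="module")
def datasets(corpus):
    return {c: extract_pairs(corpus, c) for c in Criterion}


class TestDatasetInvariants:

    def test_reverse_closure_with_inverted_tokens(self, datasets):
        for ds in datasets.values():
            for split in ("train", "valid", "test"):
                pairs = {
                    (p.source.smiles, p.target.smiles): p.change for p in ds.split(split)
                }
                for (src, tgt), change in pairs.items():
                    assert pairs[(tgt, src)] == change.invert()

    def test_year_split_partition(self, datasets):
        for ds in datasets.values():
            for pair in ds.train:
                assert 2000 <= pair.year <= 2017
            for pair in ds.valid:
                assert pair.year == 2018
            for pair in ds.test:
                assert 2019 <= pair.year <= 2020
            keys = [
                (p.source.smiles, p.target.smiles)
                for split in ("train", "valid", "test")
                for p in ds.split(split)
            ]
            assert len(keys) == len(set(keys))  # splits disjoint

    def test_criterion_containment(self, datasets):
        def key_set(ds):
            return {(p.source.smiles, p.target.smiles) for p in ds.all_pairs()}

        sim05, sim0507, sim07 = (
            key_set(datasets[Criterion.SIM05]),
            key_set(datasets[Criterion.SIM05_07]),
            key_set(datasets[Criterion.SIM07]),
        )
        assert sim07 <= sim05
        assert sim0507 <= sim05
        assert not (sim0507 & sim07)
        assert sim0507 | sim07 == sim05
        assert key_set(datasets[Criterion.SCAFFOLD]) <= key_set(
            datasets[Criterion.SCAFFOLD_GENERIC]
        )


class TestPairIO:
    def test_round_trip(self, corpus, tmp_path):
        ds = extract_pairs(corpus[:40], Criterion.SCAFFOLD)
        path = tmp_path / "pairs.tsv"
        write_pairs(ds, path)
        loaded = read_pairs(path)
        assert loaded.criterion == ds.criterion
        assert loaded.sizes() == ds.sizes()
        for split in ("train", "valid", "test"):
            got = [
                (p.source.smiles, p.target.smiles, p.change, p.year)
                for p in loaded.split(split)
            ]
            want = [
                (p.source.smiles, p.target.smiles, p.change, p.year)
                for p in ds.split(split)
            ]
            assert got == want
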