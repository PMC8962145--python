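"""Corpus filtering and molecular-pair mining under six pairing criteria.

Pairs (X, Y, Z) are mined from molecules that share a publication, on the
assumption that same-publication molecules come from the same optimization
project.  Six pairing criteria are supported:

* ``MMP`` — matched molecular pair: the two molecules differ by a single
  transformation (one acyclic single-bond cut in each molecule yields an
  identical constant core with different R-groups), with the R-group
  heavy-atom count at most 0.33 of its molecule's heavy-atom count on both
  sides;
* ``Sim>=0.5`` / ``Sim[0.5,0.7)`` / ``Sim>=0.7`` — Tanimoto (ECFP4) bands;
* ``Scaffold`` / ``ScaffoldGeneric`` — equal Murcko scaffold / equal
  all-carbon single-bond generic scaffold.

Mined unordered pairs are deduplicated keeping the earliest reported year,
expanded with their reverse pair (Y, X, invert(Z)), and split by publication
year into train (2000-2017), validation (2018) and test (2019-2020).
"""

from __future__ import annotations

import enum
from collections import defaultdict
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import Callable, Iterable, Sequence

import pandas as pd
from rdkit import Chem

from .chem_ops import CanonicalMolecule, generic_scaffold, murcko_scaffold, standardize, tanimoto
from .property_encoding import (
    PropertyChange,
    PropertyOracle,
    PropertyProfile,
    property_change,
    synthetic_oracle,
)

MIN_HEAVY_ATOMS = 10
MAX_HEAVY_ATOMS = 50
PROPERTY_SD_LIMIT = 3.0
MIN_PUBLICATION_SIZE = 10
MAX_PUBLICATION_SIZE = 60
MIN_YEAR = 2000
MAX_YEAR = 2020
TRAIN_YEARS = (2000, 2017)
VALID_YEAR = 2018
TEST_YEARS = (2019, 2020)

MMP_MAX_RGROUP_RATIO = 0.33


class Criterion(str, enum.Enum):
    """The six pair-mining criteria."""

    MMP = "mmp"
    SIM05 = "sim05"  # Tanimoto >= 0.5
    SIM05_07 = "sim0507"  # Tanimoto in [0.5, 0.7)
    SIM07 = "sim07"  # Tanimoto >= 0.7
    SCAFFOLD = "scaffold"
    SCAFFOLD_GENERIC = "scaffold-generic"


@dataclass(frozen=True)
class MoleculeRecord:
    """A standardized molecule with provenance and property profile."""

    molecule: CanonicalMolecule
    publication_id: str
    year: int
    properties: PropertyProfile

    @property
    def smiles(self) -> str:
        return self.molecule.smiles


@dataclass(frozen=True)
class MolecularPair:
    """Ordered (source X, target Y) pair with property change Z."""

    source: MoleculeRecord
    target: MoleculeRecord
    change: PropertyChange
    criterion: Criterion
    year: int


@dataclass
class PairDataset:
    """Train/validation/test pair collections mined under one criterion."""

    criterion: Criterion
    train: list[MolecularPair] = field(default_factory=list)
    valid: list[MolecularPair] = field(default_factory=list)
    test: list[MolecularPair] = field(default_factory=list)

    def all_pairs(self) -> list[MolecularPair]:
        return self.train + self.valid + self.test

    def split(self, name: str) -> list[MolecularPair]:
        return getattr(self, name)

    def sizes(self) -> dict[str, int]:
        return {"train": len(self.train), "valid": len(self.valid), "test": len(self.test)}


# --------------------------------------------------------------------------
# Molecule / publication filters
# --------------------------------------------------------------------------

def filter_molecules(
    records: Sequence[MoleculeRecord],
    extra_filters: Iterable[Callable[[MoleculeRecord], bool]] = (),
) -> list[MoleculeRecord]:
    """Keep drug-sized ring-containing molecules with non-outlier properties.

    Filters: 10 <= heavy atoms <= 50; at least one ring; each property within
    3 standard deviations of the corpus mean for that property; all
    ``extra_filters`` predicates pass (hook point for external quality /
    substructure severity filters).
    """
    records = list(records)
    if not records:
        return []
    frame = pd.DataFrame(
        {
            "logd": [r.properties.logd for r in records],
            "solubility": [r.properties.solubility for r in records],
            "clearance": [r.properties.clearance for r in records],
        }
    )
    mean, sd = frame.mean(), frame.std(ddof=0)
    lo = mean - PROPERTY_SD_LIMIT * sd
    hi = mean + PROPERTY_SD_LIMIT * sd
    kept = []
    for i, rec in enumerate(records):
        mol = rec.molecule
        if not (MIN_HEAVY_ATOMS <= mol.heavy_atom_count <= MAX_HEAVY_ATOMS):
            continue
        if mol.ring_count == 0:
            continue
        row = frame.iloc[i]
        if not ((lo <= row) & (row <= hi)).all():
            continue
        if not all(pred(rec) for pred in extra_filters):
            continue
        kept.append(rec)
    return kept


def filter_publications(records: Sequence[MoleculeRecord]) -> list[MoleculeRecord]:
    """Keep records from publications with year >= 2000 and 10-60 molecules."""
    by_pub: dict[str, list[MoleculeRecord]] = defaultdict(list)
    for rec in records:
        by_pub[rec.publication_id].append(rec)
    kept = []
    for pub_records in by_pub.values():
        if any(rec.year < MIN_YEAR for rec in pub_records):
            continue
        if not (MIN_PUBLICATION_SIZE <= len(pub_records) <= MAX_PUBLICATION_SIZE):
            continue
        kept.extend(pub_records)
    return kept


def prepare_corpus(
    records: Sequence[MoleculeRecord],
    extra_filters: Iterable[Callable[[MoleculeRecord], bool]] = (),
) -> list[MoleculeRecord]:
    """Molecule filter followed by publication filter."""
    return filter_publications(filter_molecules(records, extra_filters))


# --------------------------------------------------------------------------
# Matched-molecular-pair test (single-cut fragment indexing)
# --------------------------------------------------------------------------

def _dummy_to_h_smiles(frag: Chem.Mol) -> str:
    """Canonical SMILES of a one-dummy fragment with the dummy replaced by H."""
    em = Chem.RWMol(frag)
    for atom in em.GetAtoms():
        if atom.GetAtomicNum() == 0:
            atom.SetAtomicNum(1)
    mol = em.GetMol()
    Chem.SanitizeMol(mol)
    return Chem.MolToSmiles(Chem.RemoveHs(mol))


@lru_cache(maxsize=100_000)
def _fragment_index(smiles: str) -> tuple[frozenset, frozenset]:
    """Single-cut fragment index of a molecule.

    Returns ``(cores, cores_as_h)`` where ``cores`` holds the canonical
    SMILES of every constant part obtainable by cutting one acyclic single
    bond, restricted to cuts whose variable part (R-group) has at most
    ``MMP_MAX_RGROUP_RATIO`` of the molecule's heavy atoms, and
    ``cores_as_h`` holds those cores with the attachment point capped by a
    hydrogen (for hydrogen <-> R-group transformations).
    """
    mol = Chem.MolFromSmiles(smiles)
    n_heavy = mol.GetNumHeavyAtoms()
    cores: set[str] = set()
    cores_as_h: set[str] = set()
    for bond in mol.GetBonds():
        if bond.GetBondType() != Chem.BondType.SINGLE or bond.IsInRing():
            continue
        fragmented = Chem.FragmentOnBonds(
            mol, [bond.GetIdx()], addDummies=True, dummyLabels=[(0, 0)]
        )
        frags = Chem.GetMolFrags(fragmented, asMols=True, sanitizeFrags=True)
        if len(frags) != 2:
            continue
        for core, rgroup in (frags, frags[::-1]):
            r_heavy = sum(1 for a in rgroup.GetAtoms() if a.GetAtomicNum() > 1)
            if r_heavy / n_heavy > MMP_MAX_RGROUP_RATIO:
                continue
            core_smiles = Chem.MolToSmiles(core)
            cores.add(core_smiles)
            if core_smiles not in cores_as_h:
                cores_as_h.add(_dummy_to_h_smiles(core))
    return frozenset(cores), frozenset(cores_as_h)


def is_mmp(a: MoleculeRecord | CanonicalMolecule, b: MoleculeRecord | CanonicalMolecule) -> bool:
    """True iff the two molecules form a single-cut matched molecular pair.

    Accepts when one acyclic single-bond cut in each molecule produces an
    identical constant core with differing R-groups (a hydrogen counts as an
    R-group of zero heavy atoms), and the R-group/molecule heavy-atom ratio
    is at most 0.33 on both sides.
    """
    mol_a = a.molecule if isinstance(a, MoleculeRecord) else a
    mol_b = b.molecule if isinstance(b, MoleculeRecord) else b
    if mol_a.smiles == mol_b.smiles:
        return False
    cores_a, h_a = _fragment_index(mol_a.smiles)
    cores_b, h_b = _fragment_index(mol_b.smiles)
    if cores_a & cores_b:
        return True
    # hydrogen -> R-group transformations: one molecule equals the other's
    # capped core; the hydrogen side has R-ratio 0, always admissible
    return mol_b.smiles in h_a or mol_a.smiles in h_b


# --------------------------------------------------------------------------
# Pair predicate and extraction
# --------------------------------------------------------------------------

def pair_predicate(criterion: Criterion, a: MoleculeRecord, b: MoleculeRecord) -> bool:
    """Does the (a, b) molecule pair satisfy ``criterion``?"""
    mol_a, mol_b = a.molecule, b.molecule
    if mol_a.smiles == mol_b.smiles:
        return False
    if criterion == Criterion.MMP:
        return is_mmp(a, b)
    if criterion in (Criterion.SIM05, Criterion.SIM05_07, Criterion.SIM07):
        t = tanimoto(mol_a, mol_b)
        if criterion == Criterion.SIM05:
            return t >= 0.5
        if criterion == Criterion.SIM05_07:
            return 0.5 <= t < 0.7
        return t >= 0.7
    if criterion == Criterion.SCAFFOLD:
        return murcko_scaffold(mol_a) == murcko_scaffold(mol_b)
    if criterion == Criterion.SCAFFOLD_GENERIC:
        return generic_scaffold(mol_a) == generic_scaffold(mol_b)
    raise ValueError(f"unknown criterion: {criterion!r}")


def _split_name(year: int) -> str | None:
    if TRAIN_YEARS[0] <= year <= TRAIN_YEARS[1]:
        return "train"
    if year == VALID_YEAR:
        return "valid"
    if TEST_YEARS[0] <= year <= TEST_YEARS[1]:
        return "test"
    return None


def extract_pairs(corpus: Sequence[MoleculeRecord], criterion: Criterion) -> PairDataset:
    """Mine, deduplicate, reverse-expand and year-split pairs from a corpus.

    All unordered same-publication molecule pairs are tested against the
    criterion predicate.  Duplicated structure pairs (same two canonical
    SMILES) are kept once with the earliest reporting year (ties broken by
    lexicographic publication id).  Each retained pair contributes both
    directions, (X, Y, Z) and (Y, X, invert(Z)), to the split its year
    falls in.
    """
    by_pub: dict[str, list[MoleculeRecord]] = defaultdict(list)
    for rec in corpus:
        by_pub[rec.publication_id].append(rec)

    # unordered smiles pair -> (year, publication_id, record_x, record_y)
    best: dict[tuple[str, str], tuple[int, str, MoleculeRecord, MoleculeRecord]] = {}
    for pub_id in sorted(by_pub):
        records = sorted(by_pub[pub_id], key=lambda r: r.smiles)
        year = records[0].year
        for i in range(len(records)):
            for j in range(i + 1, len(records)):
                a, b = records[i], records[j]
                if a.smiles == b.smiles:
                    continue
                if not pair_predicate(criterion, a, b):
                    continue
                key = (a.smiles, b.smiles)
                cand = (year, pub_id, a, b)
                prev = best.get(key)
                if prev is None or cand[:2] < prev[:2]:
                    best[key] = cand

    dataset = PairDataset(criterion=criterion)
    for key in sorted(best):
        year, _pub, rec_x, rec_y = best[key]
        split = _split_name(year)
        if split is None:
            continue
        change = property_change(rec_x.properties, rec_y.properties)
        forward = MolecularPair(rec_x, rec_y, change, criterion, year)
        reverse = MolecularPair(rec_y, rec_x, change.invert(), criterion, year)
        dataset.split(split).extend((forward, reverse))
    return dataset


# --------------------------------------------------------------------------
# Corpus / pair-table I/O
# --------------------------------------------------------------------------

def read_corpus(
    path: str | Path,
    oracle: PropertyOracle = synthetic_oracle,
) -> list[MoleculeRecord]:
    """Read a corpus CSV/TSV (smiles, publication_id, year [, properties]).

    Molecules are standardized on read.  If the table carries ``logd``,
    ``solubility_log10`` and ``clearance_log10`` columns they are used as
    the property profile; otherwise ``oracle`` supplies it.
    """
    path = Path(path)
    sep = "\t" if path.suffix in (".tsv", ".tab") else ","
    frame = pd.read_csv(path, sep=sep)
    has_props = {"logd", "solubility_log10", "clearance_log10"}.issubset(frame.columns)
    records = []
    for row in frame.itertuples(index=False):
        molecule = standardize(row.smiles)
        if has_props:
            profile = PropertyProfile(
                float(row.logd), float(row.solubility_log10), float(row.clearance_log10)
            )
        else:
            profile = oracle(molecule)
        records.append(
            MoleculeRecord(molecule, str(row.publication_id), int(row.year), profile)
        )
    return records


PAIR_COLUMNS = [
    "source_smiles",
    "target_smiles",
    "logd_change_token",
    "solubility_token",
    "clearance_token",
    "criterion",
    "year",
    "split",
]


def pairs_to_frame(dataset: PairDataset) -> pd.DataFrame:
    rows = []
    for split in ("train", "valid", "test"):
        for pair in dataset.split(split):
            rows.append(
                {
                    "source_smiles": pair.source.smiles,
                    "target_smiles": pair.target.smiles,
                    "logd_change_token": pair.change.logd_token,
                    "solubility_token": pair.change.solubility_token,
                    "clearance_token": pair.change.clearance_token,
                    "criterion": dataset.criterion.value,
                    "year": pair.year,
                    "split": split,
                }
            )
    return pd.DataFrame(rows, columns=PAIR_COLUMNS)


def write_pairs(dataset: PairDataset, path: str | Path) -> None:
    pairs_to_frame(dataset).to_csv(path, sep="\t", index=False)


def read_pairs(path: str | Path, oracle: PropertyOracle = synthetic_oracle) -> PairDataset:
    """Load a pair TSV written by :func:`write_pairs`.

    Molecule property profiles are re-derived from ``oracle``; the change
    tokens are taken from the file verbatim.
    """
    frame = pd.read_csv(path, sep="\t")
    criterion = Criterion(frame["criterion"].iloc[0])
    dataset = PairDataset(criterion=criterion)
    mol_cache: dict[str, MoleculeRecord] = {}

    def record(smiles: str, year: int) -> MoleculeRecord:
        if smiles not in mol_cache:
            molecule = standardize(smiles)
            mol_cache[smiles] = MoleculeRecord(molecule, "", year, oracle(molecule))
        return mol_cache[smiles]

    for row in frame.itertuples(index=False):
        pair = MolecularPair(
            source=record(row.source_smiles, int(row.year)),
            target=record(row.target_smiles, int(row.year)),
            change=PropertyChange(
                row.logd_change_token, row.solubility_token, row.clearance_token
            ),
            criterion=criterion,
            year=int(row.year),
        )
        dataset.split(row.split).append(pair)
    return dataset
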