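"""Synthetic publication-structured corpora with a learnable structure/property grammar.

The generator emulates the shape of a literature-derived optimization corpus
without any external data: each *family* is a pair of scaffold templates
(a parent ring system and a heteroatom-swapped sibling that shares its
generic scaffold), decorated at two marked positions with substituents from
a small alphabet.  A *publication* draws 10+ molecules from one family,
restricted to a contiguous window of the family's pseudo-logD range — the
molecules of one publication behave like one optimization project working
in a local region of property space, which is the reason same-publication
pairs are mined in the first place.

Because the whole library per family is enumerable (two positions, a dozen
substituents), the exact set of targets reachable from any starting molecule
under a requested property change can be computed exhaustively
(:func:`grammar_truth`), giving an oracle benchmark for the generative model.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .chem_ops import CanonicalMolecule, standardize
from .dataset_builder import MoleculeRecord
from .property_encoding import (
    PropertyChange,
    PropertyOracle,
    property_change,
    synthetic_oracle,
)

#: Scaffold-template families.  Each family is (parent, heteroatom-swapped
#: sibling); the two share a generic scaffold but not a Murcko scaffold.
#: ``{r0}`` / ``{r1}`` mark the substituent positions.
DEFAULT_TEMPLATE_FAMILIES: tuple[tuple[str, ...], ...] = (
    (
        "O=C(c1cc{r0}cc{r1}c1)Nc1cc{r2}ccc1",
        "O=C(c1cc{r0}cc{r1}c1)Nc1cc{r2}ccn1",
    ),
    (
        "c1cc{r0}cc{r1}c1Cc1cc{r2}ccc1",
        "c1cc{r0}cc{r1}c1Cc1cc{r2}cnc1",
    ),
    (
        "c1cc{r0}cc{r1}c1-c1cc{r2}ccc1O",
        "c1cc{r0}cc{r1}c1-c1cc{r2}cc(O)n1",
    ),
)

#: Substituent alphabet (SMILES fragments; "" is hydrogen).  Spread over
#: lipophilic (C, CC, F, Cl) and polar (O, OC, N, C#N) groups so oracle
#: properties cover both sides of the solubility/clearance thresholds and
#: single edits move logD by one to a few encoder bins.
DEFAULT_SUBSTITUENTS: tuple[str, ...] = ("", "C", "CC", "F", "Cl", "O", "OC", "N", "C#N")


class FixtureError(ValueError):
    pass


@dataclass(frozen=True)
class FixtureConfig:
    """Corpus-generator settings; ``seed`` fixes all randomness."""

    n_publications: int = 20
    min_publication_size: int = 10
    max_publication_size: int = 14
    #: fraction of publications drawing from the whole family rather than a
    #: local property window (projects exploring broadly vs optimizing
    #: locally); kept small so pairs with large property changes stay a
    #: minority, as in literature-derived pair corpora
    broad_publication_fraction: float = 0.1
    #: pseudo-logD span of a windowed publication: molecules of one project
    #: sit within this property range of each other
    publication_logd_span: float = 0.8
    template_families: tuple[tuple[str, ...], ...] = DEFAULT_TEMPLATE_FAMILIES
    substituents: tuple[str, ...] = DEFAULT_SUBSTITUENTS
    year_range: tuple[int, int] = (2000, 2020)
    seed: int = 0


def _fill(template: str, subs: Sequence[str]) -> str:
    values = {f"r{i}": f"({s})" if s else "" for i, s in enumerate(subs)}
    return template.format(**values)


def _n_positions(template: str) -> int:
    n = 0
    while f"{{r{n}}}" in template:
        n += 1
    if n == 0:
        raise FixtureError(f"template has no substituent positions: {template!r}")
    return n


@dataclass
class FixtureLibrary:
    """Exhaustive enumeration of every molecule the templates can produce."""

    config: FixtureConfig
    #: per family: list of (canonical molecule, template index within family)
    families: list[list[CanonicalMolecule]] = field(default_factory=list)
    #: canonical SMILES -> family index
    family_of: dict[str, int] = field(default_factory=dict)
    #: canonical SMILES -> template index within its family
    template_of: dict[str, int] = field(default_factory=dict)

    @classmethod
    def build(cls, config: FixtureConfig) -> "FixtureLibrary":
        lib = cls(config=config)
        for fam_idx, family in enumerate(config.template_families):
            members: list[CanonicalMolecule] = []
            seen: set[str] = set()
            for tpl_idx, template in enumerate(family):
                n_pos = _n_positions(template)
                for combo in itertools.product(config.substituents, repeat=n_pos):
                    mol = standardize(_fill(template, combo))
                    if mol.smiles in seen:
                        continue
                    seen.add(mol.smiles)
                    members.append(mol)
                    lib.family_of[mol.smiles] = fam_idx
                    lib.template_of[mol.smiles] = tpl_idx
            lib.families.append(members)
        return lib

    def family_members(self, smiles: str) -> list[CanonicalMolecule]:
        try:
            return self.families[self.family_of[smiles]]
        except KeyError:
            raise FixtureError(f"molecule is not from a known template: {smiles}") from None


def generate_corpus(
    config: FixtureConfig,
    oracle: PropertyOracle = synthetic_oracle,
) -> tuple[list[MoleculeRecord], FixtureLibrary]:
    """Generate a publication-structured corpus; deterministic under seed.

    Each publication samples one family, uses either the parent template or
    both templates (so generic-scaffold-only pairs occur), and draws its
    molecules from a contiguous window of the chosen pool's pseudo-logD
    ordering.  Years are uniform over ``config.year_range`` so all three
    year splits are populated.
    """
    rng = np.random.default_rng(config.seed)
    library = FixtureLibrary.build(config)
    records: list[MoleculeRecord] = []
    for pub_idx in range(config.n_publications):
        fam_idx = int(rng.integers(len(library.families)))
        members = library.families[fam_idx]
        if len(library.config.template_families[fam_idx]) > 1 and rng.random() < 0.5:
            pool = members  # both templates: hetero-swapped generic pairs occur
        else:
            pool = [m for m in members if library.template_of[m.smiles] == 0]
        pool = sorted(pool, key=lambda m: (oracle(m).logd, m.smiles))
        size = int(
            rng.integers(config.min_publication_size, config.max_publication_size + 1)
        )
        size = min(size, len(pool))
        logd = [oracle(m).logd for m in pool]
        if rng.random() < config.broad_publication_fraction:
            lo_idx, hi_idx = 0, len(pool)  # property-broad project
        else:
            lo_idx = int(rng.integers(0, len(pool)))
            hi_idx = lo_idx
            while hi_idx < len(pool) and logd[hi_idx] <= logd[lo_idx] + config.publication_logd_span:
                hi_idx += 1
            while hi_idx - lo_idx < size and lo_idx > 0:
                lo_idx -= 1  # short windows extend backwards
        window = pool[lo_idx:hi_idx]
        chosen = rng.choice(len(window), size=min(size, len(window)), replace=False)
        year = int(rng.integers(config.year_range[0], config.year_range[1] + 1))
        pub_id = f"PUB{pub_idx:04d}"
        for offset in sorted(int(c) for c in chosen):
            mol = window[offset]
            records.append(MoleculeRecord(mol, pub_id, year, oracle(mol)))
    return records, library


def grammar_truth(
    library: FixtureLibrary,
    start: CanonicalMolecule | str,
    change: PropertyChange,
    oracle: PropertyOracle = synthetic_oracle,
) -> set[str]:
    """All template-library molecules reachable from ``start`` under ``change``.

    Exhaustively enumerates the start molecule's family and keeps every
    member (other than the start itself) whose oracle property deltas encode
    to exactly the requested change tokens.  This is the ground truth the
    trained model's conditional generation is benchmarked against.
    """
    smiles = start if isinstance(start, str) else start.smiles
    src_profile = oracle(_as_mol(library, smiles))
    targets = set()
    for member in library.family_members(smiles):
        if member.smiles == smiles:
            continue
        if property_change(src_profile, oracle(member)) == change:
            targets.add(member.smiles)
    return targets


def _as_mol(library: FixtureLibrary, smiles: str) -> CanonicalMolecule:
    fam = library.family_of.get(smiles)
    if fam is None:
        raise FixtureError(f"molecule is not from a known template: {smiles}")
    for member in library.families[fam]:
        if member.smiles == smiles:
            return member
    raise FixtureError(f"molecule missing from its family: {smiles}")


def corpus_to_frame(records: Sequence[MoleculeRecord]):
    """Corpus as a DataFrame with the on-disk CSV schema."""
    import pandas as pd

    return pd.DataFrame(
        {
            "smiles": [r.smiles for r in records],
            "publication_id": [r.publication_id for r in records],
            "year": [r.year for r in records],
            "logd": [r.properties.logd for r in records],
            "solubility_log10": [r.properties.solubility for r in records],
            "clearance_log10": [r.properties.clearance for r in records],
        }
    )
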