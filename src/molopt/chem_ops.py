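"""Molecular structure primitives: standardization, fingerprints, scaffolds.

Every molecule entering the pair-mining / generation pipeline passes through
:func:`standardize` first, so downstream code can rely on canonical SMILES
equality as molecule identity.  Similarity is Tanimoto over hashed circular
(Morgan radius-2, ECFP4-like) fingerprints; scaffolds are Bemis–Murcko ring
systems plus linkers, optionally collapsed to an all-carbon single-bond
"generic" skeleton.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

from rdkit import Chem, RDLogger
from rdkit.Chem import DataStructs, rdFingerprintGenerator
from rdkit.Chem.MolStandardize import rdMolStandardize
from rdkit.Chem.Scaffolds import MurckoScaffold

RDLogger.DisableLog("rdApp.*")

#: Hashed fingerprint length.  The radius-2 circular fingerprint is folded to
#: this many bits; 2048 is the de-facto default for ECFP4-equivalent Tanimoto
#: similarity.
FINGERPRINT_BITS = 2048
FINGERPRINT_RADIUS = 2

_fp_generator = rdFingerprintGenerator.GetMorganGenerator(
    radius=FINGERPRINT_RADIUS, fpSize=FINGERPRINT_BITS
)


class MoleculeError(ValueError):
    """Raised for unparsable SMILES or failed standardization."""


class NoScaffoldError(ValueError):
    """Raised when a scaffold is requested for an acyclic molecule."""


@dataclass(frozen=True)
class CanonicalMolecule:
    """A standardized molecule identified by its canonical SMILES.

    Attributes
    ----------
    smiles : str
        Canonical isomeric SMILES; re-canonicalizing is a fixed point.
    heavy_atom_count : int
        Number of non-hydrogen atoms (>= 1).
    ring_count : int
        Number of SSSR rings (>= 0).
    """

    smiles: str
    heavy_atom_count: int
    ring_count: int

    def to_mol(self) -> Chem.Mol:
        return Chem.MolFromSmiles(self.smiles)


def standardize(raw_smiles: str) -> CanonicalMolecule:
    """Standardize a raw SMILES into a :class:`CanonicalMolecule`.

    Steps, in order: parse; normalization/reionization cleanup; keep the
    largest fragment; neutralize charges (where chemically possible);
    sanitize; drop explicit hydrogens.  Stereochemistry annotations are
    preserved through canonicalization.

    Raises
    ------
    MoleculeError
        If the SMILES cannot be parsed or nothing remains after fragment
        selection.
    """
    if not raw_smiles or not raw_smiles.strip():
        raise MoleculeError("empty SMILES")
    mol = Chem.MolFromSmiles(raw_smiles)
    if mol is None:
        raise MoleculeError(f"unparsable SMILES: {raw_smiles!r}")
    try:
        mol = rdMolStandardize.Cleanup(mol)  # normalize, disconnect metals, reionize
        mol = rdMolStandardize.FragmentParent(mol)  # largest fragment
        mol = rdMolStandardize.Uncharger().uncharge(mol)
        Chem.SanitizeMol(mol)
        mol = Chem.RemoveHs(mol)
    except Exception as exc:  # pragma: no cover - rdkit raises C++ exceptions
        raise MoleculeError(f"standardization failed for {raw_smiles!r}: {exc}") from exc
    if mol.GetNumHeavyAtoms() == 0:
        raise MoleculeError(f"no heavy atoms left after standardization: {raw_smiles!r}")
    smiles = Chem.MolToSmiles(mol)
    return CanonicalMolecule(
        smiles=smiles,
        heavy_atom_count=mol.GetNumHeavyAtoms(),
        ring_count=mol.GetRingInfo().NumRings(),
    )


@lru_cache(maxsize=200_000)
def _fingerprint_cached(smiles: str):
    return _fp_generator.GetFingerprint(Chem.MolFromSmiles(smiles))


def fingerprint(m: CanonicalMolecule):
    """Hashed binary circular fingerprint (radius 2, 2048 bits)."""
    return _fingerprint_cached(m.smiles)


def tanimoto(a: CanonicalMolecule, b: CanonicalMolecule) -> float:
    """Tanimoto similarity |A∩B| / |A∪B| over the two bit fingerprints."""
    return DataStructs.TanimotoSimilarity(fingerprint(a), fingerprint(b))


@lru_cache(maxsize=200_000)
def _scaffolds_cached(smiles: str) -> tuple[str, str]:
    mol = Chem.MolFromSmiles(smiles)
    core = MurckoScaffold.GetScaffoldForMol(mol)
    if core is None or core.GetNumHeavyAtoms() == 0:
        raise NoScaffoldError(f"acyclic molecule has no scaffold: {smiles}")
    generic = MurckoScaffold.MakeScaffoldGeneric(core)
    return Chem.MolToSmiles(core), Chem.MolToSmiles(generic)


def murcko_scaffold(m: CanonicalMolecule) -> str:
    """Canonical SMILES of the Murcko scaffold (rings + linkers, side chains off).

    Raises :class:`NoScaffoldError` for acyclic molecules — the corpus filter
    requires ring_count > 0, so hitting this is a caller bug.
    """
    if m.ring_count == 0:
        raise NoScaffoldError(f"acyclic molecule has no scaffold: {m.smiles}")
    return _scaffolds_cached(m.smiles)[0]


def generic_scaffold(m: CanonicalMolecule) -> str:
    """Murcko scaffold with all atoms as carbon and all bonds single."""
    if m.ring_count == 0:
        raise NoScaffoldError(f"acyclic molecule has no scaffold: {m.smiles}")
    return _scaffolds_cached(m.smiles)[1]
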