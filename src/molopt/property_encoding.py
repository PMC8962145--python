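"""Property profiles, property-change conditioning tokens, and the property oracle.

Three ADMET properties are tracked per molecule: logD (octanol/water
distribution coefficient at pH 7.4, log units), solubility (log10 µM) and
intrinsic clearance (log10 µL/min/mg).  The change between a source and a
target molecule is encoded as three discrete conditioning tokens:

* logD: half-open interval bins of width 0.2, ``(-0.1, 0.1]``, ``(0.1, 0.3]``
  ... tiling (-6.9, 6.9], plus two open end bins ``(-inf, -6.9]`` and
  ``(6.9, inf]`` — 71 tokens in total;
* solubility and clearance: ``low->high`` / ``high->low`` / ``no_change``
  relative to the low/high thresholds (50 µM, i.e. 1.7 in log10, for
  solubility; 20 µL/min/mg, i.e. 1.3, for clearance; "low" includes the
  threshold value).

Token strings are rendered in a single canonical ASCII form (``->`` arrow,
one space after the comma in interval labels); they double as vocabulary
entries for the sequence model.

The module also provides a pluggable *property oracle*: any callable mapping
a molecule to a :class:`PropertyProfile`.  The default
:func:`synthetic_oracle` computes deterministic pseudo-properties from cheap
atom-count descriptors, tuned so that synthetic corpora populate both sides
of both category thresholds and so that small substituent edits move the
values by amounts comparable to one or a few logD bins.
"""

from __future__ import annotations

import bisect
import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Callable

from rdkit import Chem

from .chem_ops import CanonicalMolecule, MoleculeError

# Category thresholds, log10 scale.
SOLUBILITY_THRESHOLD = 1.7  # log10(50 µM)
CLEARANCE_THRESHOLD = 1.3  # log10(20 µL/min/mg)

LOGD_BIN_WIDTH = 0.2
LOGD_EDGE = 6.9  # open bins beyond ±6.9

# interior bin edges: -6.9, -6.7, ..., 6.7, 6.9 (all odd tenths, so one
# decimal renders them exactly)
_EDGES = [round(-LOGD_EDGE + LOGD_BIN_WIDTH * i, 1) for i in range(70)]

LOW, HIGH = "low", "high"
NO_CHANGE, LOW_TO_HIGH, HIGH_TO_LOW = "no_change", "low->high", "high->low"


def encode_logd_change(delta: float) -> str:
    """Token for the half-open logD-change bin containing ``delta``.

    Bins are left-open/right-closed; a delta exactly on an edge belongs to
    the bin whose right edge it is.
    """
    if not math.isfinite(delta):
        raise ValueError(f"logD change must be finite, got {delta!r}")
    if delta <= -LOGD_EDGE:
        return "LogD_change_(-inf, -6.9]"
    if delta > LOGD_EDGE:
        return "LogD_change_(6.9, inf]"
    k = bisect.bisect_left(_EDGES, delta)
    return f"LogD_change_({_EDGES[k - 1]:.1f}, {_EDGES[k]:.1f}]"


def all_logd_tokens() -> list[str]:
    """Every logD-change token the encoder can emit, in ascending order."""
    tokens = ["LogD_change_(-inf, -6.9]"]
    tokens += [
        f"LogD_change_({_EDGES[i]:.1f}, {_EDGES[i + 1]:.1f}]" for i in range(len(_EDGES) - 1)
    ]
    tokens.append("LogD_change_(6.9, inf]")
    return tokens


def logd_bin_bounds(token: str) -> tuple[float, float]:
    """Parse a logD-change token back into its (lo, hi] interval bounds."""
    inner = token.removeprefix("LogD_change_(").removesuffix("]")
    lo_s, hi_s = inner.split(", ")
    lo = float("-inf") if lo_s == "-inf" else float(lo_s)
    hi = float("inf") if hi_s == "inf" else float(hi_s)
    return lo, hi


def mirror_logd_token(token: str) -> str:
    """Token of the bin mirrored about zero: (a, b] -> (-b, -a]."""
    lo, hi = logd_bin_bounds(token)
    if math.isinf(lo):
        return "LogD_change_(6.9, inf]"
    if math.isinf(hi):
        return "LogD_change_(-inf, -6.9]"
    return f"LogD_change_({-hi:.1f}, {-lo:.1f}]"


_THRESHOLDS = {"solubility": SOLUBILITY_THRESHOLD, "clearance": CLEARANCE_THRESHOLD}
_PROPERTY_LABEL = {"solubility": "Solubility", "clearance": "Clearance"}


def categorize(property_name: str, value: float) -> str:
    """Binary low/high category for a log10-scale property value."""
    try:
        threshold = _THRESHOLDS[property_name]
    except KeyError:
        raise ValueError(f"unknown categorical property: {property_name!r}") from None
    return LOW if value <= threshold else HIGH


def encode_category_change(property_name: str, src: float, tgt: float) -> str:
    """``<Property>_low->high`` / ``_high->low`` / ``_no_change`` token."""
    label = _PROPERTY_LABEL[property_name]
    a, b = categorize(property_name, src), categorize(property_name, tgt)
    if a == b:
        return f"{label}_{NO_CHANGE}"
    return f"{label}_{LOW_TO_HIGH}" if a == LOW else f"{label}_{HIGH_TO_LOW}"


def invert_category_token(token: str) -> str:
    if token.endswith(NO_CHANGE):
        return token
    label, move = token.rsplit("_", 1)
    return f"{label}_{HIGH_TO_LOW}" if move == LOW_TO_HIGH else f"{label}_{LOW_TO_HIGH}"


@dataclass(frozen=True)
class PropertyProfile:
    """Per-molecule property values (logD; solubility and clearance in log10)."""

    logd: float
    solubility: float
    clearance: float

    def __post_init__(self):
        for name in ("logd", "solubility", "clearance"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")


@dataclass(frozen=True)
class PropertyChange:
    """The three-token property-change constraint Z between a pair (X, Y)."""

    logd_token: str
    solubility_token: str
    clearance_token: str

    def tokens(self) -> tuple[str, str, str]:
        return (self.logd_token, self.solubility_token, self.clearance_token)

    def invert(self) -> "PropertyChange":
        """Constraint of the reversed pair: mirrored logD bin, flipped moves."""
        return PropertyChange(
            mirror_logd_token(self.logd_token),
            invert_category_token(self.solubility_token),
            invert_category_token(self.clearance_token),
        )


def property_change(src: PropertyProfile, tgt: PropertyProfile) -> PropertyChange:
    """Assemble the (logD, solubility, clearance) token triple for X -> Y."""
    return PropertyChange(
        encode_logd_change(tgt.logd - src.logd),
        encode_category_change("solubility", src.solubility, tgt.solubility),
        encode_category_change("clearance", src.clearance, tgt.clearance),
    )


# --------------------------------------------------------------------------
# Synthetic property oracle
# --------------------------------------------------------------------------

#: Descriptor weights of the synthetic oracle.  Pseudo-logD rises with
#: lipophilic atom counts (carbon, halogens) and falls with polar atoms
#: (N, O); pseudo-solubility is anti-correlated with pseudo-logD with an
#: extra oxygen bonus; pseudo-clearance is driven by a distinct combination
#: (size and halogens up, nitrogens down).  Values are chosen so that
#: drug-sized molecules (10-25 heavy atoms, 0-5 polar atoms) land on both
#: sides of the 1.7 / 1.3 category thresholds and a single substituent edit
#: moves logD by ~0.3-1.0 (one to a few bins).
ORACLE_WEIGHTS = {
    "logd_carbon": 0.28,
    "logd_halogen": 0.42,
    "logd_polar": -0.95,
    "logd_ring": 0.10,
    "logd_bias": -0.60,
    "sol_base": 3.00,
    "sol_logd": -0.80,
    "sol_oxygen": 0.15,
    "clr_carbon": 0.10,
    "clr_halogen": 0.30,
    "clr_nitrogen": -0.45,
    "clr_bias": 0.40,
}

_HALOGENS = {9, 17, 35, 53}


@lru_cache(maxsize=200_000)
def _oracle_cached(smiles: str) -> PropertyProfile:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise MoleculeError(f"oracle got unparsable SMILES: {smiles!r}")
    n_c = n_hal = n_n = n_o = 0
    for atom in mol.GetAtoms():
        z = atom.GetAtomicNum()
        if z == 6:
            n_c += 1
        elif z == 7:
            n_n += 1
        elif z == 8:
            n_o += 1
        elif z in _HALOGENS:
            n_hal += 1
    n_rings = mol.GetRingInfo().NumRings()
    w = ORACLE_WEIGHTS
    logd = (
        w["logd_carbon"] * n_c
        + w["logd_halogen"] * n_hal
        + w["logd_polar"] * (n_n + n_o)
        + w["logd_ring"] * n_rings
        + w["logd_bias"]
    )
    solubility = w["sol_base"] + w["sol_logd"] * logd + w["sol_oxygen"] * n_o
    clearance = (
        w["clr_bias"]
        + w["clr_carbon"] * n_c
        + w["clr_halogen"] * n_hal
        + w["clr_nitrogen"] * n_n
    )
    return PropertyProfile(round(logd, 6), round(solubility, 6), round(clearance, 6))


def synthetic_oracle(m: CanonicalMolecule | str) -> PropertyProfile:
    """Deterministic pseudo-property profile from structural descriptors.

    Stands in for a trained property predictor behind the same interface:
    any ``molecule -> PropertyProfile`` callable can replace it.
    """
    smiles = m if isinstance(m, str) else m.smiles
    return _oracle_cached(smiles)


PropertyOracle = Callable[[CanonicalMolecule], PropertyProfile]
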