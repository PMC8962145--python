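"""SMILES tokenization, vocabularies, and model sequence assembly.

SMILES are split into single-character tokens except for the two-character
elements ``Cl`` and ``Br``, bracketed atoms ``[...]`` (one token each) and
two-digit ring closures ``%nn``.  Concatenating the tokens reproduces the
input string exactly, which is the round-trip contract the decoder relies
on when emitted tokens are joined back into a SMILES.

A :class:`Vocabulary` is built per pair dataset from every SMILES token and
property-change token observed across all splits, plus four specials
(pad, start, end, unk).
"""

from __future__ import annotations

import logging
import re
from typing import Iterable, Sequence

from .property_encoding import PropertyChange

logger = logging.getLogger(__name__)

PAD, START, END, UNK = "<pad>", "<start>", "<end>", "<unk>"
SPECIAL_TOKENS = (PAD, START, END, UNK)

_TOKEN_RE = re.compile(r"\[[^\]]*\]|Br|Cl|%\d{2}|.")


class TokenizationError(ValueError):
    pass


def tokenize_smiles(smiles: str) -> list[str]:
    """Split a SMILES string into tokens; concatenation round-trips exactly."""
    tokens = _TOKEN_RE.findall(smiles)
    if "[" in tokens or "]" in tokens:
        raise TokenizationError(f"unbalanced bracket in SMILES: {smiles!r}")
    assert "".join(tokens) == smiles
    return tokens


def detokenize(tokens: Iterable[str]) -> str:
    return "".join(tokens)


class Vocabulary:
    """Dense token <-> index bijection with pad/start/end/unk specials."""

    def __init__(self, tokens: Iterable[str]):
        ordered = list(SPECIAL_TOKENS)
        seen = set(ordered)
        for tok in tokens:
            if tok not in seen:
                ordered.append(tok)
                seen.add(tok)
        self._tokens = ordered
        self._index = {tok: i for i, tok in enumerate(ordered)}
        self.pad = self._index[PAD]
        self.start = self._index[START]
        self.end = self._index[END]
        self.unk = self._index[UNK]

    def __len__(self) -> int:
        return len(self._tokens)

    def __contains__(self, token: str) -> bool:
        return token in self._index

    @property
    def tokens(self) -> list[str]:
        return list(self._tokens)

    def encode(self, tokens: Sequence[str]) -> list[int]:
        """Token strings to indices; out-of-vocabulary tokens become unk."""
        ids = []
        for tok in tokens:
            idx = self._index.get(tok)
            if idx is None:
                logger.warning("out-of-vocabulary token %r -> %s", tok, UNK)
                idx = self.unk
            ids.append(idx)
        return ids

    def decode(self, ids: Sequence[int]) -> list[str]:
        return [self._tokens[i] for i in ids]

    # -- persistence: plain text, one token per line, index == line number --

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("\n".join(self._tokens) + "\n")

    @classmethod
    def load(cls, path) -> "Vocabulary":
        with open(path) as fh:
            tokens = [line.rstrip("\n") for line in fh if line.rstrip("\n")]
        if tokens[: len(SPECIAL_TOKENS)] != list(SPECIAL_TOKENS):
            raise ValueError(f"vocabulary file {path} missing special-token header")
        return cls(tokens[len(SPECIAL_TOKENS):])


def build_vocab(dataset) -> Vocabulary:
    """Vocabulary from every SMILES and property token in a :class:`PairDataset`.

    Built from all splits of the dataset (a token seen only in validation or
    test is still included); two different criterion datasets may therefore
    have different vocabularies.
    """
    pairs = dataset.all_pairs() if hasattr(dataset, "all_pairs") else list(dataset)
    if not pairs:
        raise ValueError("cannot build a vocabulary from an empty dataset")
    smiles_tokens: dict[str, None] = {}
    property_tokens: dict[str, None] = {}
    for pair in pairs:
        for tok in tokenize_smiles(pair.source.molecule.smiles):
            smiles_tokens.setdefault(tok)
        for tok in tokenize_smiles(pair.target.molecule.smiles):
            smiles_tokens.setdefault(tok)
        for tok in pair.change.tokens():
            property_tokens.setdefault(tok)
    return Vocabulary(sorted(property_tokens) + sorted(smiles_tokens))


def assemble_source(change: PropertyChange | None, start_smiles: str) -> list[str]:
    """Model input: start + property tokens + SMILES tokens + end.

    ``change=None`` builds the unconditional (property-free) source used by
    the unconditioned model variant.
    """
    prop = list(change.tokens()) if change is not None else []
    return [START] + prop + tokenize_smiles(start_smiles) + [END]


def assemble_target(target_smiles: str) -> list[str]:
    """Model output sequence: start + SMILES tokens + end."""
    return [START] + tokenize_smiles(target_smiles) + [END]


def sequences_to_frame(dataset, conditional: bool = True):
    """Dataset sequences as a DataFrame of space-joined token strings.

    The canonical interval-token rendering contains a space after the comma;
    in this space-delimited serialization that internal space is dropped so
    the column splits back into tokens unambiguously.
    """
    import pandas as pd

    def join(tokens):
        return " ".join(tok.replace(" ", "") for tok in tokens)

    rows = []
    for split in ("train", "valid", "test"):
        for pair in dataset.split(split):
            change = pair.change if conditional else None
            rows.append(
                {
                    "source_tokens": join(assemble_source(change, pair.source.smiles)),
                    "target_tokens": join(assemble_target(pair.target.smiles)),
                    "split": split,
                }
            )
    return pd.DataFrame(rows, columns=["source_tokens", "target_tokens", "split"])
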