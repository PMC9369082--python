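"""Character-level integer encoding of SMILES and protein sequences.

Strings are mapped character-by-character to the integer codes of a
:class:`~csatdta.vocab.TokenVocabulary`, right-padded with zeros to a fixed
length (100 for drugs, 1000 for proteins by default) and truncated from the
right when longer.  The integer codes feed a learned embedding downstream;
no one-hot expansion happens here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .vocab import TokenVocabulary, build_protein_vocabulary, build_smiles_vocabulary

__all__ = [
    "EncodedSequence",
    "EncodingError",
    "DRUG_MAX_LEN",
    "PROTEIN_MAX_LEN",
    "encode_smiles",
    "encode_protein",
    "decode",
    "encode_dataframe",
]

DRUG_MAX_LEN = 100
PROTEIN_MAX_LEN = 1000


class EncodingError(ValueError):
    """Raised when a string cannot be encoded under a vocabulary."""


@dataclass(frozen=True)
class EncodedSequence:
    """A fixed-length integer token vector plus the original string length."""

    tokens: np.ndarray  # int64, shape (max_len,)
    true_length: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "tokens", np.asarray(self.tokens, dtype=np.int64))

    def __len__(self) -> int:
        return self.tokens.shape[0]


def _encode(s: str, vocab: TokenVocabulary, max_len: int, kind: str) -> EncodedSequence:
    if not s:
        raise EncodingError(f"empty {kind} string cannot be encoded")
    if max_len < 1:
        raise ValueError("max_len must be positive")
    out = np.zeros(max_len, dtype=np.int64)
    for pos, ch in enumerate(s[:max_len]):
        code = vocab.index_of.get(ch)
        if code is None:
            raise EncodingError(
                f"unknown {kind} character {ch!r} at position {pos}"
            )
        out[pos] = code
    # verify the truncated tail too, so errors do not depend on length
    for pos in range(max_len, len(s)):
        if s[pos] not in vocab:
            raise EncodingError(
                f"unknown {kind} character {s[pos]!r} at position {pos}"
            )
    return EncodedSequence(tokens=out, true_length=len(s))


def encode_smiles(
    s: str,
    vocab: TokenVocabulary | None = None,
    max_len: int = DRUG_MAX_LEN,
) -> EncodedSequence:
    """Encode a SMILES string (case-sensitive: aromatic atoms are lowercase).

    Unknown characters raise :class:`EncodingError` naming the character and
    its position, so vocabulary drift can never pass silently.
    """
    if vocab is None:
        vocab = build_smiles_vocabulary()
    return _encode(s, vocab, max_len, "SMILES")


def encode_protein(
    seq: str,
    vocab: TokenVocabulary | None = None,
    max_len: int = PROTEIN_MAX_LEN,
) -> EncodedSequence:
    """Encode an amino-acid sequence with alphabetical coding (A=1, ..., Y=25).

    Input is upper-cased first; non-letter characters raise
    :class:`EncodingError`.
    """
    if vocab is None:
        vocab = build_protein_vocabulary()
    return _encode(seq.upper(), vocab, max_len, "protein")


def decode(encoded: EncodedSequence, vocab: TokenVocabulary) -> str:
    """Invert the encoding for the stored (possibly truncated) prefix."""
    n = min(encoded.true_length, len(encoded))
    return "".join(vocab.token_at(int(i)) for i in encoded.tokens[:n])


def encode_dataframe(
    df: pd.DataFrame,
    drug_max_len: int = DRUG_MAX_LEN,
    protein_max_len: int = PROTEIN_MAX_LEN,
) -> tuple[np.ndarray, np.ndarray]:
    """Batch-encode a table with ``smiles`` and ``protein_sequence`` columns.

    Returns two integer matrices of shapes (n, drug_max_len) and
    (n, protein_max_len).
    """
    for col in ("smiles", "protein_sequence"):
        if col not in df.columns:
            raise KeyError(f"missing required column {col!r}")
    sv, pv = build_smiles_vocabulary(), build_protein_vocabulary()
    drugs = np.stack(
        [encode_smiles(s, sv, drug_max_len).tokens for s in df["smiles"]]
    )
    prots = np.stack(
        [encode_protein(p, pv, protein_max_len).tokens for p in df["protein_sequence"]]
    )
    return drugs, prots
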