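"""Fixed token vocabularies for SMILES strings and protein sequences.

Both vocabularies are frozen package constants rather than being scanned
from data, so the integer code of every character is stable across runs,
platforms and datasets.  Index 0 is reserved for padding in both alphabets
and never maps to a real token.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

__all__ = [
    "TokenVocabulary",
    "SMILES_CHARACTERS",
    "PROTEIN_LETTERS",
    "build_smiles_vocabulary",
    "build_protein_vocabulary",
]

# The 64-character SMILES alphabet: digits, ring/branch/bond/stereo
# punctuation, the full uppercase range (covering one-letter elements and the
# first letter of two-letter elements such as Cl and Br) and the lowercase
# letters that occur as aromatic atoms or as the second letter of an element
# symbol.  Sorted so indices are assigned deterministically.
SMILES_CHARACTERS: str = "".join(
    sorted(
        "0123456789"
        "#%()+-./=@[]\\"
        "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
        "abcdegilnoprstu"
    )
)

# 25 amino-acid letters: the 20 standard residues plus the ambiguity /
# nonstandard codes B, J, O, U and X.  Together these are exactly the
# alphabet A..Y, so alphabetical coding gives A=1, C=3, D=4, ... Y=25.
PROTEIN_LETTERS: str = "ABCDEFGHIJKLMNOPQRSTUVWXY"

assert len(SMILES_CHARACTERS) == 64
assert len(PROTEIN_LETTERS) == 25


@dataclass(frozen=True)
class TokenVocabulary:
    """An ordered token -> positive integer map with 0 reserved for padding.

    Attributes
    ----------
    symbols:
        Tokens in index order; ``symbols[i]`` has integer code ``i + 1``.
    index_of:
        Mapping from token to its 1-based integer code.
    """

    symbols: tuple[str, ...]
    index_of: dict[str, int] = field(init=False, repr=False)
    pad_index: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(
            self,
            "index_of",
            {tok: i + 1 for i, tok in enumerate(self.symbols)},
        )
        if len(self.index_of) != len(self.symbols):
            raise ValueError("duplicate tokens in vocabulary")

    @property
    def size(self) -> int:
        """Number of real (non-pad) tokens."""
        return len(self.symbols)

    def __contains__(self, token: str) -> bool:
        return token in self.index_of

    def __getitem__(self, token: str) -> int:
        return self.index_of[token]

    def token_at(self, index: int) -> str:
        """Inverse lookup; index must be a real token code (1-based)."""
        if not 1 <= index <= self.size:
            raise KeyError(f"index {index} outside 1..{self.size}")
        return self.symbols[index - 1]

    def to_json(self) -> str:
        """Serialize as a ``{"token": index}`` JSON object."""
        return json.dumps(self.index_of, ensure_ascii=False)

    @classmethod
    def from_json(cls, text: str) -> "TokenVocabulary":
        mapping = json.loads(text)
        items = sorted(mapping.items(), key=lambda kv: kv[1])
        indices = [v for _, v in items]
        if indices != list(range(1, len(items) + 1)):
            raise ValueError("vocabulary indices must be contiguous 1..size")
        return cls(symbols=tuple(k for k, _ in items))


def build_smiles_vocabulary() -> TokenVocabulary:
    """Return the frozen 64-token SMILES vocabulary."""
    return TokenVocabulary(symbols=tuple(SMILES_CHARACTERS))


def build_protein_vocabulary() -> TokenVocabulary:
    """Return the 25-letter amino-acid vocabulary (alphabetical, A=1)."""
    return TokenVocabulary(symbols=tuple(PROTEIN_LETTERS))
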