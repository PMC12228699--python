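"""Regex SMILES tokenizer with token-to-atom mapping.

Splits a SMILES string into chemically meaningful tokens: bracket atoms
(``[NH3+]``), two-letter organic-subset elements (``Cl``, ``Br``),
one-letter aliphatic and aromatic atoms, bonds, ring-closure digits and
branch parentheses. Atom-bearing tokens are numbered left to right, which
matches the atom numbering RDKit assigns when parsing the same string —
the property the attribution module relies on to turn token scores into
atom scores.
"""

from __future__ import annotations

import re

# Order matters: bracket atoms and two-letter elements before single letters.
_TOKEN_RE = re.compile(
    r"(\[[^\]]+\]|Br|Cl|B|C|N|O|P|S|F|I|b|c|n|o|s|p|%\d{2}|\d|@@|@|=|#|\$|:|~|/|\\|\.|\-|\+|\(|\))"
)

_ATOM_TOKEN_RE = re.compile(r"^(\[[^\]]+\]|Br|Cl|B|C|N|O|P|S|F|I|b|c|n|o|s|p)$")


class TokenizationError(ValueError):
    pass


def tokenize(smiles: str) -> list[tuple[str, int | None]]:
    """Split a SMILES string into (token_text, atom_index or None) pairs.

    The concatenation of token texts reproduces the input exactly; tokens
    that introduce an atom carry sequential atom indices, all others map to
    ``None``.

    Raises
    ------
    TokenizationError
        If any character cannot be consumed by the token grammar.
    """
    tokens: list[tuple[str, int | None]] = []
    pos = 0
    atom_idx = 0
    while pos < len(smiles):
        match = _TOKEN_RE.match(smiles, pos)
        if match is None:
            raise TokenizationError(
                f"cannot tokenize {smiles!r} at position {pos}: {smiles[pos]!r}"
            )
        tok = match.group(0)
        if _ATOM_TOKEN_RE.match(tok):
            tokens.append((tok, atom_idx))
            atom_idx += 1
        else:
            tokens.append((tok, None))
        pos = match.end()
    return tokens


def token_texts(smiles: str) -> list[str]:
    return [t for t, _ in tokenize(smiles)]


class Vocab:
    """Token vocabulary with reserved padding and unknown-token ids."""

    PAD = 0
    UNK = 1

    def __init__(self, tokens):
        self.id_to_token = ["<pad>", "<unk>"] + sorted(set(tokens))
        self.token_to_id = {t: i for i, t in enumerate(self.id_to_token)}

    def __len__(self) -> int:
        return len(self.id_to_token)

    def encode(self, smiles: str) -> list[int]:
        return [
            self.token_to_id.get(tok, self.UNK) for tok in token_texts(smiles)
        ]

    @classmethod
    def from_corpus(cls, smiles_list) -> "Vocab":
        toks: list[str] = []
        for s in smiles_list:
            toks.extend(token_texts(s))
        return cls(toks)

    def to_dict(self) -> dict:
        return {"id_to_token": self.id_to_token}

    @classmethod
    def from_dict(cls, d: dict) -> "Vocab":
        v = cls.__new__(cls)
        v.id_to_token = list(d["id_to_token"])
        v.token_to_id = {t: i for i, t in enumerate(v.id_to_token)}
        return v
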