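"""SMILES tokenization and vocabulary for the sequence model.

Tokens are SMILES lexemes, not characters: bracket atoms (``[nH]``,
``[C@@H]``), two-letter elements (``Cl``, ``Br``) and ``%nn`` ring closures
stay atomic, so the round trip tokenize -> detokenize is the identity on any
syntactically valid SMILES. Three special tokens frame every sequence:
``<pad>`` (index 0), ``^`` (begin) and ``$`` (end).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

__all__ = ["Vocabulary", "tokenize"]

_TOKEN_RE = re.compile(
    r"(\[[^\]]+\]|Br|Cl|%\d{2}|[bcnosp]|[BCNOSPFI]|\(|\)|\.|=|#|-|\+|\\|/|:|~|@|\?|>|\*|\$|\d)"
)

PAD, BEGIN, END = "<pad>", "^", "$"


def tokenize(smiles: str) -> list[str]:
    """Split a SMILES string into lexemes.

    Raises ``ValueError`` if any character falls outside the grammar.
    """
    tokens = _TOKEN_RE.findall(smiles)
    if "".join(tokens) != smiles:
        raise ValueError(f"untokenizable SMILES: {smiles!r}")
    return tokens


@dataclass(frozen=True)
class Vocabulary:
    tokens: tuple[str, ...]  # includes the three specials
    index: dict[str, int] = field(repr=False)

    @classmethod
    def from_corpus(cls, corpus: list[str]) -> "Vocabulary":
        seen: set[str] = set()
        for smi in corpus:
            seen.update(tokenize(smi))
        ordered = (PAD, BEGIN, END, *sorted(seen))
        return cls(ordered, {t: i for i, t in enumerate(ordered)})

    @classmethod
    def from_tokens(cls, tokens: list[str]) -> "Vocabulary":
        ordered = tuple(tokens)
        assert ordered[:3] == (PAD, BEGIN, END)
        return cls(ordered, {t: i for i, t in enumerate(ordered)})

    def __len__(self) -> int:
        return len(self.tokens)

    @property
    def pad(self) -> int:
        return 0

    @property
    def begin(self) -> int:
        return 1

    @property
    def end(self) -> int:
        return 2

    def encode(self, smiles: str) -> list[int]:
        """Token indices, without begin/end framing."""
        try:
            return [self.index[t] for t in tokenize(smiles)]
        except KeyError as exc:
            raise ValueError(f"token {exc.args[0]!r} not in vocabulary") from None

    def decode(self, ids: list[int]) -> str:
        """Back to a SMILES string; specials are dropped."""
        return "".join(self.tokens[i] for i in ids if i > 2)
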