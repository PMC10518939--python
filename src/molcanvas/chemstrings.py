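"""Tokenizers and vocabularies for molecular line notations.

Atom-level tokenization of SMILES, DeepSMILES and SELFIES strings, a
learned pair-encoding (byte-pair-encoding over molecular tokens, the
SmilesPE idea), and vocabulary construction with the seven special tokens
used by the blank language model: ``PAD UNK FIRST LAST EOS BLANK BLANK_0``.

The SMILES vocabulary is restricted to the drug-like chemistry of the
MOSES benchmark: atoms C c O o N n F S s Cl Br [nH] [H], bonds ``- = #``,
ring-closure digits 1..6 and the two branch parentheses.  Two-letter
halogens and bracket expressions are single tokens; two-digit ``%nn``
ring closures are rejected with a clear error.
"""

from __future__ import annotations

import json
import re
from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence


class Kind(str, Enum):
    ATOM = "atom"
    BOND = "bond"
    RING = "ring"
    BRANCH = "branch"
    SPECIAL = "special"
    FRAGMENT = "fragment"


@dataclass(frozen=True)
class Token:
    text: str
    kind: Kind

    def __post_init__(self):
        if not self.text:
            raise ValueError("Token text must be non-empty")

    def __str__(self) -> str:
        return self.text


SPECIAL_TOKENS = ("PAD", "UNK", "FIRST", "LAST", "EOS", "BLANK", "BLANK_0")

PAD, UNK, FIRST, LAST, EOS, BLANK, BLANK_0 = (
    Token(t, Kind.SPECIAL) for t in SPECIAL_TOKENS
)

# MOSES drug-like chemistry, atom-level SMILES
MOSES_ATOM_TOKENS = ("C", "c", "O", "o", "N", "n", "F", "S", "s", "Cl", "Br",
                     "[nH]", "[H]")
BOND_TOKENS = ("-", "=", "#")
RING_TOKENS = ("1", "2", "3", "4", "5", "6")
BRANCH_TOKENS = ("(", ")")

_ATOM_CHARS = set("CcOoNnFSs")
_SMILES_RE = re.compile(r"Cl|Br|\[[^\]]+\]|[CcOoNnFSs]|[-=#]|[1-6]|[()]")
_SELFIES_RE = re.compile(r"\[[^\[\]]*\]")


class TokenizeError(ValueError):
    """Raised when a molecule string cannot be tokenized."""


def classify(text: str) -> Kind:
    """Assign the vocabulary kind of a single token text."""
    if text in SPECIAL_TOKENS:
        return Kind.SPECIAL
    if text in BOND_TOKENS:
        return Kind.BOND
    if text in BRANCH_TOKENS or text == ")":
        return Kind.BRANCH
    if text.isdigit():
        return Kind.RING
    if (text in _ATOM_CHARS or text in ("Cl", "Br")
            or (text.startswith("[") and text.endswith("]"))):
        return Kind.ATOM
    return Kind.FRAGMENT


def tokenize_atomwise(molecule: str, representation: str = "SMILES",
                      lenient: bool = False) -> list[Token]:
    """Split a molecule line into atom-level tokens.

    ``representation`` is one of ``SMILES``, ``DEEPSMILES``, ``SELFIES``.
    Concatenating the returned token texts reproduces the input exactly.
    Unknown characters raise :class:`TokenizeError` naming the position,
    or become ``UNK`` tokens when ``lenient`` is true.
    """
    rep = representation.upper()
    if rep == "SELFIES":
        return _tokenize_selfies(molecule, lenient)
    if rep == "DEEPSMILES":
        return _tokenize_linear(molecule, lenient, deepsmiles=True)
    if rep == "SMILES":
        return _tokenize_linear(molecule, lenient, deepsmiles=False)
    raise ValueError(f"unknown representation {representation!r}")


def _tokenize_linear(s: str, lenient: bool, deepsmiles: bool) -> list[Token]:
    tokens: list[Token] = []
    i = 0
    n = len(s)
    digits = "123456789" if deepsmiles else "123456"
    while i < n:
        ch = s[i]
        if s.startswith("Cl", i) or s.startswith("Br", i):
            tokens.append(Token(s[i:i + 2], Kind.ATOM))
            i += 2
        elif ch == "[":
            j = s.find("]", i)
            if j < 0:
                raise TokenizeError(f"unclosed bracket at position {i}")
            tokens.append(Token(s[i:j + 1], Kind.ATOM))
            i = j + 1
        elif ch in _ATOM_CHARS:
            tokens.append(Token(ch, Kind.ATOM))
            i += 1
        elif ch in "-=#":
            tokens.append(Token(ch, Kind.BOND))
            i += 1
        elif ch in digits:
            tokens.append(Token(ch, Kind.RING))
            i += 1
        elif ch == "%":
            # two-digit closures occur only in DeepSMILES (ring spans > 9)
            if deepsmiles and i + 2 < n + 1 and s[i + 1:i + 3].isdigit():
                tokens.append(Token(s[i:i + 3], Kind.RING))
                i += 3
            else:
                raise TokenizeError(
                    f"two-digit ring closure '%' at position {i} is not "
                    "supported (SMILES ring tokens are single digits 1-6)")
        elif not deepsmiles and ch in "()":
            tokens.append(Token(ch, Kind.BRANCH))
            i += 1
        elif deepsmiles and ch == ")":
            tokens.append(Token(ch, Kind.BRANCH))
            i += 1
        elif lenient:
            tokens.append(UNK)
            i += 1
        else:
            raise TokenizeError(f"unknown character {ch!r} at position {i}")
    return tokens


def _tokenize_selfies(s: str, lenient: bool) -> list[Token]:
    tokens: list[Token] = []
    i = 0
    while i < len(s):
        m = _SELFIES_RE.match(s, i)
        if m is None:
            if lenient:
                tokens.append(UNK)
                i += 1
                continue
            raise TokenizeError(
                f"unknown character {s[i]!r} at position {i} "
                "(SELFIES tokens are bracketed symbols)")
        tokens.append(Token(m.group(0), Kind.ATOM))
        i = m.end()
    return tokens


def detokenize(tokens: Sequence[Token]) -> str:
    """Concatenate token texts back into a molecule line.

    Special tokens are meaningless in a molecule string and raise.
    """
    for t in tokens:
        if t.kind is Kind.SPECIAL:
            raise ValueError(f"special token {t.text!r} in detokenize input")
    return "".join(t.text for t in tokens)


# ---------------------------------------------------------------------------
# Pair encoding (BPE over molecular tokens)
# ---------------------------------------------------------------------------

@dataclass
class MergeTable:
    """Ordered pair merges learned from a corpus, most frequent first."""
    merges: list[tuple[str, str]] = field(default_factory=list)
    learned_from: str = ""

    def to_json(self) -> str:
        return json.dumps({"merges": self.merges,
                           "learned_from": self.learned_from})

    @classmethod
    def from_json(cls, text: str) -> "MergeTable":
        d = json.loads(text)
        return cls(merges=[tuple(m) for m in d["merges"]],
                   learned_from=d.get("learned_from", ""))


def learn_pair_encoding(corpus: Sequence[Sequence[Token]], num_merges: int,
                        learned_from: str = "") -> MergeTable:
    """Learn ``num_merges`` pair merges by descending pair frequency.

    Ties are broken lexicographically on the concatenated pair text for
    reproducibility.  A zero merge budget yields an empty table.
    """
    if not corpus:
        raise ValueError("pair encoding requires a non-empty corpus")
    if num_merges < 0:
        raise ValueError("num_merges must be >= 0")
    seqs = [[t.text for t in toks] for toks in corpus]
    merges: list[tuple[str, str]] = []
    for _ in range(num_merges):
        counts: Counter[tuple[str, str]] = Counter()
        for seq in seqs:
            for a, b in zip(seq, seq[1:]):
                counts[(a, b)] += 1
        if not counts:
            break
        best = min(counts.items(), key=lambda kv: (-kv[1], kv[0][0] + kv[0][1]))
        pair = best[0]
        merges.append(pair)
        seqs = [_merge_seq(seq, pair) for seq in seqs]
    return MergeTable(merges=merges, learned_from=learned_from)


def _merge_seq(seq: list[str], pair: tuple[str, str]) -> list[str]:
    out: list[str] = []
    i = 0
    while i < len(seq):
        if i + 1 < len(seq) and (seq[i], seq[i + 1]) == pair:
            out.append(seq[i] + seq[i + 1])
            i += 2
        else:
            out.append(seq[i])
            i += 1
    return out


def apply_pair_encoding(tokens: Sequence[Token], table: MergeTable) -> list[Token]:
    """Apply learned merges greedily, in learned order.

    The concatenation of token texts is invariant under this operation.
    Merged tokens have kind ``fragment``.
    """
    seq = [t.text for t in tokens]
    for pair in table.merges:
        seq = _merge_seq(seq, pair)
    out = []
    for text in seq:
        k = classify(text)
        out.append(Token(text, k if k is not Kind.SPECIAL else Kind.FRAGMENT))
    return out


# ---------------------------------------------------------------------------
# Vocabulary
# ---------------------------------------------------------------------------

@dataclass
class Vocabulary:
    """Ordered token set with a dense text -> id index.

    The seven special tokens always occupy ids 0..6.
    """
    tokens: list[Token]
    representation: str = "SMILES"
    scheme: str = "atom"
    index: dict[str, int] = field(init=False)

    def __post_init__(self):
        texts = [t.text for t in self.tokens]
        if len(set(texts)) != len(texts):
            raise ValueError("duplicate token texts in vocabulary")
        n_special = sum(1 for t in self.tokens if t.kind is Kind.SPECIAL)
        if n_special != len(SPECIAL_TOKENS):
            raise ValueError(f"expected {len(SPECIAL_TOKENS)} special tokens, "
                             f"got {n_special}")
        self.index = {t.text: i for i, t in enumerate(self.tokens)}

    def __len__(self) -> int:
        return len(self.tokens)

    def __contains__(self, text: str) -> bool:
        return text in self.index

    def id(self, text: str) -> int:
        try:
            return self.index[text]
        except KeyError:
            raise KeyError(f"token {text!r} not in vocabulary") from None

    def token(self, i: int) -> Token:
        return self.tokens[i]

    def count(self, kind: Kind) -> int:
        return sum(1 for t in self.tokens if t.kind is kind)

    @property
    def insertable_ids(self) -> list[int]:
        """Ids of tokens the model may write onto the canvas."""
        return [i for i, t in enumerate(self.tokens)
                if t.kind is not Kind.SPECIAL]

    def to_json(self) -> str:
        return json.dumps({
            "representation": self.representation,
            "scheme": self.scheme,
            "tokens": [[t.text, t.kind.value] for t in self.tokens],
        })

    @classmethod
    def from_json(cls, text: str) -> "Vocabulary":
        d = json.loads(text)
        toks = [Token(t, Kind(k)) for t, k in d["tokens"]]
        return cls(tokens=toks, representation=d["representation"],
                   scheme=d["scheme"])


def _special_tokens() -> list[Token]:
    return [Token(t, Kind.SPECIAL) for t in SPECIAL_TOKENS]


def build_vocabulary(corpus: Iterable[str], representation: str = "SMILES",
                     scheme: str = "atom",
                     merge_table: MergeTable | None = None) -> Vocabulary:
    """Build a vocabulary of the 7 specials plus all distinct corpus tokens.

    Corpus tokens are ordered by kind (atoms, bonds, rings, branches,
    fragments) then text, so ids are deterministic for a given corpus.
    """
    corpus = list(corpus)
    if not corpus:
        raise ValueError("cannot build a vocabulary from an empty corpus")
    seen: dict[str, Token] = {}
    for line in corpus:
        toks = tokenize_atomwise(line, representation)
        if merge_table is not None:
            toks = apply_pair_encoding(toks, merge_table)
        for t in toks:
            seen.setdefault(t.text, t)
    kind_order = {Kind.ATOM: 0, Kind.BOND: 1, Kind.RING: 2,
                  Kind.BRANCH: 3, Kind.FRAGMENT: 4}
    ordered = sorted(seen.values(), key=lambda t: (kind_order[t.kind], t.text))
    return Vocabulary(tokens=_special_tokens() + ordered,
                      representation=representation,
                      scheme="pair_encoding" if merge_table else scheme)


def moses_smiles_vocabulary() -> Vocabulary:
    """The canonical atom-level SMILES vocabulary for MOSES chemistry.

    7 special + 13 atom + 3 bond + 6 ring + 2 branch tokens.
    """
    toks = _special_tokens()
    toks += [Token(t, Kind.ATOM) for t in MOSES_ATOM_TOKENS]
    toks += [Token(t, Kind.BOND) for t in BOND_TOKENS]
    toks += [Token(t, Kind.RING) for t in RING_TOKENS]
    toks += [Token(t, Kind.BRANCH) for t in BRANCH_TOKENS]
    return Vocabulary(tokens=toks, representation="SMILES", scheme="atom")
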