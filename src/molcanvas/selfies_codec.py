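"""A SELFIES-style robust molecular string codec.

SELFIES-class languages make generative modeling robust by construction:
the decoder is a *total* function, so every token sequence derives a
valence-legal molecular graph.  This module implements the package's own
dialect of that idea for MOSES-like chemistry (C, N, O, S, F, Cl, Br):

* atom tokens ``[C] [=C] [#C] [N] ... [Br]`` — the optional prefix is the
  bond order to the preceding atom, capped by the remaining valences of
  both endpoints (C4, N3, O2, S6, halogens 1);
* ``[Branch1]``/``[Branch2]`` followed by one/two index tokens encoding a
  branch of Q+1 tokens attached to the current atom;
* ``[Ring1]``/``[=Ring1]``/``[Ring2]``/``[=Ring2]`` followed by index
  token(s): a ring-closure bond from the current atom to the atom Q+1
  steps back in emission order;
* index tokens ``[0]``..``[15]`` (two index tokens encode Q = 16*hi + lo).

Derivation rules keep the decoder total: impossible requests (a ring bond
to a nonexistent atom, a branch on a saturated atom, an over-valent bond)
are capped or skipped rather than rejected; a branch or ring symbol with
no preceding atom is skipped alone, before any index token is read.
Aromatic systems are encoded kekulized; RDKit re-perceives aromaticity on
decoding.  A token sequence containing no atom token decodes to the empty
string, which is not a molecule; every sequence containing at least one
atom token yields a valid molecule (index tokens are only ever consumed
after an atom exists).
"""

from __future__ import annotations

import re
from rdkit import Chem

from .chemstrings import TokenizeError

_ELEMENTS = ("C", "N", "O", "S", "F", "Cl", "Br")
_VALENCE = {"C": 4, "N": 3, "O": 2, "S": 6, "F": 1, "Cl": 1, "Br": 1}
_BOND_PREFIX = {"": 1, "=": 2, "#": 3}
_PREFIX_OF = {1: "", 2: "=", 3: "#"}
_BOND_TYPE = {1: Chem.BondType.SINGLE, 2: Chem.BondType.DOUBLE,
              3: Chem.BondType.TRIPLE}

_ATOM_RE = re.compile(r"\[([=#]?)(C|N|O|S|F|Cl|Br)\]")
_TOKEN_RE = re.compile(r"\[[^\[\]]*\]")

INDEX_TOKENS = tuple(f"[{i}]" for i in range(16))
_INDEX_VALUE = {t: i for i, t in enumerate(INDEX_TOKENS)}


class EncodeError(ValueError):
    """Raised when a molecule cannot be expressed in this dialect."""


def alphabet() -> list[str]:
    """All tokens of the dialect (atoms, branches, rings, indices)."""
    toks = [f"[{p}{e}]" for e in _ELEMENTS for p in ("", "=", "#")
            if not (p and _VALENCE[e] < _BOND_PREFIX[p])]
    toks += ["[Branch1]", "[Branch2]", "[Ring1]", "[=Ring1]",
             "[Ring2]", "[=Ring2]"]
    toks += list(INDEX_TOKENS)
    return toks


def atom_tokens() -> list[str]:
    """The atom tokens of the dialect (bond-prefixed element symbols)."""
    return [t for t in alphabet() if _ATOM_RE.fullmatch(t)]


def split_tokens(selfies: str) -> list[str]:
    out = []
    i = 0
    while i < len(selfies):
        m = _TOKEN_RE.match(selfies, i)
        if m is None:
            raise TokenizeError(f"malformed token at position {i} of "
                                f"{selfies!r}")
        out.append(m.group(0))
        i = m.end()
    return out


# ---------------------------------------------------------------------------
# Decoding (total)
# ---------------------------------------------------------------------------

class _Graph:
    def __init__(self):
        self.elems: list[str] = []
        self.free: list[int] = []
        self.bonds: dict[tuple[int, int], int] = {}

    def add_atom(self, elem: str) -> int:
        self.elems.append(elem)
        self.free.append(_VALENCE[elem])
        return len(self.elems) - 1

    def add_bond(self, i: int, j: int, order: int) -> None:
        self.bonds[(min(i, j), max(i, j))] = order
        self.free[i] -= order
        self.free[j] -= order

    def has_bond(self, i: int, j: int) -> bool:
        return (min(i, j), max(i, j)) in self.bonds


def _read_index(tokens: list[str], i: int, n: int) -> tuple[int, int]:
    q = 0
    for _ in range(n):
        v = 0
        if i < len(tokens):
            v = _INDEX_VALUE.get(tokens[i], 0)
            i += 1
        q = q * 16 + v
    return q, i


def _derive(tokens: list[str], g: _Graph, attach: int | None) -> None:
    prev = attach
    i = 0
    n = len(tokens)
    while i < n:
        tok = tokens[i]
        i += 1
        m = _ATOM_RE.fullmatch(tok)
        if m:
            if prev is not None and g.free[prev] == 0:
                return  # saturated: derivation of this scope stops
            order = _BOND_PREFIX[m.group(1)]
            a = g.add_atom(m.group(2))
            if prev is not None:
                g.add_bond(prev, a, min(order, g.free[prev], g.free[a]))
            prev = a
        elif tok in ("[Branch1]", "[Branch2]"):
            if prev is None or g.free[prev] < 2:
                continue  # inapplicable branch symbol: skipped alone
            q, i = _read_index(tokens, i, 1 if tok == "[Branch1]" else 2)
            content = tokens[i:i + q + 1]
            i += q + 1
            if content:
                _derive(content, g, attach=prev)
        elif tok in ("[Ring1]", "[=Ring1]", "[Ring2]", "[=Ring2]"):
            if prev is None:
                continue  # inapplicable ring symbol: skipped alone
            order = 2 if tok.startswith("[=") else 1
            q, i = _read_index(tokens, i, 1 if tok.endswith("g1]") else 2)
            target = prev - (q + 1)
            if target < 0 or target == prev or g.has_bond(prev, target):
                continue
            o = min(order, g.free[prev], g.free[target])
            if o >= 1:
                g.add_bond(prev, target, o)
        else:
            continue  # standalone index or unknown token: no-op


def decode(selfies: str | list[str]) -> str:
    """Decode a token sequence to a canonical SMILES string.

    Total: any token sequence is accepted.  Returns '' when the sequence
    contains no atom token (no molecule can be derived).
    """
    tokens = split_tokens(selfies) if isinstance(selfies, str) else list(selfies)
    g = _Graph()
    _derive(tokens, g, attach=None)
    if not g.elems:
        return ""
    rw = Chem.RWMol()
    for e in g.elems:
        rw.AddAtom(Chem.Atom(e))
    for (a, b), order in g.bonds.items():
        rw.AddBond(a, b, _BOND_TYPE[order])
    mol = rw.GetMol()
    Chem.SanitizeMol(mol)
    return Chem.MolToSmiles(mol)


# ---------------------------------------------------------------------------
# Encoding
# ---------------------------------------------------------------------------

def _index_tokens(q: int, wide: bool) -> list[str]:
    if wide:
        return [INDEX_TOKENS[q // 16], INDEX_TOKENS[q % 16]]
    return [INDEX_TOKENS[q]]


def encode(smiles: str) -> str:
    """Encode a SMILES string into the dialect (stereochemistry dropped).

    Raises :class:`EncodeError` for molecules outside the dialect's
    chemistry (charges, radicals, elements beyond C/N/O/S/F/Cl/Br).
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise EncodeError(f"not a valid SMILES: {smiles!r}")
    Chem.RemoveStereochemistry(mol)
    for atom in mol.GetAtoms():
        if atom.GetSymbol() not in _ELEMENTS:
            raise EncodeError(f"element {atom.GetSymbol()} not in dialect")
        if atom.GetFormalCharge() != 0 or atom.GetNumRadicalElectrons() != 0:
            raise EncodeError("charged or radical atoms not supported")
        atom.SetIsotope(0)
    Chem.Kekulize(mol, clearAromaticFlags=True)

    nbrs = {a.GetIdx(): sorted(n.GetIdx() for n in a.GetNeighbors())
            for a in mol.GetAtoms()}

    def bond_order(a: int, b: int) -> int:
        return int(mol.GetBondBetweenAtoms(a, b).GetBondTypeAsDouble())

    # DFS pre-order from atom 0: tree edges and ring-closure (back) edges
    pos: dict[int, int] = {}
    parent: dict[int, int | None] = {0: None}
    children: dict[int, list[int]] = {i: [] for i in nbrs}
    closures: dict[int, list[int]] = {i: [] for i in nbrs}  # at later atom
    seen_edges: set[tuple[int, int]] = set()

    def dfs(a: int) -> None:
        pos[a] = len(pos)
        for b in nbrs[a]:
            e = (min(a, b), max(a, b))
            if e in seen_edges:
                continue
            seen_edges.add(e)
            if b in pos:
                closures[a].append(b)
            else:
                parent[b] = a
                children[a].append(b)
                dfs(b)

    dfs(0)
    if len(pos) != mol.GetNumAtoms():
        raise EncodeError("disconnected molecules not supported")

    def atom_token(order: int, a: int) -> str:
        return f"[{_PREFIX_OF[order]}{mol.GetAtomWithIdx(a).GetSymbol()}]"

    def ring_tokens(a: int, b: int) -> list[str]:
        order = bond_order(a, b)
        if order > 2:
            raise EncodeError("triple-bond ring closures not supported")
        q = pos[a] - pos[b] - 1
        if q < 0:
            raise EncodeError("ring closure to a later atom")
        sym = "[=Ring" if order == 2 else "[Ring"
        if q < 16:
            return [sym + "1]"] + _index_tokens(q, wide=False)
        if q < 256:
            return [sym + "2]"] + _index_tokens(q, wide=True)
        raise EncodeError("ring span too large for this dialect")

    def emit(a: int) -> list[str]:
        toks: list[str] = []
        for b in sorted(closures[a], key=lambda b: pos[b]):
            toks += ring_tokens(a, b)
        kids = children[a]
        for k in kids[:-1]:
            sub = [atom_token(bond_order(a, k), k)] + emit(k)
            q = len(sub) - 1
            if q < 16:
                toks += ["[Branch1]"] + _index_tokens(q, wide=False) + sub
            elif q < 256:
                toks += ["[Branch2]"] + _index_tokens(q, wide=True) + sub
            else:
                raise EncodeError("branch too large for this dialect")
        if kids:
            k = kids[-1]
            toks += [atom_token(bond_order(a, k), k)] + emit(k)
        return toks

    first = mol.GetAtomWithIdx(0).GetSymbol()
    return "".join([f"[{first}]"] + emit(0))
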