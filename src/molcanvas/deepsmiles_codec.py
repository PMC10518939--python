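"""Syntactic SMILES <-> DeepSMILES conversion.

DeepSMILES removes the two paired constructs of SMILES that generative
models most often get wrong.  Open parentheses are dropped: a branch of
k atoms is followed by k closing parentheses, each popping one atom off
the current path.  Paired ring-closure digits become a single digit at
the closing site, counting atoms back along the current path (6 for
benzene); spans above 9 use the ``%nn`` form.  The transform is purely
syntactic; semantic (valence) mistakes remain possible, which is the
point of comparing the representations.
"""

from __future__ import annotations

from .chemstrings import Kind, tokenize_atomwise


class DeepSmilesError(ValueError):
    """Raised when a (Deep)SMILES string cannot be converted."""


def _digit_text(n: int) -> str:
    if n <= 9:
        return str(n)
    if n <= 99:
        return f"%{n:02d}"
    raise DeepSmilesError(f"ring span {n} too large")


def to_deepsmiles(smiles: str) -> str:
    """Convert a SMILES line to DeepSMILES."""
    tokens = tokenize_atomwise(smiles, "SMILES")
    out: list[str] = []
    stack: list[int] = []          # atom ids along the current path
    saves: list[int] = []          # stack depth at each open parenthesis
    open_rings: dict[str, int] = {}  # SMILES ring digit -> atom id
    atom_id = 0
    for t in tokens:
        if t.kind is Kind.ATOM:
            atom_id += 1
            stack.append(atom_id)
            out.append(t.text)
        elif t.kind is Kind.RING:
            if t.text in open_rings:
                opener = open_rings.pop(t.text)
                try:
                    span = len(stack) - stack.index(opener)
                except ValueError:
                    raise DeepSmilesError(
                        "ring closure partner left the current path") from None
                out.append(_digit_text(span))
            else:
                open_rings[t.text] = stack[-1]
        elif t.text == "(":
            saves.append(len(stack))
        elif t.text == ")":
            if not saves:
                raise DeepSmilesError("unmatched ')' in SMILES input")
            depth = len(stack) - saves.pop()
            out.append(")" * depth)
            del stack[len(stack) - depth:]
        else:  # bond tokens pass through
            out.append(t.text)
    if open_rings:
        raise DeepSmilesError(f"unclosed ring digits {sorted(open_rings)}")
    return "".join(out)


class _Node:
    __slots__ = ("text", "bond", "children", "rings")

    def __init__(self, text: str, bond: str):
        self.text = text
        self.bond = bond          # bond token preceding this atom ('' = default)
        self.children: list["_Node"] = []
        self.rings: list[tuple[int, str]] = []  # (ring mark, bond at this end)


def from_deepsmiles(deep: str) -> str:
    """Convert a DeepSMILES line back to SMILES.

    Raises :class:`DeepSmilesError` on syntactic impossibilities (a ring
    digit reaching past the current path, an unmatched ``)``).  The result
    may still be chemically invalid; validity is the adapter's verdict.
    """
    tokens = tokenize_atomwise(deep, "DEEPSMILES")
    stack: list[_Node] = []
    root: _Node | None = None
    pending_bond = ""
    ring_marks = 0
    for t in tokens:
        if t.kind is Kind.ATOM:
            node = _Node(t.text, pending_bond)
            pending_bond = ""
            if stack:
                stack[-1].children.append(node)
            elif root is None:
                root = node
            else:
                raise DeepSmilesError("atom after the path was fully closed")
            stack.append(node)
        elif t.kind is Kind.BOND:
            if pending_bond:
                raise DeepSmilesError("two consecutive bond tokens")
            pending_bond = t.text
        elif t.kind is Kind.RING:
            span = int(t.text.lstrip("%"))
            if span < 2 or span > len(stack):
                raise DeepSmilesError(
                    f"ring digit {span} does not fit the current path")
            ring_marks += 1
            bond = pending_bond
            pending_bond = ""
            stack[-span].rings.append((ring_marks, ""))
            stack[-1].rings.append((ring_marks, bond))
        elif t.text == ")":
            if len(stack) <= 1:
                raise DeepSmilesError("unmatched ')'")
            stack.pop()
        else:
            raise DeepSmilesError(f"unexpected token {t.text!r}")
    if root is None:
        return ""

    def serialize(node: _Node) -> str:
        s = node.bond + node.text
        for mark, bond in node.rings:
            s += bond + _digit_text(mark)
        kids = node.children
        for k in kids[:-1]:
            s += "(" + serialize(k) + ")"
        if kids:
            s += serialize(kids[-1])
        return s

    return serialize(root)
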