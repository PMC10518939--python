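"""The canvas: a partially specified token sequence rewritten by actions.

Generation starts from a canvas holding a single blank between FIRST/LAST
sentinels and repeatedly applies one of four rewriting actions to a blank:

* ``E``    — replace the blank with token E;
* ``_E``   — replace with E and open a new blank on its left;
* ``E_``   — replace with E and open a new blank on its right;
* ``_E_``  — replace with E and open new blanks on both sides.

Blanks display as ``$k`` and are renumbered left-to-right after every
action.  Canvases are immutable values: ``apply_action`` returns a new
canvas and never mutates its input.

Training canvases are built from a token sequence ``x``, a fill-order
permutation ``sigma`` and a prefix length ``t``: the first ``t`` positions
of the order are kept, every maximal run of missing positions collapses to
one blank, and each remaining position yields one target action against
that same canvas.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .chemstrings import FIRST, LAST, Kind, Token


@dataclass(frozen=True)
class Blank:
    """An unfilled region of the canvas, displayed as ``$id``.

    ``initial`` marks the whole-sequence blank of a fresh canvas (the
    BLANK_0 token); blanks opened by rewriting actions use BLANK.
    """
    id: int
    initial: bool = False


Cell = Token | Blank

ACTION_KINDS = {(False, False): "E", (True, False): "_E",
                (False, True): "E_", (True, True): "_E_"}
KIND_FLAGS = {v: k for k, v in ACTION_KINDS.items()}


@dataclass(frozen=True)
class Action:
    """Fill blank ``blank_id`` with ``token``; ``left``/``right`` open blanks."""
    blank_id: int
    token: Token
    left: bool = False
    right: bool = False

    @property
    def kind(self) -> str:
        return ACTION_KINDS[(self.left, self.right)]

    @classmethod
    def from_kind(cls, blank_id: int, token: Token, kind: str) -> "Action":
        left, right = KIND_FLAGS[kind]
        return cls(blank_id, token, left, right)


class Canvas:
    """Immutable sequence of filled tokens and numbered blanks.

    Cells are framed by FIRST/LAST sentinel tokens which are never blanks
    and never rewritten.
    """

    __slots__ = ("cells", "step")

    def __init__(self, cells: Sequence[Cell], step: int = 0):
        cells = tuple(cells)
        if len(cells) < 2 or cells[0] != FIRST or cells[-1] != LAST:
            raise ValueError("canvas cells must be framed by FIRST/LAST")
        self.cells = tuple(self._renumber(cells))
        self.step = step

    @staticmethod
    def _renumber(cells: Sequence[Cell]) -> list[Cell]:
        out: list[Cell] = []
        k = 0
        for c in cells:
            if isinstance(c, Blank):
                k += 1
                out.append(Blank(k, c.initial) if c.id != k else c)
            else:
                out.append(c)
        return out

    # -- queries --------------------------------------------------------------
    @property
    def inner(self) -> tuple[Cell, ...]:
        return self.cells[1:-1]

    def blanks(self) -> list[tuple[int, Blank]]:
        """(cell index, blank) pairs, left to right."""
        return [(i, c) for i, c in enumerate(self.cells) if isinstance(c, Blank)]

    @property
    def n_blanks(self) -> int:
        return sum(1 for c in self.cells if isinstance(c, Blank))

    def blank_position(self, blank_id: int) -> int:
        for i, c in enumerate(self.cells):
            if isinstance(c, Blank) and c.id == blank_id:
                return i
        raise KeyError(f"no blank ${blank_id} on canvas {self.to_text()!r}")

    def tokens(self) -> list[Token]:
        """Filled tokens between the sentinels (errors if blanks remain)."""
        if self.n_blanks:
            raise ValueError("canvas still has blanks")
        return [c for c in self.inner if isinstance(c, Token)]

    def to_text(self) -> str:
        """Space-separated display form, blanks as ``$k`` (no sentinels)."""
        parts = []
        for c in self.inner:
            parts.append(f"${c.id}" if isinstance(c, Blank) else c.text)
        return " ".join(parts)

    def __eq__(self, other) -> bool:
        return isinstance(other, Canvas) and self.cells == other.cells

    def __hash__(self) -> int:
        return hash(self.cells)

    def __repr__(self) -> str:
        return f"Canvas({self.to_text()!r}, step={self.step})"


def init_canvas() -> Canvas:
    """A canvas holding only the initial whole-sequence blank."""
    return Canvas([FIRST, Blank(1, initial=True), LAST], step=0)


def is_complete(canvas: Canvas) -> bool:
    """True iff no blank remains on the canvas."""
    return canvas.n_blanks == 0


def apply_action(canvas: Canvas, action: Action) -> Canvas:
    """Apply one rewriting action, returning a new canvas.

    The named blank is replaced by ``[new blank] token [new blank]``
    according to the action's left/right flags; all other cells are
    unchanged and the step counter increments.
    """
    if action.token.kind is Kind.SPECIAL:
        raise ValueError(f"cannot write special token {action.token.text!r}")
    pos = canvas.blank_position(action.blank_id)
    middle: list[Cell] = []
    if action.left:
        middle.append(Blank(0))
    middle.append(action.token)
    if action.right:
        middle.append(Blank(0))
    cells = list(canvas.cells[:pos]) + middle + list(canvas.cells[pos + 1:])
    return Canvas(cells, step=canvas.step + 1)


def replay(initial: Canvas, actions: Sequence[Action]) -> Canvas:
    """Apply actions in order; raises if any blank id is missing."""
    c = initial
    for a in actions:
        c = apply_action(c, a)
    return c


@dataclass(frozen=True)
class Trajectory:
    """An initial canvas and the ordered actions applied to it."""
    initial: Canvas
    actions: tuple[Action, ...]

    def replay(self) -> Canvas:
        return replay(self.initial, self.actions)

    def __len__(self) -> int:
        return len(self.actions)


@dataclass(frozen=True)
class TrainingTarget:
    """A training canvas plus one target action per remaining token."""
    canvas: Canvas
    targets: tuple[Action, ...]


def _check_sigma(sigma: Sequence[int], n: int) -> None:
    if sorted(sigma) != list(range(1, n + 1)):
        raise ValueError(f"sigma {sigma!r} is not a permutation of 1..{n}")


def make_training_canvas(x: Sequence[Token], sigma: Sequence[int],
                         t: int) -> TrainingTarget:
    """Build the step-``t`` canvas and its target actions for (x, sigma).

    Positions ``sigma_1..sigma_t`` (1-based) are kept in original order;
    each maximal run of missing positions collapses to one blank.  For each
    remaining position ``p = sigma_j`` (j > t) the target fills ``x_p`` into
    the blank covering ``p``, opening a left (right) blank iff some other
    missing position lies before (after) ``p`` inside the same run.  All
    targets are expressed against this same canvas.
    """
    n = len(x)
    _check_sigma(sigma, n)
    if not 0 <= t <= n - 1:
        raise ValueError(f"t={t} out of range for n={n}")
    kept = set(sigma[:t])
    cells: list[Cell] = [FIRST]
    covering: dict[int, int] = {}   # original position -> blank id
    run_span: dict[int, list[int]] = {}  # blank id -> missing positions
    blank_id = 0
    run: list[int] = []

    def flush_run():
        nonlocal blank_id, run
        if run:
            blank_id += 1
            cells.append(Blank(blank_id, initial=(t == 0)))
            for q in run:
                covering[q] = blank_id
            run_span[blank_id] = run
            run = []

    for p in range(1, n + 1):
        if p in kept:
            flush_run()
            cells.append(x[p - 1])
        else:
            run.append(p)
    flush_run()
    cells.append(LAST)
    canvas = Canvas(cells, step=t)
    targets = []
    for j in range(t, n):
        pos = sigma[j]
        b = covering[pos]
        run = run_span[b]
        left = any(q < pos for q in run if q != pos)
        right = any(q > pos for q in run if q != pos)
        targets.append(Action(b, x[pos - 1], left, right))
    assert len(targets) == n - t
    return TrainingTarget(canvas=canvas, targets=tuple(targets))


def replay_training_targets(x: Sequence[Token], sigma: Sequence[int],
                            t: int) -> Canvas:
    """Fill positions ``sigma_{t+1}..sigma_n`` one by one and return the result.

    At each step the action for the next position is derived against the
    *current* canvas (blank ids shift as blanks split), then applied with
    :func:`apply_action`.  Replaying all targets from any (sigma, t) must
    reconstruct ``x`` exactly.
    """
    n = len(x)
    canvas = make_training_canvas(x, sigma, t).canvas
    # spans[i] = missing original positions covered by the i-th blank (L->R)
    kept = set(sigma[:t])
    spans: list[list[int]] = []
    run: list[int] = []
    for p in range(1, n + 1):
        if p in kept:
            if run:
                spans.append(run)
                run = []
        else:
            run.append(p)
    if run:
        spans.append(run)
    for j in range(t, n):
        p = sigma[j]
        bi = next(i for i, sp in enumerate(spans) if p in sp)
        sp = spans[bi]
        left_part = [q for q in sp if q < p]
        right_part = [q for q in sp if q > p]
        blank_id = bi + 1  # display ids are left-to-right
        action = Action(blank_id, x[p - 1], bool(left_part), bool(right_part))
        canvas = apply_action(canvas, action)
        new_spans = []
        if left_part:
            new_spans.append(left_part)
        if right_part:
            new_spans.append(right_part)
        spans[bi:bi + 1] = new_spans
    return canvas


def make_template(tokens: Sequence[Token], masked: set[int]) -> Canvas:
    """Canvas from a token list with 0-based ``masked`` positions blanked.

    Each maximal masked run becomes one blank; unmasked tokens are kept in
    order.  Masking everything reproduces :func:`init_canvas`.
    """
    tokens = list(tokens)
    if not tokens:
        raise ValueError("cannot build a template from an empty token list")
    for i in masked:
        if not 0 <= i < len(tokens):
            raise IndexError(f"masked position {i} out of range")
    all_masked = len(masked) == len(tokens)
    cells: list[Cell] = [FIRST]
    i = 0
    while i < len(tokens):
        if i in masked:
            while i < len(tokens) and i in masked:
                i += 1
            cells.append(Blank(0, initial=all_masked))
        else:
            cells.append(tokens[i])
            i += 1
    cells.append(LAST)
    return Canvas(cells, step=0)


def parse_template(text: str, representation: str = "SMILES",
                   mask_marker: str = "<mask>") -> Canvas:
    """Parse a space-separated template string with ``<mask>`` markers."""
    from .chemstrings import tokenize_atomwise

    parts = text.split()
    if not parts:
        raise ValueError("empty template")
    cells: list[Cell] = [FIRST]
    masked_prev = False
    n_tokens = 0
    for part in parts:
        if part == mask_marker or part.startswith("$"):
            if not masked_prev:
                cells.append(Blank(0))
            masked_prev = True
        else:
            toks = tokenize_atomwise(part, representation)
            if len(toks) != 1:
                raise ValueError(f"template part {part!r} is not one token")
            cells.append(toks[0])
            masked_prev = False
            n_tokens += 1
    cells.append(LAST)
    if n_tokens == 0 and sum(isinstance(c, Blank) for c in cells) == 1:
        cells = [FIRST, Blank(1, initial=True), LAST]
    return Canvas(cells, step=0)
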