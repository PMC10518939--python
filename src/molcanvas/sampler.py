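"""Sampling: de novo generation, template infilling, tinkering suggestions.

Generation starts from the single-blank canvas and repeatedly samples
(blank, token, left/right blank creation) from the temperature-scaled
three-stage action distribution until the canvas is blank-free or the
action cap is reached.  Every result carries its full rewriting
trajectory — the interpretability record: replaying the trajectory with
``canvas.apply_action`` reproduces the returned string exactly.

Tinkering design (`suggest_substitutions`) takes a masked template,
selects the blank with the highest location probability and returns the
token/action pairs ranked by probability, the machine-readable form of a
substitution table.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .blm import (CREATION_ORDER, ModelState, _gelu_np, _softmax,
                  _special_mask, action_distribution, canvas_ids,
                  encode_ids)
from .autodiff import no_grad
from .canvas import Action, Blank, Canvas, Trajectory, apply_action, \
    init_canvas, is_complete
from .chemstrings import Token, detokenize


@dataclass
class GenerationConfig:
    """Sampling knobs: 'sample' draws from the (temperature-scaled)
    distribution, 'greedy' takes the stage-wise argmax."""
    mode: str = "sample"
    temperature: float = 1.0
    max_actions: int = 100
    seed: int = 0

    def __post_init__(self):
        if self.mode not in ("sample", "greedy"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.max_actions < 1:
            raise ValueError("max_actions must be >= 1")


@dataclass
class GenerationResult:
    """A finished (or capped) generation with its rewriting trajectory."""
    text: str | None
    trajectory: Trajectory
    complete: bool
    canvas: Canvas


@dataclass
class SuggestionRow:
    """One ranked substitution: token, action kind and its probability."""
    token: Token
    action_kind: str
    probability: float


# ---------------------------------------------------------------------------
# Batched sampling core
# ---------------------------------------------------------------------------

def _choose(rng: np.random.Generator, probs: np.ndarray, greedy: bool) -> int:
    if greedy:
        return int(np.argmax(probs))
    p = probs / probs.sum()
    return int(rng.choice(len(p), p=p))


def _step_batch(canvases: list[Canvas], state: ModelState,
                rng: np.random.Generator, config: GenerationConfig
                ) -> list[Action]:
    """Sample one action for each (incomplete) canvas in a padded batch."""
    p, vocab = state.params, state.vocab
    T = config.temperature
    greedy = config.mode == "greedy"
    id_lists = [canvas_ids(c, vocab) for c in canvases]
    L = max(len(l) for l in id_lists)
    pad = vocab.id("PAD")
    B = len(canvases)
    ids = np.full((B, L), pad, dtype=int)
    valid = np.zeros((B, L), dtype=bool)
    for i, lst in enumerate(id_lists):
        ids[i, :len(lst)] = lst
        valid[i, :len(lst)] = True
    with no_grad():
        reps = encode_ids(ids, valid, state).data  # (B, L, d)
    smask = _special_mask(vocab)
    ins = np.array(vocab.insertable_ids)
    emb = p["emb"].data
    actions: list[Action] = []
    for i, canvas in enumerate(canvases):
        pb = [j for j, c in enumerate(canvas.cells) if isinstance(c, Blank)]
        bids = [c.id for c in canvas.cells if isinstance(c, Blank)]
        rb = reps[i, pb]
        loc = _softmax(((rb @ p["loc_w"].data).ravel() + p["loc_b"].data) / T)
        bsel = _choose(rng, loc, greedy)
        tok_logits = rb[bsel] @ p["tok_w"].data + p["tok_b"].data + smask
        tok = _softmax(tok_logits / T)
        v = _choose(rng, tok, greedy)
        cat = np.concatenate([rb[bsel], emb[v]])
        h1 = _gelu_np(cat @ p["cre_w1"].data + p["cre_b1"].data)
        cre = _softmax((h1 @ p["cre_w2"].data + p["cre_b2"].data) / T)
        lr = CREATION_ORDER[_choose(rng, cre, greedy)]
        actions.append(Action(bids[bsel], vocab.token(v), lr[0], lr[1]))
    return actions


def _run(initials: list[Canvas], state: ModelState, config: GenerationConfig,
         rng: np.random.Generator) -> list[GenerationResult]:
    """Drive a list of canvases to completion (or the action cap)."""
    max_cells = state.config.max_len
    n = len(initials)
    canvases = list(initials)
    actions: list[list[Action]] = [[] for _ in range(n)]
    active = [i for i in range(n) if not is_complete(canvases[i])]
    steps = 0
    while active and steps < config.max_actions:
        batch = [canvases[i] for i in active]
        acts = _step_batch(batch, state, rng, config)
        still = []
        for i, a in zip(active, acts):
            c = apply_action(canvases[i], a)
            canvases[i] = c
            actions[i].append(a)
            if not is_complete(c) and len(c.cells) + 2 <= max_cells:
                still.append(i)
        active = still
        steps += 1
    out = []
    for i in range(n):
        c = canvases[i]
        complete = is_complete(c)
        text = detokenize(c.tokens()) if complete else None
        out.append(GenerationResult(
            text=text, trajectory=Trajectory(initials[i], tuple(actions[i])),
            complete=complete, canvas=c))
    return out


# ---------------------------------------------------------------------------
# Public operations
# ---------------------------------------------------------------------------

def generate(state: ModelState, config: GenerationConfig) -> GenerationResult:
    """One de novo molecule from the single-blank canvas."""
    rng = np.random.default_rng(config.seed)
    return _run([init_canvas()], state, config, rng)[0]


def generate_batch(state: ModelState, n: int, config: GenerationConfig,
                   chunk: int = 256) -> list[GenerationResult]:
    """``n`` draws under one seeded stream; order-stable for a fixed seed."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(config.seed)
    out: list[GenerationResult] = []
    for lo in range(0, n, chunk):
        m = min(chunk, n - lo)
        out.extend(_run([init_canvas() for _ in range(m)],
                        state, config, rng))
    return out


def infill(template: Canvas, state: ModelState, config: GenerationConfig,
           n: int = 1) -> list[GenerationResult]:
    """Complete only the blanks of ``template``; unmasked tokens are kept.

    A blank-free template is returned unchanged; a fully masked template
    reduces to de novo generation.
    """
    rng = np.random.default_rng(config.seed)
    out: list[GenerationResult] = []
    for lo in range(0, n, 256):
        m = min(256, n - lo)
        out.extend(_run([template for _ in range(m)], state, config, rng))
    return out


def suggest_substitutions(template: Canvas, state: ModelState,
                          top_k: int = 10,
                          blank_id: int | None = None) -> list[SuggestionRow]:
    """Ranked (token, action) substitutions for one blank of a template.

    By default the blank with the highest location probability is analyzed
    (templates in tinkering design usually mask a single site).  The
    probabilities enumerate the joint token x action-kind distribution at
    that blank and sum to 1.
    """
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    if template.n_blanks == 0:
        raise ValueError("template has no blanks to fill")
    dist = action_distribution(template, state)
    if blank_id is None:
        b = int(np.argmax(dist.location))
    else:
        b = dist.blank_ids.index(blank_id)
    joint = dist.token[b][:, None] * dist.creation[b]   # (V, 4)
    rows: list[SuggestionRow] = []
    for v in state.vocab.insertable_ids:
        for k, lr in enumerate(CREATION_ORDER):
            rows.append(SuggestionRow(
                token=state.vocab.token(v),
                action_kind=("E", "_E", "E_", "_E_")[k],
                probability=float(joint[v, k])))
    rows.sort(key=lambda r: -r.probability)
    return rows[:top_k]


def format_suggestions(rows: Sequence[SuggestionRow]) -> str:
    """Plain-text substitution table (token, probability, action)."""
    lines = [f"{'Substitution token':<20}{'Probability':<14}{'Action'}"]
    for r in rows:
        lines.append(f"{r.token.text:<20}{r.probability:<14.4f}{r.action_kind}")
    return "\n".join(lines)
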