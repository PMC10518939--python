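"""The blank language model: a transformer encoder with three output heads.

The model factorizes the probability of a rewriting action on a canvas in
three stages (one forward pass of the shared encoder):

1. *location* — which blank to fill, a linear+softmax over the encoder
   representations of the current blanks;
2. *token* — which vocabulary token to write there, a linear+softmax over
   the non-special vocabulary;
3. *creation* — whether to open new blanks on the left and/or right, a
   two-layer perceptron on the concatenation of the selected blank's
   representation and the chosen token's embedding, softmax over the four
   combinations (E, _E, E_, _E_).

Training minimizes, for a sequence ``x`` of length ``n``, a uniformly
sampled prefix length ``t`` and fill order ``sigma``, the estimator

    -log(n!) - n/(n-t) * sum over the n-t remaining positions of
                         log p(target action | canvas c_t; theta),

where every target action is evaluated against the same canvas ``c_t``.
The ``-log(n!)`` term is a theta-free constant; it is included in reported
loss values but contributes no gradient.
"""

from __future__ import annotations

import copy
import json
import math
from dataclasses import asdict, dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.special import gammaln

from .autodiff import Adam, Tensor, linear, no_grad
from .canvas import Action, Blank, Canvas, make_training_canvas
from .chemstrings import Kind, Token, Vocabulary, build_vocabulary, \
    tokenize_atomwise

# creation-head output order: E, _E, E_, _E_
CREATION_ORDER: tuple[tuple[bool, bool], ...] = (
    (False, False), (True, False), (False, True), (True, True))
_LR_INDEX = {lr: i for i, lr in enumerate(CREATION_ORDER)}

_NEG = -1e30


@dataclass
class ModelConfig:
    """Architecture and optimization knobs.

    Six layers / width 256 are the model defaults; desk-scale runs use the
    2-layer width-128 configuration from :func:`molcanvas.workbench.desk_config`.
    """
    n_layers: int = 6
    d_model: int = 256
    n_heads: int = 8
    d_ff: int | None = None
    max_len: int = 160
    learning_rate: float = 1e-3
    batch_size: int = 32
    n_epochs: int = 10
    n_orders: int = 1       # (sigma, t) Monte-Carlo draws per example per step
    lr_schedule: str = "constant"   # or "cosine" (decay to lr/10 by the end)
    grad_clip: float = 1.0  # global gradient-norm cap (0 disables)
    max_actions: int = 100
    seed: int = 0

    def __post_init__(self):
        if self.d_ff is None:
            self.d_ff = 2 * self.d_model
        if self.d_model % self.n_heads:
            raise ValueError("d_model must be divisible by n_heads")


@dataclass
class ModelState:
    """Parameters theta plus the vocabulary and config they were built for."""
    params: dict[str, Tensor]
    vocab: Vocabulary
    config: ModelConfig

    def clone(self) -> "ModelState":
        params = {k: Tensor(p.data.copy(), requires_grad=p.requires_grad)
                  for k, p in self.params.items()}
        return ModelState(params, self.vocab, copy.deepcopy(self.config))


def init_params(vocab: Vocabulary, config: ModelConfig,
                rng: np.random.Generator | None = None) -> ModelState:
    """Seeded parameter initialization (N(0, 0.02) weights, zero biases)."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    d, ff, V = config.d_model, config.d_ff, len(vocab)

    def w(*shape):
        return Tensor(rng.normal(0.0, 0.02, size=shape), requires_grad=True)

    def zeros(*shape):
        return Tensor(np.zeros(shape), requires_grad=True)

    def ones(*shape):
        return Tensor(np.ones(shape), requires_grad=True)

    p: dict[str, Tensor] = {
        "emb": w(V, d), "pos": w(config.max_len, d),
        "lnf_g": ones(d), "lnf_b": zeros(d),
        "loc_w": w(d, 1), "loc_b": zeros(1),
        "tok_w": w(d, V), "tok_b": zeros(V),
        "cre_w1": w(2 * d, d), "cre_b1": zeros(d),
        "cre_w2": w(d, 4), "cre_b2": zeros(4),
    }
    for i in range(config.n_layers):
        p[f"l{i}.ln1_g"], p[f"l{i}.ln1_b"] = ones(d), zeros(d)
        p[f"l{i}.ln2_g"], p[f"l{i}.ln2_b"] = ones(d), zeros(d)
        for name in ("wq", "wk", "wv", "wo"):
            p[f"l{i}.{name}"] = w(d, d)
        p[f"l{i}.ff1"], p[f"l{i}.ff1_b"] = w(d, ff), zeros(ff)
        p[f"l{i}.ff2"], p[f"l{i}.ff2_b"] = w(ff, d), zeros(d)
    return ModelState(params=p, vocab=vocab, config=config)


# ---------------------------------------------------------------------------
# Encoder
# ---------------------------------------------------------------------------

def canvas_ids(canvas: Canvas, vocab: Vocabulary) -> list[int]:
    """Map canvas cells (sentinels, tokens, blanks) to vocabulary ids."""
    ids = []
    for c in canvas.cells:
        if isinstance(c, Blank):
            ids.append(vocab.id("BLANK_0" if c.initial else "BLANK"))
        else:
            try:
                ids.append(vocab.id(c.text))
            except KeyError:
                raise ValueError(
                    f"canvas token {c.text!r} outside the vocabulary") from None
    return ids


def encode_ids(ids: np.ndarray, valid: np.ndarray, state: ModelState) -> Tensor:
    """Transformer forward pass on padded id matrix ``ids`` (B, L).

    ``valid`` marks real cells; padded key positions are masked out of the
    attention softmax.  Returns per-cell representations (B, L, d).
    """
    p, cfg = state.params, state.config
    B, L = ids.shape
    if L > cfg.max_len:
        raise ValueError(f"canvas length {L} exceeds max_len {cfg.max_len}")
    d, h = cfg.d_model, cfg.n_heads
    dh = d // h
    x = p["emb"][ids] + p["pos"][:L]
    bias = np.where(valid[:, None, None, :], 0.0, _NEG)  # (B,1,1,L)
    scale = 1.0 / math.sqrt(dh)
    for i in range(cfg.n_layers):
        hx = x.layer_norm(p[f"l{i}.ln1_g"], p[f"l{i}.ln1_b"])

        def split(t: Tensor) -> Tensor:
            return t.reshape(B, L, h, dh).swapaxes(1, 2)

        q = split(hx @ p[f"l{i}.wq"])
        k = split(hx @ p[f"l{i}.wk"])
        v = split(hx @ p[f"l{i}.wv"])
        scores = (q @ k.swapaxes(-1, -2)) * scale + Tensor(bias)
        att = scores.softmax(axis=-1)
        out = (att @ v).swapaxes(1, 2).reshape(B, L, d)
        x = x + out @ p[f"l{i}.wo"]
        hx2 = x.layer_norm(p[f"l{i}.ln2_g"], p[f"l{i}.ln2_b"])
        ff = linear(linear(hx2, p[f"l{i}.ff1"], p[f"l{i}.ff1_b"]).gelu(),
                    p[f"l{i}.ff2"], p[f"l{i}.ff2_b"])
        x = x + ff
    return x.layer_norm(p["lnf_g"], p["lnf_b"])


def encode(canvas: Canvas, state: ModelState) -> np.ndarray:
    """Per-cell representation vectors for one canvas (inference mode)."""
    ids = np.array([canvas_ids(canvas, state.vocab)])
    valid = np.ones_like(ids, dtype=bool)
    with no_grad():
        return encode_ids(ids, valid, state).data[0]


def _special_mask(vocab: Vocabulary) -> np.ndarray:
    """Additive mask putting -inf on special-token logits."""
    m = np.zeros(len(vocab))
    for i, t in enumerate(vocab.tokens):
        if t.kind is Kind.SPECIAL:
            m[i] = _NEG
    return m


# ---------------------------------------------------------------------------
# Action distribution and log-probabilities
# ---------------------------------------------------------------------------

@dataclass
class ActionDistribution:
    """The three-stage distribution over actions on one canvas.

    ``location`` is over the current blanks (left-to-right, blank id k at
    index k-1); ``token[b]`` is a full-vocabulary distribution (zero on
    special tokens) conditioned on blank b; ``creation[b, v]`` is over the
    four blank-creation combinations in the order E, _E, E_, _E_.
    """
    blank_ids: list[int]
    location: np.ndarray            # (nb,)
    token: np.ndarray               # (nb, V)
    creation: np.ndarray            # (nb, V, 4)
    vocab: Vocabulary

    def joint(self, blank_id: int, token_text: str,
              left: bool, right: bool) -> float:
        b = self.blank_ids.index(blank_id)
        v = self.vocab.id(token_text)
        return float(self.location[b] * self.token[b, v]
                     * self.creation[b, v, _LR_INDEX[(left, right)]])

    def joint_table(self) -> np.ndarray:
        """(nb, V, 4) array of joint probabilities; sums to 1."""
        return (self.location[:, None, None] * self.token[:, :, None]
                * self.creation)


def action_distribution(canvas: Canvas, state: ModelState,
                        temperature: float = 1.0) -> ActionDistribution:
    """Full three-stage action distribution for a canvas with >=1 blank."""
    if canvas.n_blanks == 0:
        raise ValueError("canvas has no blanks; no action is applicable")
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    p, vocab = state.params, state.vocab
    reps = encode(canvas, state)  # (L, d)
    pb = [i for i, c in enumerate(canvas.cells) if isinstance(c, Blank)]
    blank_ids = [c.id for c in canvas.cells if isinstance(c, Blank)]
    rb = reps[pb]  # (nb, d)
    loc_logits = (rb @ p["loc_w"].data).ravel() + p["loc_b"].data
    loc = _softmax(loc_logits / temperature)
    tok_logits = rb @ p["tok_w"].data + p["tok_b"].data + _special_mask(vocab)
    tok = _softmax(tok_logits / temperature, axis=-1)
    V, d = len(vocab), state.config.d_model
    emb = p["emb"].data
    cre = np.zeros((len(pb), V, 4))
    ins = vocab.insertable_ids
    for b in range(len(pb)):
        cat = np.concatenate(
            [np.repeat(rb[b][None, :], len(ins), axis=0), emb[ins]], axis=1)
        h1 = _gelu_np(cat @ p["cre_w1"].data + p["cre_b1"].data)
        logits = h1 @ p["cre_w2"].data + p["cre_b2"].data
        cre[b, ins] = _softmax(logits / temperature, axis=-1)
    return ActionDistribution(blank_ids=blank_ids, location=loc,
                              token=tok, creation=cre, vocab=vocab)


def _softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    z = x - x.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def _gelu_np(x: np.ndarray) -> np.ndarray:
    from scipy.special import erf
    return x * 0.5 * (1.0 + erf(x / np.sqrt(2.0)))


def action_log_prob(canvas: Canvas, action: Action, state: ModelState) -> float:
    """log p(action | canvas; theta) = log p_loc + log p_tok + log p_creation."""
    dist = action_distribution(canvas, state)
    if action.blank_id not in dist.blank_ids:
        raise ValueError(f"no blank ${action.blank_id} on this canvas")
    if action.token.kind is Kind.SPECIAL:
        raise ValueError("special tokens cannot be written")
    pr = dist.joint(action.blank_id, action.token.text,
                    action.left, action.right)
    return float(np.log(pr))


# ---------------------------------------------------------------------------
# Loss (graph-building path shared by train())
# ---------------------------------------------------------------------------

@dataclass
class LossEstimate:
    value: float
    n: int
    t: int
    sigma: tuple[int, ...]


def _example_loss_graph(reps_i: Tensor, canvas: Canvas,
                        targets: Sequence[Action], n: int, t: int,
                        state: ModelState) -> Tensor:
    """Eq-style loss for one training canvas, as an autodiff scalar."""
    p, vocab = state.params, state.vocab
    pb = [i for i, c in enumerate(canvas.cells) if isinstance(c, Blank)]
    id_to_row = {c.id: r for r, c in
                 enumerate(c for c in canvas.cells if isinstance(c, Blank))}
    rb = reps_i[np.array(pb)]                       # (nb, d)
    loc_logp = (rb @ p["loc_w"] + p["loc_b"]).reshape(len(pb)).log_softmax()
    rows = np.array([id_to_row[a.blank_id] for a in targets])
    tok_ids = np.array([vocab.id(a.token.text) for a in targets])
    lr_idx = np.array([_LR_INDEX[(a.left, a.right)] for a in targets])
    m = len(targets)
    rsel = rb[rows]                                 # (m, d)
    tok_logits = rsel @ p["tok_w"] + p["tok_b"] + Tensor(_special_mask(vocab))
    tok_logp = tok_logits.log_softmax(axis=-1)
    cat = Tensor.concat([rsel, p["emb"][tok_ids]], axis=-1)
    h1 = linear(cat, p["cre_w1"], p["cre_b1"]).gelu()
    cre_logp = linear(h1, p["cre_w2"], p["cre_b2"]).log_softmax(axis=-1)
    ar = np.arange(m)
    total = (loc_logp[rows].sum() + tok_logp[ar, tok_ids].sum()
             + cre_logp[ar, lr_idx].sum())
    scale = n / (n - t)
    return total * (-scale) + Tensor(-gammaln(n + 1))


def loss(x: Sequence[Token], sigma: Sequence[int], t: int,
         state: ModelState, build_graph: bool = False
         ) -> LossEstimate | tuple[LossEstimate, Tensor]:
    """The training-objective estimate for one (x, sigma, t) triple."""
    n = len(x)
    if t >= n:
        raise ValueError("t must be < n (at least one token must remain)")
    tt = make_training_canvas(x, sigma, t)
    ids = np.array([canvas_ids(tt.canvas, state.vocab)])
    valid = np.ones_like(ids, dtype=bool)

    def compute() -> Tensor:
        reps = encode_ids(ids, valid, state)
        return _example_loss_graph(reps[0], tt.canvas, tt.targets, n, t, state)

    if build_graph:
        val = compute()
        est = LossEstimate(float(val.data), n, t, tuple(sigma))
        return est, val
    with no_grad():
        val = compute()
    return LossEstimate(float(val.data), n, t, tuple(sigma))


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def _draw_example(rng: np.random.Generator, x: Sequence[Token]
                  ) -> tuple[Sequence[Token], list[int], int]:
    n = len(x)
    t = int(rng.integers(0, n))
    sigma = list(rng.permutation(n) + 1)
    return x, sigma, t


def batch_loss(examples: Sequence[tuple[Sequence[Token], Sequence[int], int]],
               state: ModelState) -> Tensor:
    """Mean loss over a minibatch of (x, sigma, t) triples (one padded pass)."""
    vocab = state.vocab
    tts = [make_training_canvas(x, sigma, t) for x, sigma, t in examples]
    id_lists = [canvas_ids(tt.canvas, vocab) for tt in tts]
    L = max(len(ids) for ids in id_lists)
    pad = vocab.id("PAD")
    B = len(examples)
    ids = np.full((B, L), pad, dtype=int)
    valid = np.zeros((B, L), dtype=bool)
    for i, lst in enumerate(id_lists):
        ids[i, :len(lst)] = lst
        valid[i, :len(lst)] = True
    reps = encode_ids(ids, valid, state)
    total: Tensor | None = None
    for i, ((x, sigma, t), tt) in enumerate(zip(examples, tts)):
        li = _example_loss_graph(reps[i], tt.canvas, tt.targets,
                                 len(x), t, state)
        total = li if total is None else total + li
    return total * (1.0 / B)


def train(corpus: Sequence[Sequence[Token]], vocab: Vocabulary,
          config: ModelConfig,
          epoch_callback: Callable[[int, ModelState, float], None] | None = None,
          state: ModelState | None = None) -> ModelState:
    """Stochastic training loop: per example, sample t ~ U{0..n-1} and a
    uniform fill order sigma, compute the loss on the resulting canvas and
    take an Adam step.  Fully seeded; ``epoch_callback(epoch, state, loss)``
    fires after each epoch (e.g. for checkpoints)."""
    corpus = [list(x) for x in corpus]
    if not corpus:
        raise ValueError("empty training corpus")
    for x in corpus:
        for tok in x:
            if tok.text not in vocab:
                raise ValueError(f"corpus token {tok.text!r} not in vocabulary")
        if len(x) == 0:
            raise ValueError("empty sequence in corpus")
    rng = np.random.default_rng(config.seed)
    if state is None:
        state = init_params(vocab, config, rng)
    opt = Adam(state.params, lr=config.learning_rate)
    B = config.batch_size
    steps_per_epoch = max(1, math.ceil(len(corpus) / B))
    total_steps = config.n_epochs * steps_per_epoch
    step = 0
    for epoch in range(1, config.n_epochs + 1):
        order = rng.permutation(len(corpus))
        losses = []
        for lo in range(0, len(corpus), B):
            batch = [corpus[i] for i in order[lo:lo + B]]
            examples = [_draw_example(rng, x) for x in batch
                        for _ in range(config.n_orders)]
            lb = batch_loss(examples, state)
            opt.zero_grad()
            lb.backward()
            if config.grad_clip:
                opt.clip_grad_norm(config.grad_clip)
            if config.lr_schedule == "cosine":
                frac = step / max(1, total_steps - 1)
                opt.lr = config.learning_rate * (
                    0.1 + 0.45 * (1.0 + math.cos(math.pi * frac)))
            opt.step()
            step += 1
            losses.append(float(lb.data))
        if epoch_callback is not None:
            epoch_callback(epoch, state, float(np.mean(losses)))
    return state


# ---------------------------------------------------------------------------
# Checkpoints
# ---------------------------------------------------------------------------

CHECKPOINT_VERSION = "molcanvas-checkpoint-1"


def save_checkpoint(state: ModelState, path, rng_state: dict | None = None
                    ) -> None:
    """Single-archive checkpoint: params, vocabulary, config, RNG state."""
    arrays = {f"param::{k}": p.data for k, p in state.params.items()}
    meta = {
        "version": CHECKPOINT_VERSION,
        "vocab": state.vocab.to_json(),
        "config": asdict(state.config),
        "rng_state": rng_state,
    }
    arrays["meta"] = np.frombuffer(
        json.dumps(meta).encode("utf-8"), dtype=np.uint8)
    np.savez(path, **arrays)


def load_checkpoint(path) -> tuple[ModelState, dict | None]:
    with np.load(path) as npz:
        meta = json.loads(bytes(npz["meta"]).decode("utf-8"))
        if meta.get("version") != CHECKPOINT_VERSION:
            raise ValueError(f"unsupported checkpoint version in {path}")
        params = {k[len("param::"):]: Tensor(npz[k], requires_grad=True)
                  for k in npz.files if k.startswith("param::")}
    vocab = Vocabulary.from_json(meta["vocab"])
    config = ModelConfig(**meta["config"])
    return ModelState(params, vocab, config), meta.get("rng_state")


# ---------------------------------------------------------------------------
# Estimator
# ---------------------------------------------------------------------------

class BlankLanguageModel:
    """Scikit-learn style generative estimator over molecular strings.

    ``fit`` tokenizes a corpus of molecule lines in the chosen
    representation, builds (or accepts) a vocabulary, and trains the
    blank language model; ``sample`` draws new molecules by iterative
    canvas rewriting.  Follows the sklearn estimator protocol
    (``get_params``/``set_params``, fitted attributes with trailing
    underscores) so it composes with sklearn model-selection tooling.
    """

    def __init__(self, n_layers: int = 6, d_model: int = 256,
                 n_heads: int = 8, d_ff: int | None = None,
                 max_len: int = 160, learning_rate: float = 1e-3,
                 batch_size: int = 32, n_epochs: int = 10,
                 n_orders: int = 1, lr_schedule: str = "constant",
                 max_actions: int = 100,
                 representation: str = "SMILES", seed: int = 0):
        self.n_layers = n_layers
        self.d_model = d_model
        self.n_heads = n_heads
        self.d_ff = d_ff
        self.max_len = max_len
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.n_epochs = n_epochs
        self.n_orders = n_orders
        self.lr_schedule = lr_schedule
        self.max_actions = max_actions
        self.representation = representation
        self.seed = seed

    # -- sklearn plumbing ---------------------------------------------------
    _param_names = ("n_layers", "d_model", "n_heads", "d_ff", "max_len",
                    "learning_rate", "batch_size", "n_epochs", "n_orders",
                    "lr_schedule", "max_actions", "representation", "seed")

    def get_params(self, deep: bool = True) -> dict:
        return {k: getattr(self, k) for k in self._param_names}

    def set_params(self, **params) -> "BlankLanguageModel":
        for k, v in params.items():
            if k not in self._param_names:
                raise ValueError(f"invalid parameter {k!r}")
            setattr(self, k, v)
        return self

    def _config(self) -> ModelConfig:
        return ModelConfig(
            n_layers=self.n_layers, d_model=self.d_model,
            n_heads=self.n_heads, d_ff=self.d_ff, max_len=self.max_len,
            learning_rate=self.learning_rate, batch_size=self.batch_size,
            n_epochs=self.n_epochs, n_orders=self.n_orders,
            lr_schedule=self.lr_schedule, max_actions=self.max_actions,
            seed=self.seed)

    # -- estimator API ------------------------------------------------------
    def fit(self, X: Sequence[str], y=None,
            vocabulary: Vocabulary | None = None,
            snapshot_epochs: Sequence[int] = (),
            ) -> "BlankLanguageModel":
        """Train on molecule lines ``X`` (one string per molecule)."""
        X = list(X)
        corpus = [tokenize_atomwise(s, self.representation) for s in X]
        if vocabulary is None:
            vocabulary = build_vocabulary(X, self.representation)
        snap = set(snapshot_epochs)
        self.snapshots_: dict[int, ModelState] = {}
        self.loss_history_: list[float] = []

        def cb(epoch, state, mean_loss):
            self.loss_history_.append(mean_loss)
            if epoch in snap:
                self.snapshots_[epoch] = state.clone()

        self.vocabulary_ = vocabulary
        self.state_ = train(corpus, vocabulary, self._config(),
                            epoch_callback=cb)
        self.n_iter_ = len(self.loss_history_)
        return self

    def _check_fitted(self) -> None:
        if not hasattr(self, "state_"):
            raise RuntimeError("this BlankLanguageModel instance is not "
                               "fitted yet; call fit first")

    def sample(self, n: int, seed: int | None = None, mode: str = "sample",
               temperature: float = 1.0):
        """Draw ``n`` molecules; returns a list of GenerationResult."""
        from .sampler import GenerationConfig, generate_batch
        self._check_fitted()
        cfg = GenerationConfig(
            mode=mode, temperature=temperature,
            max_actions=self.max_actions,
            seed=self.seed if seed is None else seed)
        return generate_batch(self.state_, n, cfg)

    def score(self, X: Sequence[str], y=None, seed: int = 0) -> float:
        """Mean negative loss estimate over ``X`` (higher is better)."""
        self._check_fitted()
        rng = np.random.default_rng(seed)
        vals = []
        for s in X:
            x = tokenize_atomwise(s, self.representation)
            _, sigma, t = _draw_example(rng, x)
            vals.append(-loss(x, sigma, t, self.state_).value)
        return float(np.mean(vals))

    def save(self, path) -> None:
        self._check_fitted()
        save_checkpoint(self.state_, path)

    @classmethod
    def from_checkpoint(cls, path) -> "BlankLanguageModel":
        state, _ = load_checkpoint(path)
        cfg = state.config
        est = cls(n_layers=cfg.n_layers, d_model=cfg.d_model,
                  n_heads=cfg.n_heads, d_ff=cfg.d_ff, max_len=cfg.max_len,
                  learning_rate=cfg.learning_rate, batch_size=cfg.batch_size,
                  n_epochs=cfg.n_epochs, n_orders=cfg.n_orders,
                  max_actions=cfg.max_actions,
                  representation=state.vocab.representation, seed=cfg.seed)
        est.state_ = state
        est.vocabulary_ = state.vocab
        est.loss_history_ = []
        est.snapshots_ = {}
        return est
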