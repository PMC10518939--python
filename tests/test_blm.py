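"""The model: distributions, the fill-order loss, training, checkpoints."""

import math
from itertools import permutations, product

import numpy as np
import pytest
from scipy.special import gammaln

from molcanvas.blm import (BlankLanguageModel, ModelConfig, action_distribution,
                           action_log_prob, batch_loss, encode, init_params,
                           load_checkpoint, loss, save_checkpoint, train)
from molcanvas.canvas import (Action, Blank, Canvas, apply_action, init_canvas,
                              make_template)
from molcanvas.chemstrings import (FIRST, LAST, Kind, Token, build_vocabulary,
                                   tokenize_atomwise)

CO_VOCAB = build_vocabulary(["CO"])   # 2-token vocabulary + 7 specials


def _small_state(vocab, seed=0, **kw):
    cfg = ModelConfig(n_layers=1, d_model=16, n_heads=2, max_len=32,
                      seed=seed, **kw)
    return init_params(vocab, cfg)


def _zero_heads(state):
    for k in ("loc_w", "loc_b", "tok_w", "tok_b", "cre_w2", "cre_b2"):
        state.params[k].data[:] = 0.0
    return state


def _random_canvas(vocab, rng, max_len=10):
    toks = [t for t in vocab.tokens if t.kind is not Kind.SPECIAL]
    cells = [FIRST]
    n_blanks = 0
    for _ in range(int(rng.integers(1, max_len))):
        if rng.random() < 0.4:
            cells.append(Blank(0))
            n_blanks += 1
        else:
            cells.append(toks[rng.integers(len(toks))])
    if n_blanks == 0:
        cells.append(Blank(0))
    cells.append(LAST)
    return Canvas(cells)


class TestEncode:
    def test_deterministic(self, tiny_state):
        c = init_canvas()
        r1 = encode(c, tiny_state)
        r2 = encode(c, tiny_state)
        assert np.array_equal(r1, r2)
        assert r1.shape == (3, tiny_state.config.d_model)

    def test_position_encodings_break_order_symmetry(self, tiny_state):
        a = tokenize_atomwise("CO")
        b = tokenize_atomwise("OC")
        ca = Canvas([FIRST, *a, Blank(0), LAST])
        cb = Canvas([FIRST, *b, Blank(0), LAST])
        assert not np.allclose(encode(ca, tiny_state), encode(cb, tiny_state))

    def test_unknown_token_rejected(self, tiny_state):
        c = Canvas([FIRST, Token("[Xx]", Kind.ATOM), Blank(0), LAST])
        with pytest.raises(ValueError, match="vocabulary"):
            encode(c, tiny_state)


class TestActionDistribution:
    def test_zero_heads_give_uniform_stages(self):
        state = _zero_heads(_small_state(CO_VOCAB))
        c = apply_action(init_canvas(), Action(1, Token("C", Kind.ATOM),
                                               True, True))
        dist = action_distribution(c, state)
        ins = CO_VOCAB.insertable_ids
        assert np.allclose(dist.location, 0.5)
        assert np.allclose(dist.token[:, ins], 1 / len(ins))
        assert np.allclose(dist.creation[:, ins, :], 0.25)

    def test_joint_normalization_random_canvases(self, tiny_state, rng):
        for _ in range(25):
            c = _random_canvas(tiny_state.vocab, rng)
            dist = action_distribution(c, tiny_state)
            assert abs(dist.joint_table().sum() - 1.0) < 1e-6

    def test_blank_free_canvas_rejected(self, tiny_state):
        c = Canvas([FIRST, Token("C", Kind.ATOM), LAST])
        with pytest.raises(ValueError, match="blank"):
            action_distribution(c, tiny_state)


class TestActionLogProb:
    def test_exp_sums_to_one_over_all_applicable_actions(self):
        state = _small_state(CO_VOCAB, seed=3)
        c = Canvas([FIRST, Blank(0), Token("C", Kind.ATOM), Blank(0), LAST])
        total = 0.0
        ins = [CO_VOCAB.token(i) for i in CO_VOCAB.insertable_ids]
        for bid, tok, (l, r) in product(
                (1, 2), ins, [(False, False), (True, False),
                              (False, True), (True, True)]):
            total += math.exp(action_log_prob(c, Action(bid, tok, l, r), state))
        assert total == pytest.approx(1.0, abs=1e-6)

    def test_uniform_heads_closed_form(self):
        state = _zero_heads(_small_state(CO_VOCAB))
        v = len(CO_VOCAB.insertable_ids)
        lp = action_log_prob(init_canvas(),
                             Action(1, Token("C", Kind.ATOM)), state)
        assert lp == pytest.approx(-math.log(4 * v), abs=1e-9)

    def test_log_prob_nonpositive_and_increasing_in_token_logit(self):
        state = _small_state(CO_VOCAB, seed=5)
        a = Action(1, Token("C", Kind.ATOM))
        lp0 = action_log_prob(init_canvas(), a, state)
        assert lp0 <= 0.0
        state.params["tok_b"].data[CO_VOCAB.id("C")] += 0.5
        assert action_log_prob(init_canvas(), a, state) > lp0

    def test_inapplicable_action_rejected(self, tiny_state):
        with pytest.raises(ValueError):
            action_log_prob(init_canvas(), Action(
                3, Token("C", Kind.ATOM)), tiny_state)


def oracle_loss(x_texts, sigma, t, state):
    """Independent route: canvas built by plain list bookkeeping, action
    probabilities read off the full joint enumeration."""
    n = len(x_texts)
    kept = set(sigma[:t])
    cells, runs, run = [FIRST], [], []
    for p in range(1, n + 1):
        if p in kept:
            if run:
                runs.append(run)
                cells.append(Blank(0, initial=(t == 0)))
                run = []
            cells.append(Token(x_texts[p - 1], Kind.ATOM))
        else:
            run.append(p)
    if run:
        runs.append(run)
        cells.append(Blank(0, initial=(t == 0)))
    cells.append(LAST)
    dist = action_distribution(Canvas(cells), state)
    total = 0.0
    for p in sigma[t:]:
        b = next(i for i, r in enumerate(runs) if p in r) + 1
        left = any(q < p for q in runs[b - 1])
        right = any(q > p for q in runs[b - 1])
        total += math.log(dist.joint(b, x_texts[p - 1], left, right))
    return float(-gammaln(n + 1) - (n / (n - t)) * total)


class TestLoss:
    def test_closed_form_single_token_uniform(self):
        state = _zero_heads(_small_state(CO_VOCAB))
        v = len(CO_VOCAB.insertable_ids)
        est = loss(tokenize_atomwise("C"), [1], 0, state)
        assert est.value == pytest.approx(math.log(4 * v), abs=1e-9)
        assert (est.n, est.t) == (1, 0)

    def test_matches_bruteforce_oracle_n2(self):
        state = _small_state(CO_VOCAB, seed=9)
        for s in ("CO", "OC", "CC"):
            x = tokenize_atomwise(s)
            for sigma in permutations((1, 2)):
                for t in (0, 1):
                    mine = loss(x, list(sigma), t, state).value
                    ref = oracle_loss(list(s), list(sigma), t, state)
                    assert mine == pytest.approx(ref, abs=1e-8)

    def test_t_equal_n_rejected(self, tiny_state):
        with pytest.raises(ValueError):
            loss(tokenize_atomwise("CC"), [1, 2], 2, tiny_state)

    def test_batch_loss_is_mean_of_example_losses(self):
        state = _small_state(CO_VOCAB, seed=2)
        examples = [(tokenize_atomwise("CO"), [2, 1], 1),
                    (tokenize_atomwise("OC"), [1, 2], 0)]
        lb = float(batch_loss(examples, state).data)
        singles = [loss(x, s, t, state).value for x, s, t in examples]
        assert lb == pytest.approx(np.mean(singles), abs=1e-8)


class TestTraining:
    def test_seeded_determinism(self):
        corpus = [tokenize_atomwise(s) for s in ("CO", "OC", "CC")]
        cfg = ModelConfig(n_layers=1, d_model=16, n_heads=2, max_len=32,
                          n_epochs=2, batch_size=2, seed=42)
        s1 = train(corpus, CO_VOCAB, cfg)
        s2 = train(corpus, CO_VOCAB, cfg)
        for k in s1.params:
            assert np.array_equal(s1.params[k].data, s2.params[k].data), k

    def test_corpus_vocabulary_mismatch_rejected(self):
        cfg = ModelConfig(n_layers=1, d_model=16, n_heads=2, seed=0)
        with pytest.raises(ValueError, match="vocabulary"):
            train([tokenize_atomwise("CN")], CO_VOCAB, cfg)

    def test_loss_decreases_on_fixture_corpus(self, packaged_corpus):
        mols = packaged_corpus.molecules[:20]
        model = BlankLanguageModel(n_layers=1, d_model=32, n_heads=2,
                                   batch_size=20, n_epochs=50, seed=1)
        model.fit(mols)
        h = model.loss_history_
        assert np.mean(h[-10:]) < np.mean(h[:10])

    def test_overfit_constant_masked_token(self):
        # every training molecule has C in the middle: the single-blank
        # template must recover it with near-certainty
        corpus = ["OCO", "NCN", "OCN", "NCO", "FCF"]
        model = BlankLanguageModel(n_layers=1, d_model=32, n_heads=2,
                                   batch_size=5, n_epochs=400, n_orders=4,
                                   learning_rate=2e-3, seed=0)
        model.fit(corpus)
        for s in corpus:
            toks = tokenize_atomwise(s)
            tpl = make_template(toks, {1})
            dist = action_distribution(tpl, model.state_)
            b = dist.blank_ids.index(1)
            assert dist.token[b, model.vocabulary_.id("C")] >= 0.99


class TestCheckpoints:
    def test_round_trip_preserves_distributions(self, tmp_path, tiny_state):
        path = tmp_path / "model.npz"
        save_checkpoint(tiny_state, path)
        loaded, _ = load_checkpoint(path)
        c = init_canvas()
        d1 = action_distribution(c, tiny_state)
        d2 = action_distribution(c, loaded)
        assert np.array_equal(d1.location, d2.location)
        assert np.array_equal(d1.token, d2.token)
        assert np.array_equal(d1.creation, d2.creation)
        assert loaded.vocab.index == tiny_state.vocab.index

    def test_estimator_save_load(self, tmp_path):
        model = BlankLanguageModel(n_layers=1, d_model=16, n_heads=2,
                                   n_epochs=1, seed=0)
        model.fit(["CO", "OC"])
        path = tmp_path / "est.npz"
        model.save(path)
        again = BlankLanguageModel.from_checkpoint(path)
        assert again.get_params()["d_model"] == 16
        r1 = model.sample(3, seed=5)
        r2 = again.sample(3, seed=5)
        assert [g.text for g in r1] == [g.text for g in r2]


class TestEstimatorProtocol:
    def test_get_set_params_round_trip(self):
        m = BlankLanguageModel()
        params = m.get_params()
        m2 = BlankLanguageModel().set_params(**params)
        assert m2.get_params() == params

    def test_invalid_param_rejected(self):
        with pytest.raises(ValueError):
            BlankLanguageModel().set_params(bogus=1)

    def test_unfitted_sample_raises(self):
        with pytest.raises(RuntimeError, match="not.*fitted"):
            BlankLanguageModel().sample(1)

    def test_sklearn_clone_compatible(self):
        from sklearn.base import clone
        m = BlankLanguageModel(d_model=64)
        assert clone(m).get_params()["d_model"] == 64
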