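"""Canvas calculus: actions, trajectories, training canvases, templates."""

from itertools import permutations

import pytest

from molcanvas.canvas import (Action, Trajectory,
                              apply_action, init_canvas, is_complete,
                              make_template, make_training_canvas,
                              parse_template, replay,
                              replay_training_targets)
from molcanvas.chemstrings import Kind, Token, tokenize_atomwise

# the worked acetone trajectory: (action kind, token) per step
ACETONE_ACTIONS = [("_E_", "C"), ("E", "C"), ("E_", "("), ("_E_", "O"),
                   ("E", "="), ("E_", ")"), ("E", "C")]


def _tok(text):
    return tokenize_atomwise(text)[0] if text not in "()" else \
        Token(text, Kind.BRANCH)


class TestBasics:
    def test_init_canvas(self):
        c = init_canvas()
        assert c.to_text() == "$1"
        assert c.n_blanks == 1 and c.step == 0
        assert not is_complete(c)

    def test_acetone_trajectory_replays_to_final_canvas(self):
        c = init_canvas()
        texts = ["$1"]
        for kind, tok in ACETONE_ACTIONS:
            c = apply_action(c, Action.from_kind(1, _tok(tok), kind))
            texts.append(c.to_text())
        assert is_complete(c)
        assert c.step == 7
        assert c.to_text() == "C C ( = O ) C"
        # the intermediate canvases of the worked example, in order
        assert texts == ["$1", "$1 C $2", "C C $1", "C C ( $1",
                         "C C ( $1 O $2", "C C ( = O $1",
                         "C C ( = O ) $1", "C C ( = O ) C"]

    def test_single_e_action_completes(self):
        c = apply_action(init_canvas(), Action(1, _tok("C")))
        assert is_complete(c) and c.to_text() == "C"

    def test_blank_count_delta_matches_action_kind(self, rng):
        deltas = {"E": -1, "_E": 0, "E_": 0, "_E_": 1}
        c = init_canvas()
        for _ in range(30):
            kinds = list(deltas)
            kind = kinds[rng.integers(len(kinds))]
            if c.n_blanks == 0:
                break
            bid = int(rng.integers(1, c.n_blanks + 1))
            before = c.n_blanks
            c = apply_action(c, Action.from_kind(bid, _tok("C"), kind))
            assert c.n_blanks - before == deltas[kind]

    def test_apply_action_value_semantics(self):
        c = init_canvas()
        cells_before = c.cells
        apply_action(c, Action(1, _tok("C"), True, True))
        assert c.cells == cells_before and c.step == 0

    def test_unknown_blank_rejected(self):
        with pytest.raises(KeyError):
            apply_action(init_canvas(), Action(2, _tok("C")))

    def test_special_token_rejected(self):
        with pytest.raises(ValueError, match="special"):
            apply_action(init_canvas(), Action(1, Token("PAD", Kind.SPECIAL)))

    def test_blanks_renumber_left_to_right(self):
        c = apply_action(init_canvas(), Action(1, _tok("C"), True, True))
        assert [b.id for _, b in c.blanks()] == [1, 2]
        c = apply_action(c, Action(2, _tok("O"), True, True))
        assert [b.id for _, b in c.blanks()] == [1, 2, 3]


class TestTrainingCanvas:
    def test_example_keep_first_fill_second(self):
        x = tokenize_atomwise("CO")
        tt = make_training_canvas(x, [1, 2], 1)
        assert tt.canvas.to_text() == "C $1"
        assert tt.targets == (Action(1, x[1], False, False),)

    def test_single_token_initial_blank(self):
        x = tokenize_atomwise("C")
        tt = make_training_canvas(x, [1], 0)
        assert tt.canvas.to_text() == "$1"
        assert tt.targets == (Action(1, x[0], False, False),)
        # the whole-sequence blank is the initial (BLANK_0) blank
        assert tt.canvas.blanks()[0][1].initial

    def test_runs_collapse_to_single_blanks(self):
        x = tokenize_atomwise("CCOCC")
        # keep positions 1 and 4 -> C $1 C $2
        tt = make_training_canvas(x, [1, 4, 2, 3, 5], 2)
        assert tt.canvas.to_text() == "C $1 C $2"
        assert len(tt.targets) == 3

    def test_left_right_flags_within_run(self):
        x = tokenize_atomwise("CCOCC")
        tt = make_training_canvas(x, [1, 4, 3, 2, 5], 2)
        by_pos = dict(zip([3, 2, 5], tt.targets))
        assert (by_pos[3].left, by_pos[3].right) == (True, False)
        assert (by_pos[2].left, by_pos[2].right) == (False, True)
        assert (by_pos[5].left, by_pos[5].right) == (False, False)

    def test_invalid_inputs_rejected(self):
        x = tokenize_atomwise("CC")
        with pytest.raises(ValueError):
            make_training_canvas(x, [1, 2], 2)
        with pytest.raises(ValueError):
            make_training_canvas(x, [1, 1], 0)

    def test_target_count_is_n_minus_t(self, rng):
        x = tokenize_atomwise("CC(=O)Oc1ccccc1")
        n = len(x)
        for _ in range(20):
            t = int(rng.integers(0, n))
            sigma = list(rng.permutation(n) + 1)
            assert len(make_training_canvas(x, sigma, t).targets) == n - t


class TestReconstruction:
    def test_exhaustive_small_sequences(self):
        # distinct tokens catch any position mix-up
        for n in range(1, 6):
            x = [Token(f"[A{i}]", Kind.ATOM) for i in range(n)]
            for sigma in permutations(range(1, n + 1)):
                for t in range(n):
                    final = replay_training_targets(x, list(sigma), t)
                    assert final.tokens() == x, (sigma, t)

    def test_random_longer_sequences(self, rng):
        for _ in range(300):
            n = int(rng.integers(6, 25))
            x = [Token(f"[A{i}]", Kind.ATOM) for i in range(n)]
            sigma = list(rng.permutation(n) + 1)
            t = int(rng.integers(0, n))
            assert replay_training_targets(x, sigma, t).tokens() == x

    def test_completion_takes_exactly_missing_count_actions(self, rng):
        x = [Token(f"[A{i}]", Kind.ATOM) for i in range(12)]
        sigma = list(rng.permutation(12) + 1)
        t = 5
        final = replay_training_targets(x, sigma, t)
        assert final.step == t + (12 - t)

    def test_first_replay_action_matches_stored_target(self, rng):
        x = [Token(f"[A{i}]", Kind.ATOM) for i in range(10)]
        for _ in range(20):
            sigma = list(rng.permutation(10) + 1)
            t = int(rng.integers(0, 10))
            tt = make_training_canvas(x, sigma, t)
            # the stored target for sigma_{t+1} is the first replay action
            first = tt.targets[0]
            c = apply_action(tt.canvas, first)
            assert c.n_blanks == tt.canvas.n_blanks - 1 + first.left + first.right


class TestTemplates:
    TABLE4 = "CCn1nnnc1SCC(=O)N1CCc2ccccc21"

    def test_mask_first_token_of_29_token_string(self):
        toks = tokenize_atomwise(self.TABLE4)
        assert len(toks) == 29
        tpl = make_template(toks, {0})
        assert tpl.to_text() == \
            "$1 C n 1 n n n c 1 S C C ( = O ) N 1 C C c 2 c c c c c 2 1"
        assert tpl.n_blanks == 1

    def test_empty_mask_is_blank_free(self):
        toks = tokenize_atomwise("CC(=O)C")
        tpl = make_template(toks, set())
        assert tpl.n_blanks == 0 and is_complete(tpl)

    def test_masking_everything_equals_init_canvas(self):
        toks = tokenize_atomwise("CC(=O)C")
        tpl = make_template(toks, set(range(len(toks))))
        assert tpl == init_canvas()

    def test_adjacent_masked_runs_collapse(self):
        toks = tokenize_atomwise("CCOCC")
        tpl = make_template(toks, {1, 2, 4})
        assert tpl.to_text() == "C $1 C $2"

    def test_empty_token_list_rejected(self):
        with pytest.raises(ValueError):
            make_template([], set())

    def test_parse_template_round_trip(self):
        text = "<mask> C n 1 n n n c 1 S C C ( = O ) N 1 C C c 2 c c c c c 2 1"
        tpl = parse_template(text)
        toks = tokenize_atomwise(self.TABLE4)
        assert tpl == make_template(toks, {0})


class TestTrajectory:
    def test_trajectory_replays(self):
        actions = tuple(Action.from_kind(1, _tok(t), k)
                        for k, t in ACETONE_ACTIONS)
        traj = Trajectory(init_canvas(), actions)
        assert traj.replay().to_text() == "C C ( = O ) C"
        assert len(traj) == 7

    def test_replay_missing_blank_raises(self):
        traj = Trajectory(init_canvas(),
                          (Action(1, _tok("C")), Action(1, _tok("C"))))
        with pytest.raises((KeyError, ValueError)):
            traj.replay()
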