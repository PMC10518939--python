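"""Metric identities, hand-computed values and brute-force oracles."""

import math

import numpy as np
import pytest

from molcanvas import chem
from molcanvas.metrics import (cosine_counts, evaluate, frag_similarity,
                               frechet_distance, frechet_from_stats,
                               frechet_stats, int_div, novelty,
                               property_distribution, scaf_similarity, snn,
                               uniqueness_at_k, validity)

DIVERSE = ["CC(=O)Oc1ccccc1C(=O)O", "CC(=O)Nc1ccc(O)cc1", "CN1CCCC1c1cccnc1",
           "O=C(NCc1cccs1)Nc1ccc(F)cc1", "Clc1ccccc1Cl", "OCC1OC(O)C(O)C(O)C1O",
           "c1ccc2[nH]ccc2c1", "N#Cc1ccccc1"]


class TestValidity:
    def test_valid_and_invalid_mix(self):
        assert validity(["C(((", "CC"]) == 0.5

    def test_single_valid_molecule(self):
        assert validity(["CC(=O)C"]) == 1.0

    def test_decoded_selfies_always_valid(self, random_selfies_corpus):
        from molcanvas.selfies_codec import encode
        sf = [encode(s) for s in random_selfies_corpus.molecules]
        assert validity(sf, "SELFIES") == 1.0

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            validity([])


class TestUniquenessNovelty:
    def test_k_copies_of_one_molecule(self):
        assert uniqueness_at_k(["CC"] * 5, 5) == pytest.approx(1 / 5)

    def test_distinct_molecules(self):
        assert uniqueness_at_k(DIVERSE, len(DIVERSE)) == 1.0

    def test_canonicalization_collapses_aliases(self):
        assert uniqueness_at_k(["OCC", "CCO"], 2) == pytest.approx(0.5)

    def test_k_larger_than_set_rejected(self):
        with pytest.raises(ValueError):
            uniqueness_at_k(["CC"], 2)

    def test_novelty_extremes_and_half(self):
        train = DIVERSE[:4]
        assert novelty(train, train) == 0.0
        assert novelty(DIVERSE[4:], train) == 1.0
        assert novelty(DIVERSE[2:6], train) == pytest.approx(0.5)

    def test_novelty_empty_training_rejected(self):
        with pytest.raises(ValueError):
            novelty(["CC"], [])


def _hand_fp(bits):
    return np.array([list(bits)], dtype=bool)[0]


class TestIntDiv:
    def test_identical_set_is_zero(self):
        assert int_div(["CC(=O)C"] * 4) == pytest.approx(0.0)

    def test_hand_built_two_molecule_value(self):
        # fingerprints 1100_0000 and 1010_0000: T = 1/3
        fps = np.array([[1, 1, 0, 0, 0, 0, 0, 0],
                        [1, 0, 1, 0, 0, 0, 0, 0]], dtype=bool)
        val = int_div(None, p=1, fingerprints=fps)
        assert val == pytest.approx(1.0 - (2 * 1 + 2 * (1 / 3)) / 4)

    def test_matches_bruteforce_double_loop(self, rng):
        fps = rng.random((7, 32)) < 0.3
        for p in (1, 2):
            total = 0.0
            for a in fps:
                for b in fps:
                    inter = np.sum(a & b)
                    union = np.sum(a | b)
                    t = 1.0 if union == 0 else inter / union
                    total += t ** p
            ref = 1.0 - (total / len(fps) ** 2) ** (1 / p)
            assert int_div(None, p=p, fingerprints=fps) == \
                pytest.approx(ref, abs=1e-12)

    def test_duplicating_whole_set_leaves_diversity_unchanged(self, rng):
        # the ordered-pair distribution is invariant under set duplication
        for _ in range(10):
            fps = rng.random((5, 16)) < 0.4
            base = int_div(None, fingerprints=fps)
            doubled = np.vstack([fps, fps])
            assert int_div(None, fingerprints=doubled) == \
                pytest.approx(base, abs=1e-12)

    def test_mass_duplication_drives_diversity_to_zero(self, rng):
        fps = rng.random((4, 16)) < 0.4
        base = int_div(None, fingerprints=fps)
        swamped = np.vstack([fps] + [fps[:1]] * 60)
        assert int_div(None, fingerprints=swamped) < base


class TestSNN:
    def test_self_reference_is_one(self):
        assert snn(DIVERSE[:4], DIVERSE[:4]) == pytest.approx(1.0)

    def test_disjoint_fingerprints_zero(self):
        g = np.array([[1, 0, 0, 0]], dtype=bool)
        r = np.array([[0, 1, 1, 0]], dtype=bool)
        assert snn(None, None, fingerprints_g=g, fingerprints_r=r) == 0.0

    def test_matches_bruteforce_double_loop(self, rng):
        G = rng.random((3, 16)) < 0.4
        R = rng.random((2, 16)) < 0.4
        ref = np.mean([max(chem.tanimoto(a, b) for b in R) for a in G])
        assert snn(None, None, fingerprints_g=G, fingerprints_r=R) == \
            pytest.approx(ref, abs=1e-12)


class TestFrechet:
    def test_identical_sets_zero(self):
        assert frechet_distance(DIVERSE, DIVERSE) == pytest.approx(0.0,
                                                                   abs=1e-6)

    def test_one_dimensional_mean_shift(self, rng):
        # 1-D featurizer on Normal(0,1) vs Normal(1,1): distance -> (mu diff)^2
        a = rng.normal(0.0, 1.0, 10_000)
        b = rng.normal(1.0, 1.0, 10_000)
        fa = frechet_stats(list(range(10_000)),
                           featurizer=lambda i: np.array([a[i]]))
        fb = frechet_stats(list(range(10_000)),
                           featurizer=lambda i: np.array([b[i]]))
        assert frechet_from_stats(fa, fb) == pytest.approx(1.0, abs=0.1)

    def test_symmetry(self):
        G, R = DIVERSE[:4], DIVERSE[4:]
        assert frechet_distance(G, R) == pytest.approx(
            frechet_distance(R, G), rel=1e-6)

    def test_featurizer_failures_counted(self):
        stats = frechet_stats(["CC", "not_a_molecule", "CCO"])
        assert stats.n == 2 and stats.n_failed == 1

    def test_covariance_is_psd_by_construction(self):
        stats = frechet_stats(DIVERSE)
        w = np.linalg.eigvalsh((stats.sigma + stats.sigma.T) / 2)
        assert w.min() > -1e-8


class TestFragScaf:
    def test_self_similarity_is_one(self):
        assert frag_similarity(DIVERSE, DIVERSE) == pytest.approx(1.0)
        assert scaf_similarity(DIVERSE, DIVERSE) == pytest.approx(1.0)

    def test_hand_count_vectors(self):
        cg = {"a": 2, "b": 1}
        cr = {"a": 1, "b": 1, "c": 1}
        expected = 3 / (math.sqrt(5) * math.sqrt(3))
        assert cosine_counts(cg, cr) == pytest.approx(expected)

    def test_disjoint_supports_zero(self):
        assert cosine_counts({"a": 1}, {"b": 2}) == 0.0

    def test_empty_supports_zero(self):
        assert frag_similarity([], []) == 0.0
        assert cosine_counts({}, {}) == 0.0

    def test_matches_bruteforce_counting(self):
        G, R = DIVERSE[:5], DIVERSE[3:]
        from collections import Counter
        cg, cr = Counter(), Counter()
        for m in G:
            cg.update(chem.brics_fragments(m))
        for m in R:
            cr.update(chem.brics_fragments(m))
        keys = sorted(set(cg) | set(cr))
        g = np.array([cg[k] for k in keys], float)
        r = np.array([cr[k] for k in keys], float)
        ref = g @ r / (np.linalg.norm(g) * np.linalg.norm(r))
        assert frag_similarity(G, R) == pytest.approx(ref, abs=1e-12)


class TestOrderInvariance:
    def test_metrics_invariant_to_input_order(self, rng):
        G, R = list(DIVERSE[:5]), list(DIVERSE[3:])
        perm = list(rng.permutation(len(G)))
        Gp = [G[i] for i in perm]
        assert int_div(G) == pytest.approx(int_div(Gp), abs=1e-12)
        assert snn(G, R) == pytest.approx(snn(Gp, R), abs=1e-12)
        assert frag_similarity(G, R) == pytest.approx(
            frag_similarity(Gp, R), abs=1e-12)


class TestPropertyDistribution:
    def test_singleton_median(self):
        s = property_distribution(["CC(=O)C"], "logP")
        assert s.median == s.values[0] and s.n == 1

    def test_excluded_count_reported(self):
        s = property_distribution(["CC", "xxx", "CCO"], "QED")
        assert s.n == 2 and s.n_excluded == 1

    def test_unknown_property_rejected(self):
        with pytest.raises(ValueError, match="unknown property"):
            property_distribution(["CC"], "boilingPoint")

    def test_property_proxy_injection(self):
        s = property_distribution(["CC", "CCC"], "heavy",
                                  property_fn=chem.heavy_atom_count)
        assert list(s.values) == [2.0, 3.0]


class TestEvaluate:
    def test_report_structure(self):
        report = evaluate(DIVERSE, R=DIVERSE[:4], training=DIVERSE[:2])
        m = report.metrics
        for name in ("validity", "int_div", "snn", "frag", "scaf",
                     "frechet", "novelty"):
            assert name in m
        for name, value in m.items():
            if name != "frechet":
                assert 0.0 <= value <= 1.0, name
        assert m["frechet"] >= 0.0
        payload = report.to_dict()
        assert payload["validity"]["n"] == len(DIVERSE)
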