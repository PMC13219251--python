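import itertools
from collections import Counter

import numpy as np
import pytest

from artlang.lexicon import words_from_ipa, Lexicon, overlap_matrix
from artlang.streams import (
    MODES,
    Stream,
    StreamError,
    TransitionGraph,
    build_transition_graph,
    euler_circuit,
    generate_stream,
    naive_shuffle_stream,
    normalize_mode,
    reject_by_rhythmicity,
)


@pytest.fixture(scope="module")
def lex4(table):
    texts = ["b_aː|g_oː|d_iː", "k_eː|m_uː|s_øː", "l_yː|f_ɛː|n_aː", "t_oː|x_iː|v_uː"]
    words = words_from_ipa("\n".join(texts), table)
    return Lexicon(words=tuple(words), overlap=overlap_matrix(words))


class TestBuildTransitionGraph:
    def test_word_mode_exact_multiplicities(self, lex4):
        # T = 60 edges over 12 ordered pairs -> exactly 5 each
        g = build_transition_graph(lex4, "word_structured", 15, seed=0)
        assert g.n_edges == 60
        assert len(g.multiplicity) == 12
        assert set(g.multiplicity.values()) == {5}

    def test_position_random_multiplicities(self, lex4):
        # T = 180 edges over 132 pairs; out-degree 15 = 7x1 + 4x2
        g = build_transition_graph(lex4, "position_random", 15, seed=0)
        assert g.n_edges == 180
        assert len(g.multiplicity) == 132
        assert set(g.multiplicity.values()) == {1, 2}
        for v in g.vertices:
            row = sorted(
                m for (i, _), m in g.multiplicity.items() if i == v
            )
            assert row == [1] * 7 + [2] * 4

    def test_position_fixed_multiplicities(self, lex4):
        # 180 edges over 48 cross-group pairs: 3.75 -> {3, 4}
        g = build_transition_graph(lex4, "position_fixed", 15, seed=0)
        assert g.n_edges == 180
        assert len(g.multiplicity) == 48
        assert set(g.multiplicity.values()) == {3, 4}

    def test_position_fixed_edges_respect_groups(self, lex4):
        g = build_transition_graph(lex4, "position_fixed", 15, seed=1)
        pos = {
            w.syllables[p].id: p
            for w in lex4.words for p in range(3)
        }
        for (a, b) in g.multiplicity:
            assert pos[b] == (pos[a] + 1) % 3

    @pytest.mark.parametrize("mode", MODES)
    def test_degree_balance_and_no_self_loops(self, lex4, mode):
        g = build_transition_graph(lex4, mode, 15, seed=3)
        g.validate()  # raises on imbalance/self-loops/disconnection

    def test_single_word_error(self, table):
        words = words_from_ipa("b_aː|g_oː|d_iː", table)
        lex = Lexicon(words=tuple(words), overlap=overlap_matrix(words))
        with pytest.raises(StreamError):
            build_transition_graph(lex, "word_structured", 15, seed=0)

    def test_sparse_repetitions_still_connected(self, lex4):
        # q = 0 layouts (reps < N-1) must retry into a connected graph
        g = build_transition_graph(lex4, "position_random", 3, seed=0)
        g.validate()

    def test_mode_aliases(self):
        assert normalize_mode("random") == "position_random"
        assert normalize_mode("position_controlled") == "position_fixed"
        with pytest.raises(StreamError):
            normalize_mode("bogus")


def brute_force_circuits(multiplicity, start):
    """All Eulerian circuits from `start` (oracle; tiny graphs only)."""
    results = []

    def rec(v, remaining, path):
        if not any(remaining.values()):
            if v == start:
                results.append(tuple(path))
            return
        for (i, j), m in sorted(remaining.items()):
            if i == v and m > 0:
                remaining[(i, j)] -= 1
                path.append(j)
                rec(j, remaining, path)
                path.pop()
                remaining[(i, j)] += 1

    rec(start, dict(multiplicity), [start])
    return results


class TestEulerCircuit:
    def test_k3_matches_enumeration_oracle(self):
        # all 6 ordered pairs of 3 vertices, multiplicity 1
        mult = {(a, b): 1 for a in "ABC" for b in "ABC" if a != b}
        g = TransitionGraph(vertices=tuple("ABC"), multiplicity=mult)
        walk = euler_circuit(g, seed=0)
        assert len(walk) == 6
        counts = Counter(zip(walk, walk[1:]))
        # 5 of 6 pairs realized once, 1 zero (the dropped closing edge)
        assert set(counts.values()) == {1}
        assert len(counts) == 5
        # the closed walk must be a genuine Eulerian circuit of the oracle set
        oracle = brute_force_circuits(mult, walk[0])
        assert tuple(walk + [walk[0]]) in oracle

    def test_k4_matches_enumeration_oracle(self):
        mult = {(a, b): 1 for a in "ABCD" for b in "ABCD" if a != b}
        g = TransitionGraph(vertices=tuple("ABCD"), multiplicity=mult)
        walk = euler_circuit(g, seed=1)
        assert len(walk) == 12
        oracle = brute_force_circuits(mult, walk[0])
        assert tuple(walk + [walk[0]]) in oracle

    def test_k3_multiplicity2_transition_counts(self):
        mult = {(a, b): 2 for a in "ABC" for b in "ABC" if a != b}
        g = TransitionGraph(vertices=tuple("ABC"), multiplicity=mult)
        walk = euler_circuit(g, seed=2)
        counts = Counter(zip(walk, walk[1:]))
        realized = dict(counts)
        # edge conservation: realized = multiplicities minus the closing edge
        closing = (walk[-1], walk[0])
        expect = dict(mult)
        expect[closing] -= 1
        assert realized == {k: v for k, v in expect.items() if v > 0}

    def test_no_immediate_repeats(self, lex4):
        for mode in MODES:
            g = build_transition_graph(lex4, mode, 15, seed=4)
            walk = euler_circuit(g, seed=4)
            assert all(a != b for a, b in zip(walk, walk[1:]))

    def test_unbalanced_graph_error(self):
        g = TransitionGraph(
            vertices=("A", "B", "C"),
            multiplicity={("A", "B"): 2, ("B", "C"): 1, ("C", "A"): 1},
        )
        with pytest.raises(StreamError, match="unbalanced"):
            euler_circuit(g, seed=0)

    def test_disconnected_graph_error(self):
        g = TransitionGraph(
            vertices=("A", "B", "C", "D"),
            multiplicity={("A", "B"): 1, ("B", "A"): 1, ("C", "D"): 1, ("D", "C"): 1},
        )
        with pytest.raises(StreamError, match="connected"):
            euler_circuit(g, seed=0)


class TestGenerateStream:
    @pytest.mark.parametrize("mode", MODES)
    def test_token_counts_and_no_repeats(self, lex4, mode):
        s = generate_stream(lex4, mode, 15, seed=5)
        assert len(s) == 180
        counts = Counter(s.tokens)
        assert set(counts.values()) == {15}
        assert all(a != b for a, b in zip(s.tokens, s.tokens[1:]))

    def test_word_mode_within_word_tp_one(self, lex4):
        from artlang.metrics import empirical_tp

        s = generate_stream(lex4, "word_structured", 15, seed=6)
        alphabet, tp = empirical_tp(s)
        idx = {t: i for i, t in enumerate(alphabet)}
        for w in lex4.words:
            for a, b in zip(w.syllables, w.syllables[1:]):
                assert tp[idx[a.id], idx[b.id]] == 1.0

    def test_position_fixed_positions(self, lex4):
        s = generate_stream(lex4, "position_fixed", 15, seed=7)
        designated = {
            w.syllables[p].id: p for w in lex4.words for p in range(3)
        }
        for tok, pos in zip(s.tokens, s.word_position):
            assert pos == designated[tok]

    def test_determinism(self, lex4):
        a = generate_stream(lex4, "position_random", 15, seed=8)
        b = generate_stream(lex4, "position_random", 15, seed=8)
        assert a.tokens == b.tokens

    def test_word_mode_annotations(self, lex4):
        s = generate_stream(lex4, "word_structured", 15, seed=9)
        assert all(p is not None for p in s.word_position)
        assert s.word_position[:3] == [0, 1, 2]

    def test_position_random_no_annotations(self, lex4):
        s = generate_stream(lex4, "position_random", 15, seed=10)
        assert all(p is None for p in s.word_position)

    def test_boundary_tp_bounds(self, lex4):
        from artlang.metrics import empirical_tp

        W, S, reps = 4, 3, 15
        # word mode: boundary TPs within 1/reps of 1/(W-1)
        s = generate_stream(lex4, "word_structured", reps, seed=11)
        alphabet, tp = empirical_tp(s)
        idx = {t: i for i, t in enumerate(alphabet)}
        for wa in lex4.words:
            for wb in lex4.words:
                if wa is wb:
                    continue
                v = tp[idx[wa.syllables[-1].id], idx[wb.syllables[0].id]]
                assert abs(v - 1 / (W - 1)) <= 1 / reps + 1e-9
        # position_random: every off-diagonal TP within 2/reps of 1/(N-1)
        s = generate_stream(lex4, "position_random", reps, seed=12)
        alphabet, tp = empirical_tp(s)
        N = len(alphabet)
        off = tp[~np.eye(N, dtype=bool)]
        assert np.all(np.abs(off - 1 / (N - 1)) <= 2 / reps + 1e-9)
        # position_fixed: cross-group TPs within 1/reps of 1/W
        s = generate_stream(lex4, "position_fixed", reps, seed=13)
        alphabet, tp = empirical_tp(s)
        nz = tp[tp > 0]
        assert np.all(np.abs(nz - 1 / W) <= 1 / reps + 1e-9)

    def test_edge_conservation(self, lex4):
        s = generate_stream(lex4, "position_random", 15, seed=14)
        g = build_transition_graph(lex4, "position_random", 15, seed=14)
        realized = Counter(zip(s.tokens, s.tokens[1:]))
        diff = {
            k: g.multiplicity.get(k, 0) - realized.get(k, 0)
            for k in set(g.multiplicity) | set(realized)
        }
        assert sorted(diff.values()) == [0] * (len(diff) - 1) + [1]

    def test_stream_io(self, lex4, tmp_path):
        s = generate_stream(lex4, "word_structured", 15, seed=15)
        path = tmp_path / "stream.csv"
        s.write(path)
        assert path.exists()
        assert path.with_suffix(".json").exists()


class TestNaiveShuffle:
    def test_same_multiset_no_repeats(self, lex4):
        s = naive_shuffle_stream(lex4, "position_random", 15, seed=16)
        e = generate_stream(lex4, "position_random", 15, seed=16)
        assert Counter(s.tokens) == Counter(e.tokens)
        assert all(a != b for a, b in zip(s.tokens, s.tokens[1:]))

    def test_higher_boundary_tp_variance_than_circuit(self, lex4):
        from artlang.metrics import boundary_tps

        ec_vals, sh_vals = [], []
        for seed in range(50):
            ec_vals.extend(boundary_tps(generate_stream(lex4, "word_structured", 15, seed=seed)))
            sh_vals.extend(boundary_tps(naive_shuffle_stream(lex4, "word_structured", 15, seed=seed)))
        assert np.var(ec_vals) < np.var(sh_vals)

    def test_degenerate_multiset_error(self, table):
        words = words_from_ipa("b_aː|g_oː\nd_iː|k_eː", table)
        lex = Lexicon(words=tuple(words), overlap=overlap_matrix(words))
        # fine multiset, just checks the API works on 2-syllable words
        s = naive_shuffle_stream(lex, "word_structured", 5, seed=0)
        assert len(s) == 20


class TestRejectByRhythmicity:
    def test_none_accepts_all(self, lex4):
        out = reject_by_rhythmicity(lex4, MODES, n_streams_per_lexicon=1,
                                    max_rhythmicity=None, seed=0)
        assert set(out) == set(MODES)
        assert all(len(v) == 1 for v in out.values())

    def test_zero_bound_rejects_everything(self, lex4):
        out = reject_by_rhythmicity(
            lex4, ["word_structured"], n_streams_per_lexicon=1,
            max_rhythmicity=0.0, max_tries_randomize=2,
            require_all_tp_modes=True, seed=0,
        )
        assert out == {}

    def test_require_all_modes_all_or_none(self, lex4):
        out = reject_by_rhythmicity(
            lex4, MODES, n_streams_per_lexicon=1,
            max_rhythmicity=0.0, max_tries_randomize=1,
            require_all_tp_modes=True, seed=0,
        )
        assert out == {}
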