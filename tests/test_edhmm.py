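import itertools

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from cutsurvey.coverage import FoldChangeTrack
from cutsurvey.edhmm import (
    Discretizer,
    ExpandedHMM,
    build_model,
    cut_run_lengths,
    decode,
    generate,
    posterior,
    segments_from_path,
    viterbi,
    viterbi_score,
)
from cutsurvey.genomic_io import Genome


def toy_model(n_sub=2, q=0.8, a=0.4, bg=(0.7, 0.3), cut=(0.2, 0.8)):
    return build_model(n_sub=n_sub, q=q, a=a, background_emission=bg, cut_emission=cut)


class TestDiscretizer:
    def test_default_binning(self):
        d = Discretizer()
        # right-closed bins on log2 scale with edges (-0.5, 0.5, 1.0, 2.0)
        assert list(d.symbols([1.0, 2.0, 100.0, 1.2, 0.5])) == [1, 2, 4, 1, 0]

    def test_boundary_right_closed(self):
        d = Discretizer()
        assert d.symbols([2.0])[0] == 2          # log2 = 1.0 closes bin 2
        assert d.symbols([4.0])[0] == 3          # log2 = 2.0 closes bin 3

    def test_nonfinite_rejected(self):
        d = Discretizer()
        for bad in ([np.inf], [np.nan], [0.0], [-1.0]):
            with pytest.raises(ValueError):
                d.symbols(bad)

    def test_edges_must_ascend(self):
        with pytest.raises(ValueError):
            Discretizer((1.0, 0.5))


class TestBuildModel:
    def test_default_is_ten_states(self):
        m = build_model()
        assert m.n_states == 10 and m.n_sub == 9

    def test_degenerate_two_state(self):
        m = toy_model(n_sub=1)
        assert m.n_states == 2
        assert m.A[1, 0] == pytest.approx(0.4)

    def test_expected_cut_length_closed_form(self):
        m = build_model(a=2e-4)
        assert m.expected_cut_length == pytest.approx(9 / 2e-4)

    def test_invariants_enforced(self):
        m = build_model()
        bad = m.A.copy()
        bad[0, 5] = 0.1  # disallowed B -> C5 jump
        bad[0, 0] -= 0.1
        with pytest.raises(ValueError, match="disallowed"):
            ExpandedHMM(9, bad, m.E, m.pi)
        bad_e = m.E.copy()
        bad_e[3] = bad_e[3][::-1]  # sub-states must share one emission row
        with pytest.raises(ValueError, match="share"):
            ExpandedHMM(9, m.A, bad_e, m.pi)
        with pytest.raises(ValueError, match="sum"):
            ExpandedHMM(9, m.A * 0.5, m.E, m.pi)

    def test_stationary_distribution(self):
        m = build_model(n_sub=3, q=0.9, a=0.1)
        pi = m.stationary()
        assert pi @ m.A == pytest.approx(pi, abs=1e-10)
        assert pi.sum() == pytest.approx(1.0)


def brute_force_best(sym, model):
    """Max log joint probability over all legal state paths (enumeration)."""
    n = model.n_states
    logA = np.where(model.A > 0, np.log(np.where(model.A > 0, model.A, 1)), -np.inf)
    logE = np.where(model.E > 0, np.log(np.where(model.E > 0, model.E, 1)), -np.inf)
    logpi = np.where(model.pi > 0, np.log(np.where(model.pi > 0, model.pi, 1)), -np.inf)
    best = -np.inf
    for path in itertools.product(range(n), repeat=len(sym)):
        score = logpi[path[0]] + logE[path[0], sym[0]]
        for t in range(1, len(sym)):
            score += logA[path[t - 1], path[t]] + logE[path[t], sym[t]]
            if score == -np.inf:
                break
        best = max(best, score)
    return best


class TestViterbi:
    def test_all_background_symbols_give_all_background_path(self):
        m = toy_model()
        path = viterbi(np.zeros(200, dtype=int), m)
        assert not (path > 0).any()

    def test_matches_enumeration_on_short_sequences(self):
        m = toy_model()
        for L in (1, 2, 5, 8):
            for sym in itertools.product(range(2), repeat=L):
                sym = np.array(sym)
                _, score = viterbi_score(sym, m)
                assert score == pytest.approx(brute_force_best(sym, m), abs=1e-9)

    def test_block_boundaries_recovered(self):
        m = build_model()
        d = Discretizer()
        fc = np.ones(1500)
        fc[500:1000] = 2.0
        path = viterbi(d.symbols(fc), m)
        segs = segments_from_path({("chrI", "+"): path})
        assert len(segs) == 1
        assert abs(segs[0].start - 500) <= 5 and abs(segs[0].end - 1000) <= 5

    def test_path_respects_transition_topology(self):
        m = build_model()
        rng = np.random.default_rng(3)
        sym = rng.integers(0, 5, size=5000)
        path = viterbi(sym, m)
        allowed = m.allowed_transitions()
        assert all(allowed[a, b] for a, b in zip(path[:-1], path[1:]))

    def test_empty_sequence(self):
        assert viterbi(np.array([], dtype=int), toy_model()).size == 0

    def test_symbol_outside_alphabet_rejected(self):
        with pytest.raises(ValueError):
            viterbi(np.array([0, 5]), toy_model())

    def test_posterior_sums_to_one_and_agrees_on_strong_signal(self):
        m = build_model()
        d = Discretizer()
        fc = np.ones(600)
        fc[200:400] = 8.0
        sym = d.symbols(fc)
        post, loglik = posterior(sym, m)
        assert np.allclose(post.sum(axis=1), 1.0)
        assert loglik < 0
        in_cut = post[:, 1:].sum(axis=1)
        assert in_cut[250:350].min() > 0.95 and in_cut[:150].max() < 0.05


class TestSegments:
    def test_runs_become_intervals(self):
        path = np.array([0, 0, 1, 2, 2, 2, 0, 1, 2, 0])
        segs = segments_from_path({("chrI", "+"): path})
        assert [(s.start, s.end) for s in segs] == [(2, 6), (7, 9)]

    def test_all_background_is_empty(self):
        assert segments_from_path({("chrI", "+"): np.zeros(50, dtype=int)}) == []

    def test_minimum_decoded_length_is_n_sub(self):
        # neutral symbol 0 plus equiprobable transitions: one CUT-favoring
        # observation forces a traversal of the whole sub-state chain
        m = build_model(
            q=0.5, a=0.5,
            background_emission=(0.5, 0.49, 0.01),
            cut_emission=(0.5, 0.01, 0.49),
        )
        sym = np.zeros(60, dtype=int)
        sym[30] = 2
        segs = segments_from_path({("c", "+"): viterbi(sym, m)})
        assert segs and min(s.length for s in segs) >= m.n_sub

    @given(st.lists(st.integers(0, 1), min_size=1, max_size=400))
    def test_interior_decoded_runs_never_shorter_than_n_sub(self, sym):
        # runs truncated by the sequence ends may be shorter; interior runs
        # must traverse the whole chain
        m = toy_model(n_sub=2)
        runs = cut_run_lengths(viterbi(np.array(sym), m), complete_only=True)
        assert (runs >= 2).all() if runs.size else True


class TestGenerate:
    def test_seed_reproducibility(self):
        m = toy_model()
        s1, p1 = generate(m, 5000, seed=42)
        s2, p2 = generate(m, 5000, seed=42)
        assert np.array_equal(s1, s2) and np.array_equal(p1, p2)
        s3, _ = generate(m, 5000, seed=43)
        assert not np.array_equal(s1, s3)

    def test_advance_probability_one_gives_exact_runs(self):
        m = build_model(n_sub=9, q=0.9, a=1.0)
        _, path = generate(m, 50_000, seed=0)
        runs = cut_run_lengths(path)
        assert runs.size > 100 and (runs == 9).all()

    def test_duration_mean_matches_negative_binomial(self):
        a = 0.02
        m = build_model(n_sub=9, q=1 - 1 / 500, a=a)
        _, path = generate(m, 2_000_000, seed=7)
        runs = cut_run_lengths(path)
        assert runs.size > 500
        assert abs(runs.mean() - 9 / a) / (9 / a) < 0.05


class TestDecode:
    def test_fold_change_track_decoding(self):
        g = Genome({"chrI": 2000})
        data = {}
        for strand in ("+", "-"):
            arr = np.ones(2000)
            if strand == "+":
                arr[600:1100] = 4.0
            data[("chrI", strand)] = arr
        fc = FoldChangeTrack(g, data)
        segs = segments_from_path(decode(fc, build_model()))
        assert len(segs) == 1 and segs[0].strand == "+"
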