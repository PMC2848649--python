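import numpy as np
import pytest

from seqdbn import (
    CPTParams,
    DBNParams,
    DBNSpec,
    NodeSpec,
    SequenceBatch,
    ancestral_sample,
    completed_loglik,
    forward_loglik,
    gibbs_infer,
    gibbs_sweep,
    hmm_structure,
    markov_blanket,
)
from seqdbn.discrete import discrete_log_density
from seqdbn.errors import DataError, TopologyError
from seqdbn.inference import GibbsSampler, UnderflowError

from ._oracles import enumerate_paths_loglik, forward_backward_marginals
from .conftest import make_hmm_batch, make_hmm_params, make_hmm_spec


class TestMarkovBlanket:
    def test_hmm_interior_slice(self):
        spec = make_hmm_spec()
        assert markov_blanket(spec, 5, 2, 0) == [(1, 0), (2, 1), (3, 0)]

    def test_hmm_boundaries(self):
        spec = make_hmm_spec()
        assert markov_blanket(spec, 5, 0, 0) == [(0, 1), (1, 0)]
        assert markov_blanket(spec, 5, 4, 0) == [(3, 0), (4, 1)]

    def test_two_chain_model_blankets(self):
        spec = DBNSpec(
            nodes=(NodeSpec("H", "discrete", 5, hidden_allowed=True),
                   NodeSpec("I", "discrete", 3, hidden_allowed=True),
                   NodeSpec("G", "gaussian_multi", 4),
                   NodeSpec("V", "vonmises_bi", 2)),
            intra_edges=((0, 2), (1, 3)),
            inter_edges=((0, 0), (1, 1)),
        )
        # H at an interior slice: its own chain neighbours plus its child G
        assert markov_blanket(spec, 6, 3, 0) == [(2, 0), (3, 2), (4, 0)]
        assert markov_blanket(spec, 6, 3, 1) == [(2, 1), (3, 3), (4, 1)]

    def test_coparents_included(self):
        spec = DBNSpec(
            nodes=(NodeSpec("a", "discrete", 2, hidden_allowed=True),
                   NodeSpec("b", "discrete", 2),
                   NodeSpec("c", "discrete", 2)),
            intra_edges=((0, 2), (1, 2)),
        )
        assert markov_blanket(spec, 1, 0, 0) == [(0, 1), (0, 2)]


class TestGibbsSweep:
    def test_single_slice_conditional_matches_enumeration(self):
        """Hidden root with one observed child: one sweep samples exactly
        from the enumerated posterior; check the empirical law over many
        independent chains."""
        spec = DBNSpec(
            nodes=(NodeSpec("h", "discrete", 2, hidden_allowed=True),
                   NodeSpec("o", "discrete", 3)),
            intra_edges=((0, 1),),
        )
        prior = np.array([0.35, 0.65])
        emis = np.array([[0.5, 0.3, 0.2], [0.1, 0.2, 0.7]])
        params = DBNParams(
            spec=spec,
            cpds=[CPTParams(table=prior), CPTParams(table=emis)],
            cpds0=[None, None],
        )
        obs = 2
        n = 100_000
        per_seq = [([np.zeros(1, np.int64), np.array([obs], np.int64)],
                    [np.ones(1, bool), np.zeros(1, bool)])] * n
        batch = SequenceBatch.from_arrays(spec, per_seq)
        rng = np.random.default_rng(8)
        sampler = GibbsSampler(params, batch, rng)
        sampler.sweep(rng)
        draws = np.array([sampler.engine.vals[0][s, 0] for s in range(n)])
        post = prior * emis[:, obs]
        post /= post.sum()
        emp = np.bincount(draws, minlength=2) / n
        assert np.abs(emp - post).max() < 0.005

    def test_deterministic_emission_forces_state(self, rng):
        spec = make_hmm_spec(2, 2)
        params = make_hmm_params(
            spec, [0.5, 0.5], [[0.5, 0.5], [0.5, 0.5]],
            [[1.0, 0.0], [0.0, 1.0]])
        batch = make_hmm_batch(spec, [0, 1, 1, 0])
        hidden = gibbs_sweep(params, batch, GibbsSampler(params, batch, rng).assignment(), rng)
        assert np.array_equal(hidden[0][0], [0, 1, 1, 0])

    def test_resample_ops_double_with_length_and_states(self, rng, hmm_2state):
        spec, params, *_ = hmm_2state
        for L, expect_ratio in [(10, None), (20, 2.0)]:
            batch = make_hmm_batch(spec, np.zeros(L, np.int64))
            sampler = GibbsSampler(params, batch, rng)
            sampler.resample_ops = 0
            sampler.sweep(rng)
            if expect_ratio is None:
                base = sampler.resample_ops
            else:
                assert sampler.resample_ops == expect_ratio * base
        # ops scale linearly in the node's state count as well
        for s, expect in [(2, 10 * 2), (4, 10 * 4)]:
            spec_s = make_hmm_spec(s, 2)
            params_s = make_hmm_params(
                spec_s, np.full(s, 1 / s), np.full((s, s), 1 / s),
                np.full((s, 2), 0.5))
            batch = make_hmm_batch(spec_s, np.zeros(10, np.int64))
            sampler = GibbsSampler(params_s, batch, rng)
            sampler.resample_ops = 0
            sampler.sweep(rng)
            assert sampler.resample_ops == expect

    def test_all_zero_conditional_raises_underflow(self, rng):
        spec = make_hmm_spec(2, 2)
        # both hidden states give the observed symbol probability zero
        params = make_hmm_params(
            spec, [0.5, 0.5], [[0.5, 0.5], [0.5, 0.5]],
            [[0.0, 1.0], [0.0, 1.0]])
        batch = make_hmm_batch(spec, [1, 0, 1])
        sampler = GibbsSampler(params, batch, rng, init=False)
        with pytest.raises(UnderflowError, match="slice 1"):
            sampler.sweep(rng)

    def test_same_seed_same_completion(self, hmm_2state):
        spec, params, *_ = hmm_2state
        batch = make_hmm_batch(spec, [0, 1, 0, 1, 1])
        runs = []
        for _ in range(2):
            rng = np.random.default_rng(77)
            sampler = GibbsSampler(params, batch, rng)
            sampler.sweep(rng)
            runs.append(sampler.assignment())
        assert np.array_equal(runs[0][0][0], runs[1][0][0])


class TestGibbsInfer:
    def test_marginals_match_forward_backward(self, hmm_2state):
        """Empirical Gibbs marginals against exact smoothing marginals on a
        3-slice 2-state chain; many parallel chains supply the sample
        budget."""
        spec, params, pi, T, E = hmm_2state
        obs = np.array([0, 1, 0], dtype=np.int64)
        reps = 100
        per_seq = [([np.zeros(3, np.int64), obs],
                    [np.ones(3, bool), np.zeros(3, bool)])] * reps
        batch = SequenceBatch.from_arrays(spec, per_seq)
        rng = np.random.default_rng(13)
        freq = gibbs_infer(params, batch, n_burn=50, n_samples=500, rng=rng)
        emp = np.mean([freq[s][0] for s in range(reps)], axis=0)
        em = E[:, obs].T  # (L, s) emission likelihoods
        exact = forward_backward_marginals(pi, T, em)
        tv = 0.5 * np.abs(emp - exact).sum(axis=1).max()
        assert tv < 0.02

    def test_single_sample_is_one_hot(self, hmm_2state, rng):
        spec, params, *_ = hmm_2state
        batch = make_hmm_batch(spec, [0, 1])
        freq = gibbs_infer(params, batch, n_burn=5, n_samples=1, rng=rng)
        table = freq[0][0]
        assert np.all(np.isin(table, [0.0, 1.0]))
        assert np.allclose(table.sum(axis=1), 1.0)

    def test_symmetric_model_gives_uniform_marginals(self):
        spec = make_hmm_spec(2, 2)
        params = make_hmm_params(
            spec, [0.5, 0.5], [[0.5, 0.5], [0.5, 0.5]],
            [[0.5, 0.5], [0.5, 0.5]])
        reps = 200
        per_seq = [([np.zeros(4, np.int64), np.array([0, 1, 0, 1], np.int64)],
                    [np.ones(4, bool), np.zeros(4, bool)])] * reps
        batch = SequenceBatch.from_arrays(spec, per_seq)
        rng = np.random.default_rng(14)
        freq = gibbs_infer(params, batch, n_burn=10, n_samples=250, rng=rng)
        emp = np.mean([freq[s][0] for s in range(reps)], axis=0)
        assert np.abs(emp - 0.5).max() < 0.01


class TestCompletedLoglik:
    def test_fully_observed_equals_joint(self, hmm_2state):
        spec, params, pi, T, E = hmm_2state
        h = np.array([0, 1, 1], dtype=np.int64)
        o = np.array([0, 1, 0], dtype=np.int64)
        batch = make_hmm_batch(spec, o, hidden=h)
        expected = (np.log(pi[h[0]]) + np.log(T[h[0], h[1]]) + np.log(T[h[1], h[2]])
                    + np.log(E[h, o]).sum())
        assert completed_loglik(params, batch) == pytest.approx(expected, abs=1e-12)

    def test_uniform_parentless_closed_form(self):
        spec = DBNSpec(nodes=(NodeSpec("u", "discrete", 5),))
        params = DBNParams(spec=spec, cpds=[CPTParams(table=np.full(5, 0.2))],
                           cpds0=[None])
        vals = np.zeros(50, dtype=np.int64)
        batch = SequenceBatch.from_arrays(
            spec, [([vals], [np.zeros(50, bool)])])
        assert completed_loglik(params, batch) == pytest.approx(50 * np.log(0.2))

    def test_matches_per_factor_recomputation(self, rng):
        """Brute-force per-factor sum over a random 3-node model."""
        spec = DBNSpec(
            nodes=(NodeSpec("a", "discrete", 2, hidden_allowed=True),
                   NodeSpec("b", "discrete", 3),
                   NodeSpec("c", "discrete", 2)),
            intra_edges=((0, 1), (1, 2)),
            inter_edges=((0, 0),),
        )
        t_a = rng.dirichlet(np.ones(2), size=2)
        pi_a = rng.dirichlet(np.ones(2))
        t_b = rng.dirichlet(np.ones(3), size=2)
        t_c = rng.dirichlet(np.ones(2), size=3)
        params = DBNParams(
            spec=spec,
            cpds=[CPTParams(table=t_a), CPTParams(table=t_b), CPTParams(table=t_c)],
            cpds0=[CPTParams(table=pi_a), None, None],
        )
        L = 6
        a = rng.integers(0, 2, L)
        b = rng.integers(0, 3, L)
        c = rng.integers(0, 2, L)
        batch = SequenceBatch.from_arrays(
            spec, [([a, b, c], [np.zeros(L, bool)] * 3)])
        expected = np.log(pi_a[a[0]])
        for t in range(1, L):
            expected += discrete_log_density(params.cpds[0], [a[t - 1]], a[t])
        for t in range(L):
            expected += discrete_log_density(params.cpds[1], [a[t]], b[t])
            expected += discrete_log_density(params.cpds[2], [b[t]], c[t])
        assert completed_loglik(params, batch) == pytest.approx(expected, abs=1e-10)

    def test_hidden_without_assignment_rejected(self, hmm_2state):
        spec, params, *_ = hmm_2state
        batch = make_hmm_batch(spec, [0, 1])
        with pytest.raises(DataError):
            completed_loglik(params, batch)


class TestForwardLoglik:
    def test_matches_path_enumeration(self, hmm_2state):
        spec, params, pi, T, E = hmm_2state
        obs = np.array([0, 1, 1], dtype=np.int64)
        batch = make_hmm_batch(spec, obs)
        oracle = enumerate_paths_loglik(pi, T, E[:, obs].T)
        assert forward_loglik(params, batch) == pytest.approx(oracle, abs=1e-10)

    def test_uniform_model_closed_form(self):
        M, L = 4, 7
        spec = make_hmm_spec(3, M)
        params = make_hmm_params(
            spec, np.full(3, 1 / 3), np.full((3, 3), 1 / 3), np.full((3, M), 1 / M))
        batch = make_hmm_batch(spec, np.arange(L) % M)
        assert forward_loglik(params, batch) == pytest.approx(L * np.log(1 / M))

    def test_upper_bounds_completed_loglik(self, hmm_2state, rng):
        spec, params, *_ = hmm_2state
        obs = np.array([0, 1, 0, 0, 1], dtype=np.int64)
        batch = make_hmm_batch(spec, obs)
        fll = forward_loglik(params, batch)
        sampler = GibbsSampler(params, batch, rng)
        for _ in range(10):
            sampler.sweep(rng)
            cll = completed_loglik(params, batch, sampler.assignment())
            assert fll >= cll

    def test_invariant_under_state_relabeling(self, hmm_2state):
        spec, params, pi, T, E = hmm_2state
        obs = np.array([0, 0, 1, 1], dtype=np.int64)
        batch = make_hmm_batch(spec, obs)
        perm = [1, 0]
        permuted = make_hmm_params(spec, pi[perm], T[np.ix_(perm, perm)], E[perm])
        assert forward_loglik(params, batch) == pytest.approx(
            forward_loglik(permuted, batch), abs=1e-12)

    def test_non_hmm_topology_refused(self):
        spec = DBNSpec(
            nodes=(NodeSpec("a", "discrete", 2, hidden_allowed=True),
                   NodeSpec("b", "discrete", 2, hidden_allowed=True),
                   NodeSpec("o", "discrete", 2)),
            intra_edges=((0, 2),),
            inter_edges=((0, 0), (1, 1)),
        )
        with pytest.raises(TopologyError):
            hmm_structure(spec)

    def test_observed_hidden_entries_are_clamped(self, hmm_2state):
        spec, params, pi, T, E = hmm_2state
        obs = np.array([0, 1], dtype=np.int64)
        h = np.array([0, 1], dtype=np.int64)
        batch = make_hmm_batch(spec, obs, hidden=h)  # chain fully observed
        expected = (np.log(pi[0]) + np.log(E[0, 0])
                    + np.log(T[0, 1]) + np.log(E[1, 1]))
        assert forward_loglik(params, batch) == pytest.approx(expected, abs=1e-12)


class TestAncestralSample:
    def test_moments_match_model(self, hmm_2state):
        spec, params, pi, T, E = hmm_2state
        rng = np.random.default_rng(55)
        batch = ancestral_sample(params, 4000, 2, rng)
        h0 = np.array([s.values[0][0] for s in batch.sequences])
        freq = np.bincount(h0, minlength=2) / len(h0)
        assert np.abs(freq - pi).max() < 0.03
        # transition frequencies
        h = np.array([s.values[0] for s in batch.sequences])
        for a in range(2):
            sel = h[:, 0] == a
            tr = np.bincount(h[sel, 1], minlength=2) / sel.sum()
            assert np.abs(tr - T[a]).max() < 0.04

    def test_same_seed_identical(self, hmm_2state):
        spec, params, *_ = hmm_2state
        a = ancestral_sample(params, 5, 4, np.random.default_rng(3))
        b = ancestral_sample(params, 5, 4, np.random.default_rng(3))
        for sa, sb in zip(a.sequences, b.sequences):
            for va, vb in zip(sa.values, sb.values):
                assert np.array_equal(va, vb)
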