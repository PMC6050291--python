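import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import poisson

from switchkin.config import GeneratorConfig
from switchkin.model import HMMModel, ReducibleChainError
from switchkin.hmm import (
    fit_em,
    loglikelihood,
    posteriors,
    predicted_histogram,
    select_model,
    viterbi,
)
from switchkin.synthetic import simulate_dataset, simulate_state_path
from switchkin.traces import LineageTrace

from conftest import match_states


def trace_from_counts(counts):
    counts = np.asarray(counts)
    n = len(counts)
    return LineageTrace(
        lineage_id="t", frame_interval=5.0,
        time_min=np.arange(n) * 5.0,
        cro=counts[:, 0], ci=counts[:, 1],
        cell_age=np.full(n, 0.5), division_flag=np.zeros(n, dtype=bool),
    )


def make_model(means, A=None, pi=None):
    means = np.atleast_2d(np.asarray(means, float))
    K = means.shape[0]
    if A is None:
        A = np.full((K, K), 0.2 / max(K - 1, 1))
        np.fill_diagonal(A, 0.8 if K > 1 else 1.0)
    if pi is None:
        pi = np.full(K, 1.0 / K)
    return HMMModel(means=means, transmat=np.asarray(A, float), startprob=np.asarray(pi, float))


def loglik_by_enumeration(model, counts):
    """Oracle: exhaustive sum over all K^T hidden paths."""
    counts = np.asarray(counts)
    K, T = model.n_states, len(counts)
    total = 0.0
    for path in itertools.product(range(K), repeat=T):
        p = model.startprob[path[0]]
        for t in range(1, T):
            p *= model.transmat[path[t - 1], path[t]]
        for t, s in enumerate(path):
            p *= poisson.pmf(counts[t, 0], model.means[s, 0])
            p *= poisson.pmf(counts[t, 1], model.means[s, 1])
        total += p
    return np.log(total) if total > 0 else -np.inf


def best_path_by_enumeration(model, counts):
    counts = np.asarray(counts)
    K, T = model.n_states, len(counts)
    best, best_lp = None, -np.inf
    for path in itertools.product(range(K), repeat=T):
        lp = np.log(model.startprob[path[0]] + 1e-300)
        for t in range(1, T):
            lp += np.log(model.transmat[path[t - 1], path[t]] + 1e-300)
        for t, s in enumerate(path):
            lp += poisson.logpmf(counts[t, 0], model.means[s, 0])
            lp += poisson.logpmf(counts[t, 1], model.means[s, 1])
        if lp > best_lp:
            best, best_lp = path, lp
    return np.array(best), best_lp


class TestLogLikelihood:
    def test_single_frame_unit_means(self):
        m = make_model([[1.0, 1.0]])
        tr = trace_from_counts([(0, 0)])
        assert loglikelihood(m, tr) == pytest.approx(-2.0, abs=1e-12)

    def test_matches_enumeration_small(self):
        m = make_model([[0.5, 3.0], [4.0, 0.2]])
        tr = trace_from_counts([(0, 3), (4, 0), (1, 1)])
        assert loglikelihood(m, tr) == pytest.approx(
            loglik_by_enumeration(m, tr.counts), abs=1e-10
        )

    @given(
        K=st.integers(1, 3),
        T=st.integers(1, 6),
        seed=st.integers(0, 10_000),
    )
    @settings(max_examples=30, deadline=None)
    def test_matches_enumeration_property(self, K, T, seed):
        rng = np.random.default_rng(seed)
        means = rng.uniform(0.1, 6.0, size=(K, 2))
        A = rng.dirichlet(np.ones(K), size=K)
        pi = rng.dirichlet(np.ones(K))
        m = HMMModel(means=means, transmat=A, startprob=pi)
        counts = rng.integers(0, 8, size=(T, 2))
        tr = trace_from_counts(counts)
        expected = loglik_by_enumeration(m, counts)
        assert loglikelihood(m, tr) == pytest.approx(expected, abs=1e-10)

    def test_appending_frame_bound(self):
        m = make_model([[2.0, 2.0], [0.5, 0.5]])
        rng = np.random.default_rng(0)
        counts = rng.integers(0, 5, size=(6, 2))
        ll_short = loglikelihood(m, trace_from_counts(counts[:5]))
        ll_full = loglikelihood(m, trace_from_counts(counts))
        max_emis = max(
            poisson.logpmf(counts[5, 0], m.means[k, 0])
            + poisson.logpmf(counts[5, 1], m.means[k, 1])
            for k in range(2)
        )
        assert ll_full <= ll_short + max_emis + 1e-9

    def test_impossible_observation_is_neg_inf(self):
        m = make_model([[0.0, 0.0]])  # lambda exactly 0, count > 0
        tr = trace_from_counts([(2, 0)])
        assert loglikelihood(m, tr) == -np.inf


class TestFitEM:
    def test_single_state_recovers_means(self):
        rng = np.random.default_rng(1)
        counts = rng.poisson(5.0, size=(3000, 2))
        fit = fit_em([trace_from_counts(counts)], K=1, n_restarts=2, seed=0)
        se = np.sqrt(5.0 / 3000)
        np.testing.assert_allclose(fit.model.means[0], 5.0, atol=3 * se)

    def test_loglik_monotone_nondecreasing(self, default_dataset):
        fit = fit_em(default_dataset[:20], K=3, n_restarts=1, seed=2)
        h = np.array(fit.ll_history)
        assert np.all(np.diff(h) >= -1e-8 * np.abs(h[:-1]))

    def test_rows_and_start_normalized(self, default_dataset):
        fit = fit_em(default_dataset[:20], K=4, n_restarts=2, seed=3)
        np.testing.assert_allclose(fit.model.transmat.sum(axis=1), 1.0, atol=1e-10)
        assert fit.model.startprob.sum() == pytest.approx(1.0, abs=1e-10)

    def test_table_recovery_single_seed(self, default_config, default_dataset):
        fit = fit_em(default_dataset, K=4, n_restarts=5, seed=0)
        true = np.asarray(default_config.emission_means)
        perm = match_states(fit.model.means, true)
        got = fit.model.means[perm]
        for t, g in zip(true.ravel(), got.ravel()):
            if t >= 0.5:
                assert abs(g - t) / t < 0.10
            else:
                assert abs(g - t) < 0.25

    def test_validates_inputs(self, default_dataset):
        with pytest.raises(ValueError):
            fit_em(default_dataset, K=0)
        with pytest.raises(ValueError):
            fit_em([], K=2)


class TestSelectModel:
    def test_single_state_data_selects_one(self):
        rng = np.random.default_rng(4)
        counts = rng.poisson((3.0, 1.0), size=(2000, 2))
        traces = [trace_from_counts(counts)]
        sel = select_model(traces, [1, 2, 3], n_restarts=2, seed=1)
        assert sel.selected_K == 1

    def test_empty_range_rejected(self, default_dataset):
        with pytest.raises(ValueError):
            select_model(default_dataset, [])

    def test_four_state_data_selects_four_both_criteria(self, default_dataset):
        sel = select_model(
            default_dataset, range(1, 7), n_restarts=3, seed=0
        )
        tab = sel.table
        assert int(tab.loc[tab.selected_bic, "K"].iloc[0]) == 4
        assert int(tab.loc[tab.selected_histmatch, "K"].iloc[0]) == 4


class TestViterbi:
    def test_well_separated_matches_framewise_argmax(self):
        m = make_model(
            [[0.2, 10.0], [10.0, 0.2]],
            A=[[0.95, 0.05], [0.05, 0.95]],
            pi=[0.5, 0.5],
        )
        path_true = np.array([0, 0, 1, 1, 0])
        counts = np.array([[0, 9], [1, 12], [11, 0], [9, 1], [0, 8]])
        dec = viterbi(m, trace_from_counts(counts))
        np.testing.assert_array_equal(dec.states, path_true)

    def test_identical_states_tie_to_lower_index(self):
        m = make_model(
            [[2.0, 2.0], [2.0, 2.0]],
            A=[[0.5, 0.5], [0.5, 0.5]],
            pi=[0.5, 0.5],
        )
        counts = np.array([[2, 2], [1, 3], [2, 2]])
        dec = viterbi(m, trace_from_counts(counts))
        assert np.all(dec.states == 0)

    def test_optimal_vs_enumeration(self):
        rng = np.random.default_rng(9)
        m = HMMModel(
            means=rng.uniform(0.2, 6.0, (2, 2)),
            transmat=rng.dirichlet((1, 1), size=2),
            startprob=rng.dirichlet((1, 1)),
        )
        counts = rng.integers(0, 7, size=(5, 2))
        dec = viterbi(m, trace_from_counts(counts))
        best_path, best_lp = best_path_by_enumeration(m, counts)
        np.testing.assert_array_equal(dec.states, best_path)

    def test_viterbi_beats_pointwise_argmax(self, default_dataset, four_state_model):
        # the Viterbi path's joint probability >= that of the posterior
        # pointwise-argmax path
        m = four_state_model
        tr = default_dataset[0]
        dec = viterbi(m, tr)
        gamma = posteriors(m, tr.counts)
        pointwise = gamma.argmax(axis=1)

        def path_lp(path):
            lp = np.log(m.startprob[path[0]] + 1e-300)
            lp += poisson.logpmf(tr.counts[0, 0], m.means[path[0], 0])
            lp += poisson.logpmf(tr.counts[0, 1], m.means[path[0], 1])
            for t in range(1, len(path)):
                lp += np.log(m.transmat[path[t - 1], path[t]] + 1e-300)
                lp += poisson.logpmf(tr.counts[t, 0], m.means[path[t], 0])
                lp += poisson.logpmf(tr.counts[t, 1], m.means[path[t], 1])
            return lp

        assert path_lp(dec.states) >= path_lp(pointwise) - 1e-9

    def test_segments_tile_trace(self, default_dataset, four_state_model):
        dec = viterbi(four_state_model, default_dataset[1])
        covered = np.zeros(len(default_dataset[1]), dtype=int)
        for seg in dec.segments:
            covered[seg.start : seg.start + seg.length] += 1
        assert np.all(covered == 1)

    def test_decoding_accuracy_on_generator_truth(
        self, default_dataset, four_state_model
    ):
        hits = total = 0
        for tr in default_dataset[:20]:
            dec = viterbi(four_state_model, tr)
            hits += (dec.states == tr.true_state).sum()
            total += len(tr)
        assert hits / total > 0.85


class TestPredictedHistogram:
    def test_single_state_product_of_poissons(self):
        m = make_model([[2.0, 3.0]])
        h = predicted_histogram(m, max_count=15)
        expect = np.outer(poisson.pmf(np.arange(16), 2.0), poisson.pmf(np.arange(16), 3.0))
        expect[-1, :] += 0  # tail pooling negligible at this lambda
        np.testing.assert_allclose(h.probabilities, expect / expect.sum(), atol=1e-6)

    def test_sums_to_one(self, four_state_model):
        h = predicted_histogram(four_state_model, max_count=25)
        assert h.probabilities.sum() == pytest.approx(1.0, abs=1e-9)

    def test_matches_long_simulation_tv(self, four_state_model, default_config):
        # oracle: 10^6-frame forward simulation of the same model
        n = 1_000_000
        path = simulate_state_path(four_state_model, n, seed=55)
        rng = np.random.default_rng(56)
        lam = four_state_model.means[path.states]
        counts = rng.poisson(lam)
        max_count = 20
        c = np.clip(counts, 0, max_count)
        hist = np.zeros((max_count + 1, max_count + 1))
        np.add.at(hist, (c[:, 0], c[:, 1]), 1.0)
        hist /= n
        pred = predicted_histogram(four_state_model, max_count=max_count)
        tv = 0.5 * np.abs(pred.probabilities - hist).sum()
        assert tv < 0.01

    def test_reducible_chain_rejected(self):
        m = make_model([[1.0, 1.0], [2.0, 2.0]], A=np.eye(2), pi=[0.5, 0.5])
        with pytest.raises(ReducibleChainError):
            predicted_histogram(m, max_count=5)
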