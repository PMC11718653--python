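import networkx as nx
import numpy as np
import pytest
from scipy import stats

from ppibias.graphs import degree_sequence, generate_er
from ppibias.simulate import (
    SimConfig,
    _simulate_dense,
    _simulate_sparse,
    current_edges,
    run_experiment,
    sample_baits,
    sample_preys,
    simulate,
)
from ppibias.simulate import TestCounts as PairCounts



class TestBaitSampling:
    def test_zero_degrees_is_uniform(self):
        deg = dict.fromkeys(range(5), 0)
        rng = np.random.default_rng(0)
        counts = np.zeros(5)
        for _ in range(5000):
            counts[sample_baits(deg, 1, 0.01, rng)[0]] += 1
        _, p = stats.chisquare(counts)
        assert p > 0.01

    def test_weight_ratio_with_one_hub(self):
        """degrees (100, 0, 0): node 0 drawn with probability 100.01/100.03."""
        deg = {0: 100, 1: 0, 2: 0}
        rng = np.random.default_rng(1)
        reps = 50_000
        hits = sum(sample_baits(deg, 1, 0.01, rng)[0] == 0 for _ in range(reps))
        expect = 100.01 / 100.03
        se = np.sqrt(expect * (1 - expect) / reps)
        assert abs(hits / reps - expect) < max(4 * se, 2e-4)

    def test_full_draw_is_permutation(self):
        deg = {i: i for i in range(6)}
        out = sample_baits(deg, 6, 0.01, seed=3)
        assert sorted(out) == list(range(6))

    def test_too_many_baits_rejected(self):
        with pytest.raises(ValueError):
            sample_baits({0: 1}, 2, 0.01, seed=0)


class TestPreySampling:
    def test_apms_ignores_degrees(self):
        deg = {0: 1000, 1: 0}
        rng = np.random.default_rng(2)
        reps = 20_000
        hits = sum(sample_preys(deg, 1, "AP-MS", 0.01, rng)[0] == 0 for _ in range(reps))
        assert abs(hits / reps - 0.5) < 4 * np.sqrt(0.25 / reps)

    def test_y2h_weight_ratio(self):
        deg = {0: 10, 1: 0}
        rng = np.random.default_rng(3)
        reps = 50_000
        hits = sum(sample_preys(deg, 1, "Y2H", 0.01, rng)[0] == 0 for _ in range(reps))
        expect = 10.01 / 10.02
        assert abs(hits / reps - expect) < 4 * np.sqrt(expect * (1 - expect) / reps)


class TestRunExperiment:
    def test_error_free_counts(self):
        gt = nx.Graph([(0, 1)])
        gt.add_node(2)
        counts = PairCounts()
        run_experiment(gt, [0], [1, 2], fnr=0.0, fpr=0.0, counts=counts, seed=0)
        assert (counts.a(0, 1), counts.b(0, 1)) == (1, 1)
        assert (counts.a(0, 2), counts.b(0, 2)) == (1, 0)

    def test_certain_false_positives_accumulate(self):
        gt = nx.empty_graph(2)
        counts = PairCounts()
        for s in range(5):
            run_experiment(gt, [0], [1], fnr=0.0, fpr=1.0, counts=counts, seed=s)
        assert (counts.a(0, 1), counts.b(0, 1)) == (5, 5)

    def test_self_pairs_skipped(self):
        counts = PairCounts()
        run_experiment(nx.empty_graph(2), [0], [0, 1], 0.0, 1.0, counts, seed=0)
        assert counts.a(0, 0) == 0 and counts.a(0, 1) == 1


class TestGammaRule:
    def test_strict_inequality_at_half(self):
        counts = PairCounts()
        counts._c[(0, 1)] = [4, 2]
        assert current_edges(counts, 0.5) == set()

    def test_majority_included(self):
        counts = PairCounts()
        counts._c[(0, 1)] = [4, 3]
        assert current_edges(counts, 0.5) == {(0, 1)}

    def test_any_detection_suffices_at_gamma_zero(self):
        counts = PairCounts()
        counts._c[(0, 1)] = [7, 1]
        assert current_edges(counts, 0.0) == {(0, 1)}

    def test_counts_invariant_b_le_a(self):
        counts = PairCounts()
        with pytest.raises(ValueError):
            counts.record(0, 0, True)


def _config(**kw):
    defaults = dict(
        method="AP-MS", fnr=0.0, fpr=0.0, gamma=0.0,
        n_experiments=40, study_sizes=[(2, 20)] * 40, seed=5,
    )
    defaults.update(kw)
    return SimConfig(**defaults)


class TestSimulate:
    def test_error_free_equals_tested_true_edges(self):
        gt = generate_er(200, 400, seed=1)
        res = simulate(gt, _config())
        tested_true = {
            frozenset((u, v)) for u, v, a, b in res.counts.pairs() if gt.has_edge(u, v)
        }
        assert {frozenset(e) for e in res.network.edges()} == tested_true

    def test_empty_ground_truth_no_false_positives(self):
        gt = nx.empty_graph(100)
        res = simulate(gt, _config(study_sizes=[(2, 10)] * 40))
        assert res.network.number_of_edges() == 0

    def test_false_positive_rate_matches_expectation(self):
        """Empty ground truth: E|E'| = sum over tested pairs of 1-(1-fpr)^a."""
        fpr = 0.05
        devs = []
        for seed in range(5):
            gt = nx.empty_graph(300)
            res = simulate(
                gt,
                _config(fpr=fpr, seed=seed, n_experiments=100,
                        study_sizes=[(2, 30)] * 100),
            )
            a = np.array([a for _, _, a, _ in res.counts.pairs()])
            expect = (1 - (1 - fpr) ** a).sum()
            sd = np.sqrt(((1 - (1 - fpr) ** a) * (1 - fpr) ** a).sum())
            devs.append((res.network.number_of_edges() - expect) / sd)
        assert np.all(np.abs(devs) < 3)

    def test_gamma_monotone(self):
        gt = generate_er(150, 300, seed=2)
        res = simulate(gt, _config(fnr=0.1, fpr=0.1, seed=9))
        assert current_edges(res.counts, 0.5) <= current_edges(res.counts, 0.0)

    def test_bit_reproducible(self):
        gt = generate_er(150, 300, seed=3)
        r1 = simulate(gt, _config(fpr=0.02, seed=13))
        r2 = simulate(gt, _config(fpr=0.02, seed=13))
        assert set(r1.network.edges()) == set(r2.network.edges())
        assert dict(r1.counts._c) == dict(r2.counts._c)
        assert r1.log == r2.log

    def test_dense_and_sparse_paths_agree(self):
        gt = generate_er(120, 240, seed=4)
        cfg = _config(method="Y2H", fnr=0.1, fpr=0.05, gamma=0.5, seed=21)
        d = _simulate_dense(gt, cfg)
        s = _simulate_sparse(gt, cfg)
        assert {frozenset(e) for e in d.network.edges()} == {
            frozenset(e) for e in s.network.edges()
        }
        assert {frozenset(k): tuple(v) for k, v in d.counts._c.items()} == {
            frozenset(k): tuple(v) for k, v in s.counts._c.items()
        }

    def test_study_bias_feedback_correlation(self):
        """With fpr > 0, bait-selection count correlates with final degree."""
        rhos = []
        for seed in range(5):
            gt = nx.empty_graph(200)
            res = simulate(
                gt,
                _config(fpr=0.1, seed=seed, n_experiments=150,
                        study_sizes=[(3, 20)] * 150),
            )
            times_bait = np.zeros(200)
            for baits, _, _ in res.log:
                for u in baits:
                    times_bait[u] += 1
            deg = degree_sequence(res.network)
            rhos.append(stats.spearmanr(deg, times_bait).statistic)
        assert np.all(np.array(rhos) > 0)

    def test_invalid_gamma(self):
        with pytest.raises(ValueError):
            _config(gamma=1.0)
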