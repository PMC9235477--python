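"""Evaluation metrics, stratification, hub filtering, sparsification."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hybridppi import (
    ValidationError,
    aupr,
    auroc,
    build_network,
    evaluate,
    filter_hub_edges,
    fpr_at_recall,
    sparsify,
    stratify_by_distance,
    stratify_by_max_degree,
    synth_network,
)


def brute_force_aupr(labels, scores):
    """Step-wise precision-recall summation over threshold groups
    (descending unique scores), ties entering together."""
    labels = np.asarray(labels)
    scores = np.asarray(scores)
    n_pos = labels.sum()
    area = 0.0
    prev_recall = 0.0
    tp = fp = 0
    for thr in sorted(set(scores), reverse=True):
        sel = scores == thr
        tp += labels[sel].sum()
        fp += (1 - labels[sel]).sum()
        recall = tp / n_pos
        precision = tp / (tp + fp)
        area += (recall - prev_recall) * precision
        prev_recall = recall
    return area


def brute_force_auroc(labels, scores):
    """Mann-Whitney concordance: P(score_pos > score_neg) + 0.5 ties."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0
               for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestAUPR:
    def test_perfect_separation(self):
        assert aupr([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9]) == 1.0

    def test_four_point_case_matches_threshold_sweep(self):
        labels = [1, 0, 1, 0]
        scores = [0.9, 0.8, 0.7, 0.1]
        assert aupr(labels, scores) == pytest.approx(
            brute_force_aupr(labels, scores), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError):
            aupr([1, 1, 1], [0.1, 0.2, 0.3])

    def test_random_scores_approach_prevalence_at_1_to_10(self):
        # the step-wise estimator carries a small O(1/n_pos) upward bias,
        # so the check uses enough positives to make it negligible
        rng = np.random.default_rng(0)
        vals = []
        labels = np.array([1] * 100 + [0] * 1000)
        for _ in range(150):
            vals.append(aupr(labels, rng.random(1100)))
        assert np.mean(vals) == pytest.approx(1 / 11, abs=0.015)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_matches_brute_force_with_ties(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 14))
        labels = rng.integers(0, 2, n)
        if labels.sum() in (0, n):
            labels[0], labels[-1] = 0, 1
        scores = rng.choice([0.1, 0.3, 0.5, 0.7, 0.9], size=n)
        assert aupr(labels, scores) == pytest.approx(
            brute_force_aupr(labels, scores), abs=1e-9)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(1)
        labels = rng.integers(0, 2, 40)
        labels[:2] = [0, 1]
        scores = rng.random(40)
        assert aupr(labels, scores) == pytest.approx(
            aupr(labels, np.exp(3 * scores)), abs=1e-12)
        assert auroc(labels, scores) == pytest.approx(
            auroc(labels, np.exp(3 * scores)), abs=1e-12)


class TestAUROC:
    def test_perfect_and_random(self):
        assert auroc([0, 1], [0.1, 0.9]) == 1.0
        rng = np.random.default_rng(2)
        labels = np.array([1] * 100 + [0] * 1000)
        vals = [auroc(labels, rng.random(1100)) for _ in range(50)]
        assert np.mean(vals) == pytest.approx(0.5, abs=0.01)

    def test_four_point_concordance(self):
        labels = [1, 0, 1, 0]
        scores = [0.9, 0.8, 0.7, 0.1]
        assert auroc(labels, scores) == pytest.approx(
            brute_force_auroc(labels, scores), abs=1e-12)

    @settings(max_examples=120, deadline=None, derandomize=True)
    @given(st.integers(0, 100_000))
    def test_equals_concordance_oracle_up_to_12_pairs(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 13))
        labels = rng.integers(0, 2, n)
        if labels.sum() in (0, n):
            labels[0] = 1 - labels[0]
        scores = np.round(rng.random(n), 1)  # coarse grid induces ties
        assert auroc(labels, scores) == pytest.approx(
            brute_force_auroc(labels, scores), abs=1e-12)


class TestFPRAtRecall:
    def test_perfect_classifier_zero_fpr(self):
        labels = [1, 1, 0, 0, 0]
        scores = [0.9, 0.8, 0.3, 0.2, 0.1]
        for level in (0.1, 0.5, 1.0):
            assert fpr_at_recall(labels, scores, level) == 0.0

    def test_degenerate_constant_scores(self):
        labels = [1, 0, 1, 0, 0]
        scores = [0.5] * 5
        for level in (0.1, 0.5, 1.0):
            assert fpr_at_recall(labels, scores, level) == 1.0

    def test_ten_pair_case_matches_sweep_oracle(self):
        labels = np.array([1, 0, 1, 1, 0, 0, 1, 0, 0, 0])
        scores = np.array([0.95, 0.9, 0.85, 0.6, 0.55, 0.5, 0.45, 0.3, 0.2, 0.1])
        n_pos, n_neg = labels.sum(), (1 - labels).sum()

        def oracle(level):
            best = None
            for thr in sorted(set(scores), reverse=True):
                tp = ((scores >= thr) & (labels == 1)).sum()
                fp = ((scores >= thr) & (labels == 0)).sum()
                if tp / n_pos >= level:
                    best = fp / n_neg
                    break
            return best

        for level in (0.1, 0.5, 0.75, 1.0):
            assert fpr_at_recall(labels, scores, level) == pytest.approx(oracle(level))

    def test_level_validation(self):
        with pytest.raises(ValidationError):
            fpr_at_recall([0, 1], [0.1, 0.9], 0.0)
        with pytest.raises(ValidationError):
            fpr_at_recall([0, 1], [0.1, 0.9], 1.5)


class TestStratification:
    @pytest.fixture
    def net(self):
        # hub H with 30 neighbours, a 4-chain, and a detached pair
        edges = [("H", f"x{i}", 1.0) for i in range(30)]
        edges += [("a", "b", 1.0), ("b", "c", 1.0), ("c", "d", 1.0)]
        edges += [("u", "v", 1.0)]
        return build_network(edges)

    def test_max_degree_rule_and_partition(self, net):
        pairs = [("H", "x0"), ("a", "b"), ("a", "c"), ("x0", "x1"), ("u", "v")]
        strata = stratify_by_max_degree(pairs, net)
        assert ("H", "x0") in strata[">=21"]
        assert ("a", "b") in strata["2-5"]       # max(deg a=1, deg b=2) = 2
        assert ("u", "v") in strata["<2"]        # both degree 1: underflow
        got = [p for group in strata.values() for p in group]
        assert sorted(got) == sorted(pairs)
        sets = [set(map(frozenset, g)) for g in strata.values()]
        for s1, s2 in itertools.combinations(sets, 2):
            assert not (s1 & s2)

    def test_star_spoke_pairs_underflow(self):
        star = build_network([("hub", f"s{i}", 1.0) for i in range(5)])
        pairs = [(f"s{i}", f"s{j}") for i in range(5) for j in range(i + 1, 5)]
        strata = stratify_by_max_degree(pairs, star)
        assert sorted(strata["<2"]) == sorted(pairs)  # spokes have degree 1
        hub_pairs = [("hub", "s0")]
        assert stratify_by_max_degree(hub_pairs, star)["2-5"] == hub_pairs

    def test_off_network_endpoint_rejected(self, net):
        with pytest.raises(ValidationError, match="ghost"):
            stratify_by_max_degree([("H", "ghost")], net)

    def test_distance_strata(self, net):
        strata = stratify_by_distance(
            [("a", "b"), ("a", "c"), ("a", "d"), ("a", "u"), ("H", "a")], net)
        assert ("a", "b") in strata[1]
        assert ("a", "c") in strata[2]
        assert ("a", "d") in strata[3]
        assert ("a", "u") in strata["inf"]
        assert ("H", "a") in strata["inf"]

    def test_six_cycle_opposite_nodes(self):
        cyc = build_network([(f"c{i}", f"c{(i + 1) % 6}", 1.0) for i in range(6)])
        strata = stratify_by_distance([("c0", "c3")], cyc)
        assert ("c0", "c3") in strata[3]


class TestFilterHubEdges:
    def test_strict_boundary(self):
        # two nodes of degree exactly 20: kept; degree 21: removed
        edges = [("A", f"a{i}", 1.0) for i in range(19)] + [("A", "B", 1.0)]
        edges += [("B", f"b{i}", 1.0) for i in range(19)]
        net = build_network(edges)
        assert net.degree("A") == net.degree("B") == 20
        assert filter_hub_edges([("A", "B")], net) == [("A", "B")]
        net.add_edge("A", "extra", 1.0)  # now degree(A) = 21
        assert filter_hub_edges([("A", "B"), ("B", "b0")], net) == [("B", "b0")]

    def test_kept_plus_removed_partition_input(self):
        net = synth_network(60, seed=1)
        nodes = sorted(net.nodes)
        pairs = [(nodes[i], nodes[i + 1]) for i in range(0, 50, 2)]
        kept = filter_hub_edges(pairs, net)
        removed = [p for p in pairs if p not in kept]
        assert sorted(kept + removed) == sorted(pairs)
        for a, b in removed:
            assert max(net.degree(a), net.degree(b)) >= 21


class TestSparsify:
    @pytest.fixture
    def net50(self):
        # connected 15-node graph with exactly 50 edges (tree needs 14,
        # so p down to ~0.3 is feasible)
        import networkx as nx
        g = nx.gnm_random_graph(15, 50, seed=7)
        assert nx.is_connected(g)
        net = build_network([(f"n{a}", f"n{b}", 1.0) for a, b in g.edges()])
        assert net.n_edges == 50
        return net

    def test_p_one_identity(self, net50):
        split = sparsify(net50, 1.0, seed=0)
        assert split.network.n_edges == net50.n_edges
        assert split.held_out_positives == []

    @pytest.mark.parametrize("p", [0.3, 0.5, 0.8])
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_connected_and_exact_heldout_identity(self, net50, p, seed):
        split = sparsify(net50, p, seed=seed)
        assert split.network.is_connected()
        assert set(split.network.nodes) == set(net50.nodes)
        full = {frozenset((a, b)) for a, b, _ in net50.edges()}
        kept = {frozenset((a, b)) for a, b, _ in split.network.edges()}
        held = {frozenset(p_) for p_ in split.held_out_positives}
        assert kept | held == full
        assert not (kept & held)

    def test_rounding_rule(self, net50):
        n_edges = net50.n_edges
        for p in (0.37, 0.5, 0.83):
            split = sparsify(net50, p, seed=0)
            import math
            assert split.network.n_edges == math.floor(p * n_edges + 0.5)

    def test_too_small_p_reports_feasible_minimum(self, net50):
        with pytest.raises(ValidationError, match="feasible"):
            sparsify(net50, 0.05, seed=0)

    def test_disconnected_input_rejected(self):
        net = build_network([("A", "B", 1.0), ("C", "D", 1.0)])
        with pytest.raises(ValidationError):
            sparsify(net, 0.9, seed=0)


class TestRandomBaselineLaw:
    @pytest.mark.parametrize("n_pos,n_neg", [(200, 200), (100, 1000), (40, 2000)])
    def test_expected_aupr_is_prevalence(self, n_pos, n_neg):
        # ratios 1:1, 1:10, 1:50; mean within Monte-Carlo error plus the
        # estimator's small positive O(1/n_pos) bias
        rng = np.random.default_rng(4)
        labels = np.array([1] * n_pos + [0] * n_neg)
        vals = [aupr(labels, rng.random(n_pos + n_neg)) for _ in range(120)]
        prevalence = n_pos / (n_pos + n_neg)
        mc_sd = np.std(vals) / np.sqrt(len(vals))
        assert prevalence - 4 * mc_sd < np.mean(vals) < prevalence + 0.02


class TestEvaluateReport:
    def test_perfect_scores_report(self):
        labels = [1, 1, 0, 0, 0]
        scores = [0.9, 0.8, 0.3, 0.2, 0.1]
        rep = evaluate(labels, scores)
        assert rep.aupr == 1.0 and rep.auroc == 1.0
        assert rep.fpr_at[0.1] == 0.0 and rep.fpr_at[0.5] == 0.0
        assert (rep.n_pos, rep.n_neg) == (2, 3)

    def test_matches_direct_component_calls(self):
        rng = np.random.default_rng(5)
        labels = rng.integers(0, 2, 60)
        labels[:2] = [0, 1]
        scores = rng.random(60)
        rep = evaluate(labels, scores)
        assert rep.aupr == aupr(labels, scores)
        assert rep.auroc == auroc(labels, scores)
        assert rep.fpr_at[0.5] == fpr_at_recall(labels, scores, 0.5)

    def test_random_scores_near_baselines_at_1_to_10(self):
        rng = np.random.default_rng(6)
        labels = np.array([1] * 200 + [0] * 2000)
        reps = [evaluate(labels, rng.random(2200)) for _ in range(20)]
        assert np.mean([r.aupr for r in reps]) == pytest.approx(0.091, abs=0.01)
        assert np.mean([r.auroc for r in reps]) == pytest.approx(0.5, abs=0.01)

    def test_stratified_report_serializes(self):
        net = build_network([("a", "b", 1.0), ("b", "c", 1.0), ("c", "d", 1.0)])
        pairs = [("a", "b"), ("a", "c"), ("b", "d"), ("a", "d")]
        labels = [1, 0, 1, 0]
        scores = [0.9, 0.4, 0.6, 0.2]
        rep = evaluate(labels, scores, pairs=pairs, net=net, strata="distance")
        d = rep.to_dict()
        assert "strata" in d
        rep.to_json()
        rows = rep.to_flat_rows()
        assert rows[0]["stratum"] == "overall"
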