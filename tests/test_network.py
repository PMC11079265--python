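"""wTO networks, ego extraction, tissue merging and enrichment oracles."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from subgwas import network, simulate
from subgwas.network import EgoNetwork, WTONetwork


def wto_oracle(a):
    """Independent double-loop evaluation of the topological-overlap formula."""
    n = a.shape[0]
    k = [sum(a[i, u] for u in range(n) if u != i) for i in range(n)]
    w = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            cross = sum(a[i, m] * a[m, j] for m in range(n) if m != i and m != j)
            w[i, j] = (a[i, j] + cross) / (min(k[i], k[j]) + 1 - a[i, j])
    return w


def random_adjacency(n, rng):
    r = rng.uniform(-1, 1, size=(n, n))
    r = (r + r.T) / 2
    a = np.abs(r) ** 6
    np.fill_diagonal(a, 0.0)
    return a


class TestSoftAdjacency:
    def test_identical_vectors_give_unit_adjacency(self):
        expr = pd.DataFrame([[1.0, 2, 3, 4], [1.0, 2, 3, 4]], index=["g1", "g2"])
        a = network.soft_adjacency(expr)
        assert a.loc["g1", "g2"] == pytest.approx(1.0)
        assert a.loc["g1", "g1"] == 0.0

    def test_power_six_of_half_correlation(self):
        assert 0.5**6 == pytest.approx(0.015625)
        rng = np.random.default_rng(0)
        x = rng.normal(size=500)
        y = 0.5 * x + np.sqrt(1 - 0.25) * rng.normal(size=500)
        expr = pd.DataFrame([x, y], index=["g1", "g2"])
        r = np.corrcoef(x, y)[0, 1]
        a = network.soft_adjacency(expr)
        assert a.loc["g1", "g2"] == pytest.approx(abs(r) ** 6, abs=1e-12)

    def test_power_one_equals_absolute_correlation(self):
        rng = np.random.default_rng(1)
        expr = pd.DataFrame(rng.normal(size=(5, 50)), index=list("abcde"))
        a = network.soft_adjacency(expr, power=1)
        r = np.abs(np.corrcoef(expr.to_numpy()))
        np.fill_diagonal(r, 0.0)
        assert np.allclose(a.to_numpy(), r, atol=1e-12)

    def test_constant_gene_raises_naming_it(self):
        expr = pd.DataFrame([[1.0, 1, 1, 1], [1.0, 2, 3, 4]], index=["flat", "g2"])
        with pytest.raises(ValueError, match="flat"):
            network.soft_adjacency(expr)

    def test_too_few_samples_rejected(self):
        expr = pd.DataFrame([[1.0, 2], [2.0, 1]], index=["g1", "g2"])
        with pytest.raises(ValueError):
            network.soft_adjacency(expr)


class TestWto:
    def test_hand_computed_three_gene_value(self):
        a = np.array([[0, 0.5, 0.2], [0.5, 0, 0.4], [0.2, 0.4, 0]])
        w = network.wto_matrix(a)
        # (0.5 + 0.2*0.4) / (min(0.7, 0.9) + 1 - 0.5) = 0.58 / 1.2
        assert w[0, 1] == pytest.approx(0.58 / 1.2, abs=1e-12)

    def test_all_zero_adjacency_gives_zero_wto(self):
        w = network.wto_matrix(np.zeros((4, 4)))
        assert np.all(w == 0)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(2)
        for n in (5, 10, 20):
            a = random_adjacency(n, rng)
            assert np.allclose(network.wto_matrix(a), wto_oracle(a), atol=1e-12)

    def test_symmetry_and_unit_range(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            a = random_adjacency(int(rng.integers(4, 30)), rng)
            w = network.wto_matrix(a)
            assert np.allclose(w, w.T, atol=1e-15)
            assert w.min() >= 0 and w.max() <= 1 + 1e-12

    def test_nonzero_diagonal_rejected(self):
        a = np.eye(3)
        with pytest.raises(ValueError):
            network.wto_matrix(a)

    def test_gene_permutation_invariance(self):
        rng = np.random.default_rng(4)
        a = random_adjacency(8, rng)
        perm = rng.permutation(8)
        w = network.wto_matrix(a)
        w_perm = network.wto_matrix(a[np.ix_(perm, perm)])
        assert np.allclose(w[np.ix_(perm, perm)], w_perm, atol=1e-12)


class TestTopFractionFilter:
    def _net(self, weights):
        n = len(weights)
        edges = pd.DataFrame(
            {"gene_a": [f"a{i:03d}" for i in range(n)],
             "gene_b": [f"b{i:03d}" for i in range(n)],
             "weight": weights}
        )
        return WTONetwork(edges=edges, tissue="t")

    def test_exact_count_at_fraction(self):
        rng = np.random.default_rng(0)
        net = self._net(list(rng.uniform(size=100)))
        out = network.top_fraction_filter(net, 0.15)
        assert len(out.edges) == 15

    def test_ceiling_of_fractional_count(self):
        net = self._net([0.9, 0.5, 0.1])
        out = network.top_fraction_filter(net, 0.5)  # ceil(1.5) = 2
        assert len(out.edges) == 2

    def test_fraction_one_is_identity(self):
        net = self._net([0.9, 0.5, 0.1])
        out = network.top_fraction_filter(net, 1.0)
        assert len(out.edges) == 3

    def test_kept_weights_dominate_dropped(self):
        rng = np.random.default_rng(1)
        net = self._net(list(rng.uniform(size=60)))
        out = network.top_fraction_filter(net, 0.25)
        dropped = set(net.edges.gene_a) - set(out.edges.gene_a)
        min_kept = out.edges.weight.min()
        max_dropped = net.edges[net.edges.gene_a.isin(dropped)].weight.max()
        assert min_kept >= max_dropped

    def test_empty_network(self):
        net = self._net([])
        assert network.top_fraction_filter(net, 0.15).edges.empty


class TestEgocentricExtract:
    def _net(self, rows, genes):
        return WTONetwork(
            edges=pd.DataFrame(rows, columns=["gene_a", "gene_b", "weight"]),
            tissue="t", genes=tuple(genes),
        )

    def test_fewer_edges_than_k(self):
        net = self._net(
            [("T", "a", 0.5), ("T", "b", 0.4), ("T", "c", 0.3), ("a", "b", 0.9)],
            ["T", "a", "b", "c"],
        )
        ego = network.egocentric_extract(net, "T", k=25)
        assert ego.neighbors.neighbor.tolist() == ["a", "b", "c"]

    def test_top_k_strongest_direct_links(self):
        rows = [("T", f"g{i:02d}", w) for i, w in enumerate(np.linspace(0.9, 0.1, 30))]
        net = self._net(rows, ["T"] + [f"g{i:02d}" for i in range(30)])
        ego = network.egocentric_extract(net, "T", k=25)
        assert len(ego.neighbors) == 25
        assert ego.neighbors.weight.is_monotonic_decreasing
        assert ego.neighbors.neighbor.iloc[0] == "g00"

    def test_target_with_no_surviving_edges_is_empty(self):
        net = self._net([("a", "b", 0.9)], ["T", "a", "b"])
        ego = network.egocentric_extract(net, "T")
        assert ego.neighbors.empty

    def test_unknown_target_rejected(self):
        net = self._net([("a", "b", 0.9)], ["a", "b"])
        with pytest.raises(ValueError):
            network.egocentric_extract(net, "nope")


class TestMergeTissueEgos:
    def _ego(self, target, pairs, tissue):
        return EgoNetwork(
            target=target,
            neighbors=pd.DataFrame(pairs, columns=["neighbor", "weight"]),
            tissue=tissue,
        )

    def test_hand_computed_merge_weight(self):
        egos = [
            self._ego("T", [("n1", 0.5)], "t1"),
            self._ego("T", [("n1", 0.3)], "t2"),
        ]
        merged = network.merge_tissue_egos(egos)
        assert merged.neighbors.weight.iloc[0] == pytest.approx(0.25 + 0.09, abs=1e-12)

    def test_single_tissue_ranking_preserved(self):
        ego = self._ego("T", [("n1", 0.8), ("n2", 0.5), ("n3", 0.2)], "t1")
        merged = network.merge_tissue_egos([ego])
        assert merged.neighbors.neighbor.tolist() == ["n1", "n2", "n3"]
        assert merged.neighbors.weight.tolist() == pytest.approx([0.64, 0.25, 0.04])

    def test_absent_tissue_contributes_zero(self):
        # n2 is in tissue t1's top-k only; t2 contributes nothing for it
        egos = [
            self._ego("T", [("n1", 0.5), ("n2", 0.6)], "t1"),
            self._ego("T", [("n1", 0.5)], "t2"),
        ]
        merged = network.merge_tissue_egos(egos)
        weights = dict(zip(merged.neighbors.neighbor, merged.neighbors.weight))
        assert weights["n1"] == pytest.approx(0.5)
        assert weights["n2"] == pytest.approx(0.36)

    def test_mixed_targets_rejected(self):
        with pytest.raises(ValueError):
            network.merge_tissue_egos(
                [self._ego("T1", [("n", 0.5)], "t1"), self._ego("T2", [("n", 0.5)], "t1")]
            )

    def test_top_k_cap_applied(self):
        pairs = [(f"n{i:03d}", 0.9 - 0.01 * i) for i in range(40)]
        merged = network.merge_tissue_egos([self._ego("T", pairs, "t1")], k=25)
        assert len(merged.neighbors) == 25


class TestSharedNeighborhood:
    def _ego(self, target, names):
        return EgoNetwork(
            target=target,
            neighbors=pd.DataFrame({"neighbor": names, "weight": 0.5}),
            tissue="merged",
        )

    def test_intersection_semantics(self):
        shared = network.shared_neighborhood(
            [self._ego("T1", ["a", "b"]), self._ego("T2", ["b", "c"])]
        )
        assert shared.shared_genes == ("b",)
        assert set(shared.edges.target) == {"T1", "T2"}
        assert shared.n_targets_largest_component == 2

    def test_disjoint_egos_empty(self):
        shared = network.shared_neighborhood(
            [self._ego("T1", ["a"]), self._ego("T2", ["b"])]
        )
        assert shared.shared_genes == () and shared.edges.empty

    def test_component_counting(self):
        shared = network.shared_neighborhood(
            [
                self._ego("T1", ["a"]), self._ego("T2", ["a"]),
                self._ego("T3", ["z"]), self._ego("T4", ["z"]), self._ego("T5", ["z"]),
            ]
        )
        assert shared.n_targets_largest_component == 3
        assert shared.targets_per_neighbor["z"] == 3

    def test_single_target_rejected(self):
        with pytest.raises(ValueError):
            network.shared_neighborhood([self._ego("T1", ["a"])])


def hypergeom_tail_oracle(k, N, K, n):
    """Exact upper-tail sum over the hypergeometric support."""
    total = 0.0
    for x in range(k, min(K, n) + 1):
        total += math.comb(K, x) * math.comb(N - K, n - x) / math.comb(N, n)
    return total


class TestFisherEnrichment:
    def test_fold_enrichment_and_tail_probability(self):
        background = [f"g{i}" for i in range(100)]
        term = {"term1": background[:10]}
        study = background[:5] + background[50:55]
        out = network.fisher_enrichment(study, term, background)
        row = out.iloc[0]
        assert row.fold_enrichment == pytest.approx(5.0)
        assert row.p == pytest.approx(hypergeom_tail_oracle(5, 100, 10, 10), abs=1e-12)

    def test_zero_overlap_p_is_one(self):
        background = [f"g{i}" for i in range(50)]
        out = network.fisher_enrichment(
            background[:5], {"t": background[40:]}, background
        )
        assert out.iloc[0].k_study == 0
        assert out.iloc[0].fold_enrichment == 0.0
        assert out.iloc[0].p == pytest.approx(1.0)

    def test_study_equals_background_saturates(self):
        background = [f"g{i}" for i in range(30)]
        out = network.fisher_enrichment(
            background, {"t1": background[:7], "t2": background[10:]}, background
        )
        assert np.allclose(out.fold_enrichment, 1.0)
        assert np.allclose(out.p, 1.0)

    def test_stray_study_gene_rejected(self):
        with pytest.raises(ValueError, match="stranger"):
            network.fisher_enrichment(["stranger"], {"t": ["a"]}, ["a", "b"])

    def test_empty_terms_skipped(self):
        background = [f"g{i}" for i in range(10)]
        out = network.fisher_enrichment(background[:3], {"empty": []}, background)
        assert out.empty

    @given(
        n_bg=st.integers(20, 120), frac_k=st.floats(0.05, 0.9),
        frac_n=st.floats(0.05, 0.9), seed=st.integers(0, 1000),
    )
    @settings(max_examples=50, deadline=None)
    def test_p_matches_enumeration_and_fdr_bounds(self, n_bg, frac_k, frac_n, seed):
        rng = np.random.default_rng(seed)
        background = [f"g{i}" for i in range(n_bg)]
        big_k = max(1, int(frac_k * n_bg))
        n = max(1, int(frac_n * n_bg))
        term = {"t": list(rng.choice(background, size=big_k, replace=False))}
        study = list(rng.choice(background, size=n, replace=False))
        out = network.fisher_enrichment(study, term, background)
        row = out.iloc[0]
        assert row.p == pytest.approx(
            hypergeom_tail_oracle(int(row.k_study), n_bg, big_k, n), abs=1e-12
        )
        assert row.fdr >= row.p - 1e-15


class TestPipelineRecovery:
    def test_planted_modules_fill_merged_egos(self):
        cfg = simulate.ExpressionSimConfig(
            n_genes=150, n_samples_per_tissue=200, n_tissues=2,
            target_genes=("TG01", "TG02"), module_cor=0.9,
            shared_neighbor_overlap=0.5, seed=0,
        )
        panels, truth = simulate.gen_expression_panels(cfg)
        merged = network.build_merged_egos(panels, ["TG01", "TG02"])
        for target, ego in merged.items():
            got = set(ego.neighbors.neighbor) - {"TG01", "TG02"}
            planted = set(truth[truth.target == target].neighbor)
            jaccard = len(got & planted) / len(got | planted)
            assert jaccard >= 0.9

    def test_single_tissue_merge_degenerates_to_tissue_ego(self):
        cfg = simulate.ExpressionSimConfig(
            n_genes=100, n_samples_per_tissue=150, n_tissues=1,
            target_genes=("TG01",), module_size=10, shared_neighbor_overlap=0.0, seed=1,
        )
        panels, _ = simulate.gen_expression_panels(cfg)
        expr = panels["tissue_00"]
        net = network.top_fraction_filter(
            network.wto_network(network.soft_adjacency(expr), tissue="tissue_00")
        )
        tissue_ego = network.egocentric_extract(net, "TG01")
        merged = network.merge_tissue_egos([tissue_ego])
        assert merged.neighbors.neighbor.tolist() == tissue_ego.neighbors.neighbor.tolist()
        assert np.allclose(merged.neighbors.weight, tissue_ego.neighbors.weight**2)
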