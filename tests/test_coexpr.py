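import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from modulenet import coexpr, synth
from modulenet.io import CASE, CONTROL, ExpressionMatrix


def brute_force_tom(a: np.ndarray) -> np.ndarray:
    """Double-loop reference implementation of unsigned TOM."""
    a = a.copy()
    np.fill_diagonal(a, 0.0)
    n = a.shape[0]
    k = a.sum(axis=1)
    tom = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            shared = sum(a[i, u] * a[u, j] for u in range(n) if u not in (i, j))
            tom[i, j] = (shared + a[i, j]) / (min(k[i], k[j]) + 1 - a[i, j])
    return tom


class TestTOM:
    def test_two_gene_closed_form(self):
        for a in (0.1, 0.5, 0.9):
            adj = np.array([[0.0, a], [a, 0.0]])
            tom = coexpr.tom_from_adjacency(adj)
            assert tom[0, 1] == pytest.approx(a, abs=1e-15)

    @pytest.mark.parametrize("a", [0.1, 0.5, 0.9])
    def test_equal_weight_triangle_closed_form(self, a):
        adj = np.full((3, 3), a)
        np.fill_diagonal(adj, 0.0)
        tom = coexpr.tom_from_adjacency(adj)
        # (a^2 + a) / (2a + 1 - a) = a
        off = tom[~np.eye(3, dtype=bool)]
        np.testing.assert_allclose(off, a, atol=1e-15)

    @pytest.mark.parametrize("n", [10, 20, 30])
    def test_matches_brute_force_oracle(self, n):
        rng = np.random.default_rng(n)
        a = rng.uniform(0, 1, size=(n, n))
        a = (a + a.T) / 2
        tom = coexpr.tom_from_adjacency(a)
        np.testing.assert_allclose(tom, brute_force_tom(a), atol=1e-12)

    @given(st.integers(min_value=3, max_value=12), st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None)
    def test_range_and_symmetry_property(self, n, seed):
        rng = np.random.default_rng(seed)
        a = rng.uniform(0, 1, size=(n, n))
        a = (a + a.T) / 2
        tom = coexpr.tom_from_adjacency(a)
        assert np.all((tom >= 0) & (tom <= 1))
        np.testing.assert_allclose(tom, tom.T)
        assert np.all(np.diag(tom) == 1)


class TestSoftThreshold:
    def test_singleton_power_is_forced_choice(self, default_fixture):
        expr, _ = default_fixture
        rep_lo = coexpr.pick_soft_threshold(expr, powers=[1])
        assert rep_lo.chosen_power == 1
        assert rep_lo.warning == (rep_lo.table.signed_r2.iloc[0] < 0.85)

    def test_gene_order_permutation_invariance(self, default_fixture):
        expr, _ = default_fixture
        rng = np.random.default_rng(0)
        perm = rng.permutation(expr.n_genes)
        shuffled = ExpressionMatrix(
            gene_ids=[expr.gene_ids[i] for i in perm],
            sample_ids=list(expr.sample_ids),
            values=expr.values[perm],
            condition=list(expr.condition),
        )
        r1 = coexpr.pick_soft_threshold(expr, powers=[4, 6])
        r2 = coexpr.pick_soft_threshold(shuffled, powers=[4, 6])
        assert r1.chosen_power == r2.chosen_power
        np.testing.assert_allclose(
            r1.table.signed_r2.to_numpy(), r2.table.signed_r2.to_numpy()
        )

    def test_constant_gene_is_error(self, tiny_expr):
        tiny_expr.values[0] = 3.0
        with pytest.raises(ValueError, match="constant gene"):
            coexpr.pick_soft_threshold(tiny_expr)

    def test_build_matrices_invariants(self, default_fixture):
        expr, _ = default_fixture
        m = coexpr.build_matrices(expr, 6)
        assert np.all(np.abs(m.correlation) <= 1)
        np.testing.assert_allclose(
            m.adjacency[np.triu_indices(10, 1)],
            (np.abs(m.correlation) ** 6)[np.triu_indices(10, 1)],
        )
        assert np.all(np.diag(m.dissimilarity) == 0)


class TestDetectModules:
    def test_shared_factor_modules_get_merged(self):
        # two planted blocks driven by the same latent factor
        rng = np.random.default_rng(3)
        n_samp = 20
        factor = rng.standard_normal(n_samp)
        values = 0.9 * factor + rng.normal(scale=0.3, size=(80, n_samp))
        expr = ExpressionMatrix(
            gene_ids=[f"G{i}" for i in range(80)],
            sample_ids=[f"S{i}" for i in range(n_samp)],
            values=values,
            condition=[CASE] * 10 + [CONTROL] * 10,
        )
        m = coexpr.build_matrices(expr, 4)
        part, _ = coexpr.detect_modules(m, expr, min_size=20, merge_cut=0.25)
        assert len(part.module_labels) == 1

    def test_oversized_min_size_raises(self, default_fixture, detected_modules):
        expr, _ = default_fixture
        _, matrices, _, _ = detected_modules
        with pytest.raises(ValueError, match="unassigned"):
            coexpr.detect_modules(matrices, expr, min_size=10_000)

    def test_gene_order_invariance_of_partition(self):
        expr, _ = synth.simulate_expression(
            n_genes=120, module_sizes=[40, 40], n_samples_per_condition=10, seed=5
        )
        m = coexpr.build_matrices(expr, 6)
        part1, _ = coexpr.detect_modules(m, expr, min_size=20)
        perm = np.random.default_rng(1).permutation(expr.n_genes)
        shuffled = ExpressionMatrix(
            gene_ids=[expr.gene_ids[i] for i in perm],
            sample_ids=list(expr.sample_ids),
            values=expr.values[perm],
            condition=list(expr.condition),
        )
        m2 = coexpr.build_matrices(shuffled, 6)
        part2, _ = coexpr.detect_modules(m2, shuffled, min_size=20)
        assert part1.module_of_gene == part2.module_of_gene


class TestEigengenes:
    def test_unit_norm_and_sign_rule(self, default_fixture, detected_modules):
        expr, _ = default_fixture
        _, _, partition, eigengenes = detected_modules
        idx = {g: i for i, g in enumerate(expr.gene_ids)}
        for label, me in eigengenes.eigengenes.items():
            assert np.linalg.norm(me) == pytest.approx(1.0)
            rows = [idx[g] for g in partition.members(label)]
            block = expr.values[rows]
            z = (block - block.mean(1, keepdims=True)) / block.std(1, keepdims=True)
            assert np.corrcoef(me, z.mean(axis=0))[0, 1] >= 0

    def test_sign_invariant_to_pc_flip(self, default_fixture, detected_modules):
        # flipping every gene profile flips the mean profile and the PC,
        # so the reported eigengene flips with it (sign rule tracks data)
        expr, _ = default_fixture
        _, _, partition, eigengenes = detected_modules
        label = partition.module_labels[0]
        flipped = ExpressionMatrix(
            gene_ids=list(expr.gene_ids),
            sample_ids=list(expr.sample_ids),
            values=-expr.values,
            condition=list(expr.condition),
        )
        eg2 = coexpr.compute_eigengenes(flipped, partition)
        np.testing.assert_allclose(
            eg2.eigengenes[label], -eigengenes.eigengenes[label], atol=1e-9
        )


class TestModuleTraitStats:
    def _partition_and_eigengenes(self, me, n_genes=40):
        part = coexpr.ModulePartition({f"G{i}": "M1" for i in range(n_genes)})
        es = coexpr.EigengeneSet(
            sample_ids=[f"S{i}" for i in range(len(me))], eigengenes={"M1": me}
        )
        return part, es

    def test_condition_equal_eigengene_is_perfectly_correlated(self):
        n = 12
        cond = [CASE] * 6 + [CONTROL] * 6
        me = np.array([1.0] * 6 + [0.0] * 6)
        part, es = self._partition_and_eigengenes(me)
        tab = coexpr.module_trait_stats(es, cond, set(), part, universe_size=100)
        assert tab.pearson_r.iloc[0] == pytest.approx(1.0)
        assert tab.p_corr.iloc[0] < 1e-6

    def test_disjoint_module_overlap_p_is_one(self):
        me = np.arange(8.0)
        cond = [CASE] * 4 + [CONTROL] * 4
        part, es = self._partition_and_eigengenes(me, n_genes=10)
        tab = coexpr.module_trait_stats(
            es, cond, {"X1", "X2"}, part, universe_size=100
        )
        assert tab.p_overlap.iloc[0] == 1.0

    def test_overlap_matches_enumeration_oracle(self):
        # universe 10, disease 5, module 4, overlap 4 -> C(5,4)/C(10,4)
        from itertools import combinations

        universe = [f"U{i}" for i in range(10)]
        disease = set(universe[:5])
        module_genes = universe[:4]
        count = sum(
            1
            for c in combinations(universe, 4)
            if len(set(c) & disease) >= 4
        )
        expected = count / 210
        part = coexpr.ModulePartition({g: "M1" for g in module_genes})
        me = np.arange(8.0)
        es = coexpr.EigengeneSet(
            sample_ids=[f"S{i}" for i in range(8)], eigengenes={"M1": me}
        )
        tab = coexpr.module_trait_stats(
            es, [CASE] * 4 + [CONTROL] * 4, disease, part, universe_size=10
        )
        assert tab.p_overlap.iloc[0] == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(5 / 210)

    def test_fdr_bounds_p(self, default_fixture, detected_modules):
        expr, truth = default_fixture
        _, _, partition, eigengenes = detected_modules
        tab = coexpr.module_trait_stats(
            eigengenes, expr.condition, truth.disease_genes, partition, expr.n_genes
        )
        ok = tab.dropna(subset=["p_diff"])
        assert np.all(ok.fdr_diff.to_numpy() >= ok.p_diff.to_numpy() - 1e-12)
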