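"""Hoeffding thresholds, permutation nulls, and preprocessing screens."""

import itertools
import math

import networkx as nx
import numpy as np
import pytest
from scipy.optimize import brentq

from damokle import (
    CohortPair,
    ContractError,
    DamokleParams,
    MutationMatrix,
    ParameterError,
    PermutationConfig,
    best_solution,
    count_connected_subgraphs,
    damokle,
    differential_coverage,
    fdr_epsilon,
    fwer_epsilon,
    hoeffding_bound,
    low_frequency_filter,
    mutation_burden_test,
    permutation_pvalue,
    permute_gene_null,
    permute_label_null,
    remove_gene,
    single_gene_screen,
)

from conftest import random_instance


class TestConfigValidation:
    def test_significance_config_domains(self):
        from damokle import SignificanceConfig

        SignificanceConfig(alpha=0.05)
        SignificanceConfig(alpha=0.05, nk_mode="user", nk_value=100)
        with pytest.raises(ParameterError):
            SignificanceConfig(alpha=1.5)
        with pytest.raises(ParameterError):
            SignificanceConfig(alpha=0.05, nk_mode="user")

    def test_permutation_config_domains(self):
        PermutationConfig(null_type="gene", num_permutations=1)
        with pytest.raises(ParameterError):
            PermutationConfig(null_type="bootstrap", num_permutations=10)
        with pytest.raises(ParameterError):
            PermutationConfig(null_type="label", num_permutations=0)


class TestHoeffdingBound:
    def test_vacuous_at_zero(self):
        assert hoeffding_bound(0.0, 50, 70) == 2.0

    def test_symmetric_in_cohort_sizes(self):
        assert hoeffding_bound(0.1, 100, 300) == hoeffding_bound(0.1, 300, 100)

    def test_closed_form_value(self):
        assert hoeffding_bound(0.1, 200, 200) == pytest.approx(
            2 * math.exp(-2), abs=1e-12
        )

    def test_monotone_nonincreasing(self):
        values = [hoeffding_bound(e, 80, 120) for e in np.linspace(0, 1, 21)]
        assert all(a >= b for a, b in zip(values, values[1:]))

    def test_negative_epsilon_rejected(self):
        with pytest.raises(ParameterError):
            hoeffding_bound(-0.01, 10, 10)


class TestSubnetworkCount:
    def test_single_edge(self):
        assert count_connected_subgraphs(nx.Graph([("u", "v")]), 2) == 3

    def test_triangle(self):
        G = nx.complete_graph(["a", "b", "c"])
        assert count_connected_subgraphs(G, 3) == 7

    def test_k_one_counts_vertices(self):
        G = nx.path_graph(["a", "b", "c", "d"])
        assert count_connected_subgraphs(G, 1) == 4

    def test_matches_naive_enumeration(self):
        rng = np.random.default_rng(2)
        for _ in range(5):
            G, _ = random_instance(rng)
            if G.number_of_nodes() > 9:
                continue
            k = 4
            naive = sum(
                1
                for r in range(1, k + 1)
                for sub in itertools.combinations(G.nodes, r)
                if nx.is_connected(G.subgraph(sub))
            )
            assert count_connected_subgraphs(G, k) == naive

    def test_guard(self):
        with pytest.raises(ContractError):
            count_connected_subgraphs(nx.path_graph(50), 3)


class TestCorrectedThresholds:
    def test_fwer_closed_form_example(self):
        # sqrt(ln(4) * 200 / 20000)
        assert fwer_epsilon(1, 100, 100, 0.5) == pytest.approx(0.117741, abs=1e-5)

    def test_fwer_matches_numeric_inversion(self):
        for N_k, nC, nD, alpha in [(1, 100, 100, 0.5), (250, 80, 120, 0.05),
                                   (10**6, 500, 300, 0.01)]:
            eps = fwer_epsilon(N_k, nC, nD, alpha)
            numeric = brentq(
                lambda e: N_k * hoeffding_bound(e, nC, nD) - alpha, 1e-12, 10.0,
                xtol=1e-14,
            )
            assert eps == pytest.approx(numeric, abs=1e-10)

    def test_fwer_monotone_in_nk_and_scaling(self):
        base = fwer_epsilon(100, 100, 100, 0.05)
        assert fwer_epsilon(200, 100, 100, 0.05) > base
        assert fwer_epsilon(100, 400, 400, 0.05) == pytest.approx(base / 2)

    def test_fwer_threshold_saturates_budget(self):
        eps = fwer_epsilon(500, 120, 90, 0.05)
        assert 500 * hoeffding_bound(eps, 120, 90) == pytest.approx(0.05)

    def test_fdr_single_strong_discovery_reduces_to_fwer(self):
        nC = nD = 10**5
        assert fdr_epsilon([1.0], 100, nC, nD, 0.05) == 1.0

    def test_fdr_no_satisfying_candidate(self):
        assert fdr_epsilon([0.01, 0.02], 10**9, 50, 50, 0.01) is None

    def test_fdr_candidate_scan_matches_direct_evaluation(self):
        dcs = [0.2, 0.5, 0.9]
        N_k, nC, nD, alpha = 100, 500, 500, 0.05
        got = fdr_epsilon(dcs, N_k, nC, nD, alpha)
        satisfying = [
            e for e in dcs
            if N_k * hoeffding_bound(e, nC, nD) / sum(d >= e for d in dcs) <= alpha
        ]
        assert got == min(satisfying)
        # and a dense grid finds no admissible threshold below it that would
        # admit more discoveries than the returned candidate
        for e in np.linspace(0, got, 500, endpoint=False):
            n_e = sum(d >= e for d in dcs)
            if N_k * hoeffding_bound(e, nC, nD) / n_e <= alpha:
                assert sum(d >= e for d in dcs) == sum(d >= got for d in dcs)


class TestPermutationNulls:
    def test_gene_null_preserves_pooled_totals(self, toy_pair):
        for seed in range(5):
            permuted = permute_gene_null(toy_pair, seed=seed)
            before = np.hstack([toy_pair.C.values, toy_pair.D.values]).sum(axis=1)
            after = np.hstack([permuted.C.values, permuted.D.values]).sum(axis=1)
            assert np.array_equal(before, after)
            assert permuted.C.sample_ids == toy_pair.C.sample_ids

    def test_gene_null_extremes_are_fixed_points(self):
        C = MutationMatrix(("z", "f"), ("c1", "c2"), np.array([[0, 0], [1, 1]]))
        D = MutationMatrix(("z", "f"), ("d1", "d2"), np.array([[0, 0], [1, 1]]))
        permuted = permute_gene_null(CohortPair(C=C, D=D), seed=0)
        assert not permuted.C.row("z").any() and not permuted.D.row("z").any()
        assert permuted.C.row("f").all() and permuted.D.row("f").all()

    def test_label_null_preserves_profile_multiset_and_sizes(self, toy_pair):
        permuted = permute_label_null(toy_pair, seed=4)
        assert permuted.C.n_samples == toy_pair.C.n_samples
        assert permuted.D.n_samples == toy_pair.D.n_samples
        pooled_before = np.hstack([toy_pair.C.values, toy_pair.D.values])
        pooled_after = np.hstack([permuted.C.values, permuted.D.values])
        assert sorted(map(tuple, pooled_before.T)) == sorted(map(tuple, pooled_after.T))

    def test_nulls_are_reproducible(self, toy_pair):
        for permute in (permute_gene_null, permute_label_null):
            a, b = permute(toy_pair, seed=9), permute(toy_pair, seed=9)
            assert np.array_equal(a.C.values, b.C.values)
            assert np.array_equal(a.D.values, b.D.values)


class TestPermutationPvalue:
    def test_ceiling_when_data_carry_no_signal(self):
        """All samples share one profile: every permutation ties the
        observed dc, so x = N and p = 1 under both nulls."""
        G = nx.Graph([("a", "b")])
        ones = np.ones((2, 3), dtype=bool)
        pair = CohortPair(
            C=MutationMatrix(("a", "b"), ("c0", "c1", "c2"), ones),
            D=MutationMatrix(("a", "b"), ("d0", "d1", "d2"), ones),
        )
        for null in ("gene", "label"):
            res = permutation_pvalue(
                pair, G, DamokleParams(k=2, theta=0.0),
                PermutationConfig(null_type=null, num_permutations=19, rng_seed=0),
            )
            assert res.p_value == 1.0 and res.exceedances == 19

    def test_floor_with_perfectly_separating_signal(self):
        """dc = 1 observed; no permutation replicates it (seed-fixed), so
        p = 1/(N+1)."""
        G = nx.Graph([("a", "b")])
        pair = CohortPair(
            C=MutationMatrix(("a", "b"), tuple(f"c{j}" for j in range(10)),
                             np.vstack([np.ones(10, bool), np.zeros(10, bool)])),
            D=MutationMatrix(("a", "b"), tuple(f"d{j}" for j in range(10)),
                             np.zeros((2, 10), bool)),
        )
        res = permutation_pvalue(
            pair, G, DamokleParams(k=2, theta=0.5),
            PermutationConfig(null_type="gene", num_permutations=99, rng_seed=1),
        )
        assert res.observed.dc == 1.0
        assert res.p_value == pytest.approx(1 / 100)

    def test_no_observed_solution_is_an_error(self):
        G = nx.Graph([("a", "b")])
        pair = CohortPair(
            C=MutationMatrix(("a", "b"), ("c0",), np.zeros((2, 1))),
            D=MutationMatrix(("a", "b"), ("d0",), np.zeros((2, 1))),
        )
        with pytest.raises(ContractError):
            permutation_pvalue(
                pair, G, DamokleParams(k=2, theta=0.5),
                PermutationConfig(null_type="label", num_permutations=9),
            )


class TestPreprocessing:
    def test_screen_cutoff_one_is_empty(self, toy_pair):
        assert single_gene_screen(toy_pair, 1.0) == []

    def test_screen_is_two_sided_and_sorted(self):
        C = MutationMatrix(
            ("hi", "lo", "mid"), tuple(f"c{j}" for j in range(10)),
            np.vstack([np.r_[np.ones(9), 0], np.zeros(10), np.r_[np.ones(5), np.zeros(5)]]).astype(bool),
        )
        D = MutationMatrix(
            ("hi", "lo", "mid"), tuple(f"d{j}" for j in range(10)),
            np.vstack([np.r_[np.ones(2), np.zeros(8)], np.ones(10), np.r_[np.ones(4), np.zeros(6)]]).astype(bool),
        )
        hits = single_gene_screen(CohortPair(C=C, D=D), 0.5)
        assert [g for g, _ in hits] == ["lo", "hi"]
        assert hits[0][1] == pytest.approx(-1.0)   # enriched in D, reported signed
        assert hits[1][1] == pytest.approx(0.7)

    def test_low_frequency_filter_requires_both_cohorts_below(self):
        genes = ("kept_onesided", "dropped", "kept_high")
        C = MutationMatrix(genes, tuple(f"c{j}" for j in range(12)),
                           np.vstack([np.r_[np.ones(10), np.zeros(2)],
                                      np.r_[np.ones(5), np.zeros(7)],
                                      np.ones(12)]).astype(bool))
        D = MutationMatrix(genes, tuple(f"d{j}" for j in range(12)),
                           np.vstack([np.zeros(12),
                                      np.r_[np.ones(5), np.zeros(7)],
                                      np.ones(12)]).astype(bool))
        filtered = low_frequency_filter(CohortPair(C=C, D=D), 6)
        assert filtered.gene_ids == ("kept_onesided", "kept_high")

    def test_low_frequency_filter_zero_is_identity(self, toy_pair):
        assert low_frequency_filter(toy_pair, 0).gene_ids == toy_pair.gene_ids

    def test_remove_gene_unknown_is_error(self, toy_pair):
        with pytest.raises(ContractError):
            remove_gene(toy_pair, "nope")

    def test_remove_unmutated_gene_preserves_dc(self, toy_pair):
        reduced = remove_gene(toy_pair, "c")  # c is all-zero in both cohorts
        assert differential_coverage(["a", "b"], reduced) == differential_coverage(
            ["a", "b"], toy_pair
        )

    def test_remove_only_mutated_gene_zeroes_dc(self, toy_pair):
        reduced = remove_gene(toy_pair, "a")
        assert differential_coverage(["a"], reduced) == 0.0

    def test_removing_dominant_gene_changes_best_solution(self):
        """Mirrors the screen-then-remove workflow: once the dominating
        gene is gone, the runner-up subnetwork becomes the top solution."""
        G = nx.Graph([("top", "x"), ("u", "v")])
        genes = ("top", "x", "u", "v")
        C = MutationMatrix(genes, tuple(f"c{j}" for j in range(10)),
                           np.vstack([np.ones(10), np.zeros(10),
                                      np.r_[np.ones(6), np.zeros(4)],
                                      np.zeros(10)]).astype(bool))
        D = MutationMatrix(genes, tuple(f"d{j}" for j in range(10)),
                           np.zeros((4, 10), bool))
        pair = CohortPair(C=C, D=D)
        params = DamokleParams(k=2, theta=0.2)
        assert best_solution(damokle(pair, G, params)).genes == {"top", "x"}
        reduced = remove_gene(pair, "top")
        G.remove_node("top")
        assert best_solution(damokle(reduced, G, params)).genes == {"u", "v"}

    def test_burden_identical_cohorts(self):
        vals = np.array([[1, 1, 1], [0, 1, 1], [0, 0, 1]], dtype=bool)  # burdens 1,2,3
        pair = CohortPair(
            C=MutationMatrix(("a", "b", "c"), ("c0", "c1", "c2"), vals),
            D=MutationMatrix(("a", "b", "c"), ("d0", "d1", "d2"), vals),
        )
        assert mutation_burden_test(pair) == pytest.approx(1.0)

    def test_burden_gross_shift_detected(self):
        rng = np.random.default_rng(0)
        C = MutationMatrix(tuple(f"g{i}" for i in range(40)),
                           tuple(f"c{j}" for j in range(30)),
                           rng.random((40, 30)) < 0.8)
        D = MutationMatrix(tuple(f"g{i}" for i in range(40)),
                           tuple(f"d{j}" for j in range(30)),
                           rng.random((40, 30)) < 0.05)
        assert mutation_burden_test(CohortPair(C=C, D=D)) < 1e-6

    def test_burden_requires_two_samples(self):
        pair = CohortPair(
            C=MutationMatrix(("a",), ("c0",), np.ones((1, 1))),
            D=MutationMatrix(("a",), ("d0", "d1"), np.ones((1, 2))),
        )
        with pytest.raises(ContractError):
            mutation_burden_test(pair)
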