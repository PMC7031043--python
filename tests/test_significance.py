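import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats
from statsmodels.stats.multitest import multipletests

from mediatornet import (
    PermutationConfig,
    bh_adjust,
    centrality_table,
    exhaustive_pvalues,
    make_query,
    permutation_pvalues,
    select_mediators,
    subset_betweenness,
)
from mediatornet.errors import ParameterError, SizeError, ValidationError

from conftest import random_weighted_graph, weighted_graph


@pytest.fixture
def six_gene_network():
    """Small network where every size-2 target set can be enumerated."""
    return weighted_graph(
        [
            ("S", "A", 0.9),
            ("A", "B", 0.8),
            ("A", "C", 0.5),
            ("B", "D", 0.9),
            ("C", "D", 0.7),
            ("S", "E", 0.4),
            ("E", "D", 0.6),
        ]
    )


class TestPermutationPvalues:
    def test_zero_centrality_gene_has_p_one(self, six_gene_network):
        q = make_query(six_gene_network, "S", {"D", "B"})
        p = permutation_pvalues(
            six_gene_network, q, PermutationConfig(n_permutations=200, seed=1)
        )
        bc = subset_betweenness(six_gene_network, q)
        for gene, score in bc.items():
            if score == 0.0:
                assert p[gene] == 1.0

    def test_same_seed_reproduces(self, six_gene_network):
        q = make_query(six_gene_network, "S", {"D", "B"})
        cfg = PermutationConfig(n_permutations=500, seed=99)
        p1 = permutation_pvalues(six_gene_network, q, cfg)
        p2 = permutation_pvalues(six_gene_network, q, cfg)
        pd.testing.assert_series_equal(p1, p2)

    def test_monte_carlo_matches_exhaustive(self, six_gene_network):
        """MC estimates sit within 3 binomial standard errors of the exact
        enumeration over all C(5, 2) = 10 permuted target sets."""
        q = make_query(six_gene_network, "S", {"D", "B"})
        exact = exhaustive_pvalues(six_gene_network, q)
        n = 10_000
        mc = permutation_pvalues(
            six_gene_network, q, PermutationConfig(n_permutations=n, seed=4)
        )
        for gene in exact.index:
            se = np.sqrt(exact[gene] * (1 - exact[gene]) / n)
            assert abs(mc[gene] - exact[gene]) <= 3 * se + 1e-12

    def test_add_one_smoothing(self, six_gene_network):
        q = make_query(six_gene_network, "S", {"D"})
        n = 100
        plain = permutation_pvalues(
            six_gene_network, q, PermutationConfig(n_permutations=n, seed=5)
        )
        smooth = permutation_pvalues(
            six_gene_network,
            q,
            PermutationConfig(n_permutations=n, seed=5, add_one_smoothing=True),
        )
        np.testing.assert_allclose(smooth.to_numpy(), (plain.to_numpy() * n + 1) / (n + 1))
        assert (smooth > 0).all()

    def test_universe_smaller_than_targets_rejected(self, six_gene_network):
        q = make_query(six_gene_network, "S", {"D", "B"})
        cfg = PermutationConfig(
            n_permutations=10, seed=0, candidate_universe=frozenset({"D"})
        )
        with pytest.raises(ParameterError):
            permutation_pvalues(six_gene_network, q, cfg)

    def test_degree_matched_mode_runs_and_is_deterministic(self, six_gene_network):
        q = make_query(six_gene_network, "S", {"D", "B"})
        cfg = PermutationConfig(n_permutations=300, seed=3, degree_matched=True)
        p1 = permutation_pvalues(six_gene_network, q, cfg)
        p2 = permutation_pvalues(six_gene_network, q, cfg)
        pd.testing.assert_series_equal(p1, p2)
        assert ((p1 >= 0) & (p1 <= 1)).all()


class TestExhaustivePvalues:
    def test_p_values_on_rational_grid(self, six_gene_network):
        q = make_query(six_gene_network, "S", {"D", "B"})
        exact = exhaustive_pvalues(six_gene_network, q)
        # universe = 5 non-source genes, so support is k/10
        assert all(abs(v * 10 - round(v * 10)) < 1e-12 for v in exact)

    def test_degenerate_universe_gives_all_ones(self, six_gene_network):
        q = make_query(six_gene_network, "S", {"D", "B"})
        exact = exhaustive_pvalues(six_gene_network, q, candidate_universe={"D", "B"})
        assert (exact == 1.0).all()

    def test_combinatorial_guard(self):
        g = random_weighted_graph(np.random.default_rng(0), 12, 0.5)
        nodes = sorted(g.nodes)
        q = make_query(g, nodes[0], nodes[1:7])
        with pytest.raises(SizeError):
            exhaustive_pvalues(g, q, max_combinations=10)

    def test_null_pvalues_are_superuniform(self):
        """Exact permutation p-values are stochastically >= uniform (valid
        p-values) on random graphs whose target sets are themselves drawn
        from the permutation null."""
        rng = np.random.default_rng(23)
        collected = []
        for _ in range(40):
            g = random_weighted_graph(rng, 8, 0.45)
            nodes = sorted(g.nodes)
            source = nodes[0]
            others = nodes[1:]
            targets = list(rng.choice(others, size=2, replace=False))
            try:
                q = make_query(g, source, targets)
            except ValidationError:
                continue
            exact = exhaustive_pvalues(g, q)
            collected.extend(exact[gene] for gene in exact.index if gene != source)
        assert len(collected) > 50
        # reject only if the empirical CDF rises significantly ABOVE uniform
        res = stats.kstest(collected, "uniform", alternative="greater")
        assert res.pvalue > 0.01


class TestBHAdjust:
    def test_hand_computed_step_up(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_value_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.2]), [0.2])

    def test_all_ones_stay_capped(self):
        np.testing.assert_allclose(bh_adjust([1.0, 1.0, 1.0]), [1.0, 1.0, 1.0])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            bh_adjust([0.5, 1.2])

    @settings(deadline=None, max_examples=200)
    @given(
        p=st.lists(st.floats(0.0, 1.0, allow_nan=False), min_size=1, max_size=50)
    )
    def test_agrees_with_reference_step_up(self, p):
        ours = bh_adjust(p)
        _, reference, _, _ = multipletests(p, method="fdr_bh")
        np.testing.assert_allclose(ours, reference, atol=1e-12)


class TestMediatorSelection:
    def make_table(self, fdrs, bcs=None, source="S"):
        genes = [f"G{i}" for i in range(len(fdrs))]
        table = pd.DataFrame(
            {
                "gene": genes,
                "bc": bcs if bcs is not None else [1.0] * len(fdrs),
                "p_value": fdrs,
                "fdr": fdrs,
                "mediator": [f <= 0.1 for f in fdrs],
                "in_target_set": [False] * len(fdrs),
            }
        )
        table.attrs["source"] = source
        return table

    def test_threshold_split(self):
        table = self.make_table([0.05, 0.2])
        assert select_mediators(table, fdr_threshold=0.1) == ["G0"]

    def test_empty_table(self):
        table = self.make_table([])
        assert select_mediators(table) == []

    def test_threshold_one_keeps_all_but_source(self):
        table = self.make_table([0.5, 0.9, 0.3], source="G1")
        assert set(select_mediators(table, fdr_threshold=1.0)) == {"G0", "G2"}

    def test_sorted_by_fdr_then_bc(self):
        table = self.make_table([0.05, 0.01, 0.05], bcs=[2.0, 1.0, 5.0])
        assert select_mediators(table) == ["G1", "G2", "G0"]

    def test_missing_fdr_column(self):
        with pytest.raises(ValidationError):
            select_mediators(pd.DataFrame({"gene": ["A"]}))

    def test_selection_invariant_to_row_order(self):
        table = self.make_table([0.02, 0.5, 0.08], bcs=[3.0, 1.0, 2.0])
        shuffled = table.sample(frac=1.0, random_state=1)
        shuffled.attrs["source"] = "S"
        assert select_mediators(table) == select_mediators(shuffled)


def test_centrality_table_invariants(six_gene_network):
    q = make_query(six_gene_network, "S", {"D", "B"})
    bc = subset_betweenness(six_gene_network, q)
    p = permutation_pvalues(six_gene_network, q, PermutationConfig(n_permutations=200, seed=2))
    table = centrality_table(bc, p, q, fdr_threshold=0.1)
    assert set(table.columns) == {"gene", "bc", "p_value", "fdr", "mediator", "in_target_set"}
    assert (table["fdr"] >= table["p_value"] - 1e-12).all()
    assert not table.loc[table["gene"] == "S", "mediator"].any()
    assert set(table.loc[table["in_target_set"], "gene"]) == {"D", "B"}
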