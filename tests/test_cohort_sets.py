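import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mediatornet import (
    classify_anxious_openfield,
    classify_anxious_shelter,
    flx_normalized_set,
    significant_genes,
    three_way_overlap,
)
from mediatornet.cohort_sets import classify_cohort, read_behavior_table, read_de_table
from mediatornet.errors import FormatError, ParameterError, ValidationError


def de_table(rows, contrast="Sh_vs_Gh"):
    table = pd.DataFrame(rows, columns=["gene", "log2fc", "p", "adj_p"])
    table.attrs["contrast"] = contrast
    return table


class TestSignificantGenes:
    def test_threshold_split(self):
        table = de_table([("A", 1.0, 0.001, 0.01), ("B", 1.0, 0.1, 0.2)])
        assert significant_genes(table, alpha=0.05) == {"A"}

    def test_alpha_one_keeps_all(self):
        table = de_table([("A", 1.0, 0.5, 0.9), ("B", 1.0, 0.6, 1.0)])
        assert significant_genes(table, alpha=1.0) == {"A", "B"}

    def test_empty_table(self):
        assert significant_genes(de_table([])) == set()

    def test_missing_adj_p(self):
        with pytest.raises(FormatError):
            significant_genes(pd.DataFrame({"gene": ["A"], "p": [0.1]}))

    def test_bad_alpha(self):
        with pytest.raises(ParameterError):
            significant_genes(de_table([]), alpha=0.0)


class TestFlxNormalizedSet:
    def test_plain_intersection(self):
        assert flx_normalized_set({"A", "B", "C"}, {"B", "C", "D"}) == {"B", "C"}

    def test_disjoint_sets(self):
        assert flx_normalized_set({"A"}, {"B"}) == set()

    def test_direction_consistency(self):
        stress = de_table([("B", 1.2, 0.001, 0.01), ("C", 1.2, 0.001, 0.01)])
        treatment = de_table([("B", 0.9, 0.001, 0.01), ("C", -0.9, 0.001, 0.01)])
        kept = flx_normalized_set(
            {"B", "C"},
            {"B", "C"},
            direction_tables=(stress, treatment),
            require_consistent_direction=True,
        )
        assert kept == {"B"}

    def test_direction_flag_requires_tables(self):
        with pytest.raises(ParameterError):
            flx_normalized_set({"A"}, {"A"}, require_consistent_direction=True)

    def test_directed_subset_of_plain_intersection(self):
        stress = de_table([(g, fc, 0.001, 0.01) for g, fc in [("A", 1.0), ("B", -1.0)]])
        treatment = de_table([(g, fc, 0.001, 0.01) for g, fc in [("A", -1.0), ("B", -2.0)]])
        plain = flx_normalized_set({"A", "B"}, {"A", "B"})
        directed = flx_normalized_set(
            {"A", "B"}, {"A", "B"}, direction_tables=(stress, treatment),
            require_consistent_direction=True,
        )
        assert directed <= plain


class TestThreeWayOverlap:
    def test_hand_enumeration(self):
        regions = three_way_overlap({"1", "2"}, {"2", "3"}, {"2"})
        assert regions["abc"] == 1
        assert regions["a_only"] == 1
        assert regions["b_only"] == 1
        assert regions["c_only"] == 0

    def test_identical_sets_only_center(self):
        s = {"A", "B", "C"}
        regions = three_way_overlap(s, s, s)
        assert regions["abc"] == 3
        assert regions["union"] == 3
        assert sum(regions[k] for k in ("a_only", "b_only", "c_only", "ab", "ac", "bc")) == 0

    def test_random_sets_match_membership_tabulation(self):
        rng = np.random.default_rng(3)
        pool = [f"G{i}" for i in range(300)]
        a, b, c = (set(rng.choice(pool, size=100, replace=False)) for _ in range(3))
        regions = three_way_overlap(a, b, c)
        tallies = {key: 0 for key in ("a_only", "b_only", "c_only", "ab", "ac", "bc", "abc")}
        for g in set().union(a, b, c):
            membership = (g in a, g in b, g in c)
            key = {
                (True, False, False): "a_only",
                (False, True, False): "b_only",
                (False, False, True): "c_only",
                (True, True, False): "ab",
                (True, False, True): "ac",
                (False, True, True): "bc",
                (True, True, True): "abc",
            }[membership]
            tallies[key] += 1
        for key, count in tallies.items():
            assert regions[key] == count

    @settings(deadline=None, max_examples=100)
    @given(
        a=st.sets(st.integers(0, 40)),
        b=st.sets(st.integers(0, 40)),
        c=st.sets(st.integers(0, 40)),
    )
    def test_regions_partition_the_union(self, a, b, c):
        a, b, c = (set(map(str, s)) for s in (a, b, c))
        regions = three_way_overlap(a, b, c)
        region_sum = sum(
            regions[k] for k in ("a_only", "b_only", "c_only", "ab", "ac", "bc", "abc")
        )
        assert region_sum == regions["union"] == len(a | b | c)


class TestShelterClassification:
    def test_degenerate_sem_strict_boundary(self):
        calls = classify_anxious_shelter({"x": 101.0, "y": 100.0}, [100.0, 100.0, 100.0])
        assert calls == {"x": True, "y": False}

    def test_hand_computed_sem_threshold(self):
        # controls [90, 110]: mean 100, sd 14.142, SEM 10 -> cutoff 120
        calls = classify_anxious_shelter({"a": 121.0, "b": 119.0}, [90.0, 110.0])
        assert calls == {"a": True, "b": False}

    def test_below_control_mean_never_anxious(self):
        calls = classify_anxious_shelter({"a": 50.0}, [90.0, 110.0])
        assert calls == {"a": False}

    def test_needs_two_controls(self):
        with pytest.raises(ParameterError):
            classify_anxious_shelter({"a": 100.0}, [100.0])

    @settings(deadline=None, max_examples=50)
    @given(shift=st.floats(-500, 500, allow_nan=False))
    def test_translation_equivariance(self, shift):
        controls = [80.0, 95.0, 110.0, 120.0]
        values = {"a": 130.0, "b": 100.0, "c": 118.0}
        base = classify_anxious_shelter(values, controls)
        moved = classify_anxious_shelter(
            {k: v + shift for k, v in values.items()}, [c + shift for c in controls]
        )
        assert base == moved


class TestOpenFieldClassification:
    @pytest.mark.parametrize(
        "ratio,anxious", [(0.20, True), (0.25, False), (0.60, False), (0.0, True)]
    )
    def test_threshold_rule(self, ratio, anxious):
        assert classify_anxious_openfield(ratio) is anxious

    def test_negative_ratio_rejected(self):
        with pytest.raises(ValidationError):
            classify_anxious_openfield(-0.1)


class TestTableIO:
    def test_read_de_table_round_trip(self, tmp_path):
        path = tmp_path / "de.tsv"
        de_table([("a", 1.0, 0.01, 0.02), ("b", -0.5, 0.5, 0.7)]).to_csv(
            path, sep="\t", index=False
        )
        table = read_de_table(path)
        assert list(table["gene"]) == ["A", "B"]

    def test_read_de_table_missing_column(self, tmp_path):
        path = tmp_path / "bad.tsv"
        pd.DataFrame({"gene": ["A"], "p": [0.1]}).to_csv(path, sep="\t", index=False)
        with pytest.raises(FormatError):
            read_de_table(path)

    def test_read_de_table_duplicate_gene(self, tmp_path):
        path = tmp_path / "dup.tsv"
        de_table([("A", 1.0, 0.1, 0.2), ("A", 2.0, 0.1, 0.2)]).to_csv(
            path, sep="\t", index=False
        )
        with pytest.raises(ValidationError):
            read_de_table(path)

    def test_classify_cohort(self, tmp_path):
        rows = [
            ("g1", "Gh", 100.0, 0.5),
            ("g2", "Gh", 100.0, 0.5),
            ("g3", "Gh", 100.0, 0.5),
            ("s1", "Sh", 300.0, 0.4),
            ("f1", "Sh+Flx", 100.0, 0.1),
        ]
        path = tmp_path / "behavior.csv"
        pd.DataFrame(
            rows, columns=["animal", "group", "shelter_time_s", "center_periphery_ratio"]
        ).to_csv(path, index=False)
        out = classify_cohort(read_behavior_table(path))
        by_animal = out.set_index("animal")
        assert bool(by_animal.loc["s1", "anxious_shelter"]) is True
        assert bool(by_animal.loc["g1", "anxious_shelter"]) is False
        assert bool(by_animal.loc["f1", "anxious_openfield"]) is True

    def test_shelter_time_range_validated(self, tmp_path):
        path = tmp_path / "bad.csv"
        pd.DataFrame(
            [("a", "Gh", 1200.0, 0.5)],
            columns=["animal", "group", "shelter_time_s", "center_periphery_ratio"],
        ).to_csv(path, index=False)
        with pytest.raises(ValidationError):
            read_behavior_table(path)
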