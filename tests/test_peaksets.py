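"""Peak-set/gene-set algebra, primed vs de novo classification and
intersection-independence testing."""

import math

import numpy as np
import pandas as pd
import pytest

from accessome.annotation import PeakGeneMap
from accessome.intervals import merge_to_accessome
from accessome.peaksets import (
    GeneSet,
    PeakSet,
    classify_primed_denovo_elements,
    define_accessibility_sets,
    define_expression_gene_sets,
    intersection_independence_test,
    summarize_overlap,
    threshold_select,
)


class TestAccessibilitySets:
    def test_first_union_branch_opened_at_10(self, toy_da_tables):
        sets = define_accessibility_sets(toy_da_tables)
        assert "p0" in sets["opened_by_fgf_mapk_10hpf"].members

    def test_second_union_branch_only(self, toy_da_tables):
        # p1 qualifies only through mek_act_vs_fgfr_dn up
        sets = define_accessibility_sets(toy_da_tables)
        assert "p1" in sets["opened_by_fgf_mapk_10hpf"].members

    def test_boundary_log2fc_excluded(self, toy_da_tables):
        # p2 sits exactly at log2fc = -0.5 with tiny fdr: strict inequality
        sets = define_accessibility_sets(toy_da_tables)
        assert "p2" not in sets["opened_by_fgf_mapk_10hpf"].members

    def test_closed_at_10_both_branches(self, toy_da_tables):
        sets = define_accessibility_sets(toy_da_tables)
        assert sets["closed_by_fgf_mapk_10hpf"].members == {"p3", "p4"}

    def test_18hpf_sets(self, toy_da_tables):
        sets = define_accessibility_sets(toy_da_tables)
        assert "p5" in sets["opened_by_fgf_mapk_18hpf"].members
        assert "p6" in sets["closed_by_fgf_mapk_18hpf"].members

    def test_de_novo_excludes_opened_at_10(self, toy_da_tables):
        tables = {k: v.copy() for k, v in toy_da_tables.items()}
        # make p0 also closed at 10 vs 18: must not appear in de novo
        tables["control_10_vs_18"].loc["p0"] = [-1.0, 0.001, 0.001]
        sets = define_accessibility_sets(tables)
        assert sets["de_novo"].members == {"p7"}
        assert "p0" not in sets["de_novo"].members

    def test_primed_and_de_novo_disjoint(self, toy_da_tables):
        sets = define_accessibility_sets(toy_da_tables)
        assert not (sets["primed"].members & sets["de_novo"].members)
        assert "p0" in sets["primed"].members

    def test_missing_contrast_named(self, toy_da_tables):
        tables = dict(toy_da_tables)
        del tables["control_10_vs_18"]
        with pytest.raises(KeyError, match="control_10_vs_18"):
            define_accessibility_sets(tables)

    def test_fdr_threshold_monotonicity(self, toy_da_tables):
        tight = define_accessibility_sets(toy_da_tables, fdr_threshold=0.011)
        loose = define_accessibility_sets(toy_da_tables, fdr_threshold=0.05)
        for name in tight:
            assert tight[name].members <= loose[name].members

    def test_rerun_is_identical(self, toy_da_tables):
        a = define_accessibility_sets(toy_da_tables)
        b = define_accessibility_sets(toy_da_tables)
        assert {k: v.members for k, v in a.items()} == {
            k: v.members for k, v in b.items()
        }


class TestExpressionGeneSets:
    @pytest.fixture
    def de_tables(self):
        genes = [f"g{i}" for i in range(6)]

        def table(lfc, p):
            return pd.DataFrame(
                {"log2fc": lfc, "p_value": p, "fdr": p}, index=genes
            )

        return {
            # g0 passes foxf rule; g1 sits exactly at -0.75 (excluded)
            "foxf_crispr_vs_control": table(
                [-1.4, -0.75, 0, 0, 0, 0], [0.001, 0.001, 0.9, 0.9, 0.9, 0.9]
            ),
            # g2 down in both mras contrasts -> mapk_inhibited_18
            "mras_ca_vs_control_18": table(
                [0, 0, -1.8, 0, 0, 0], [0.9, 0.9, 0.001, 0.9, 0.9, 0.9]
            ),
            "mras_ca_vs_fgfr_dn_18": table(
                [0, 0, -1.6, 1.5, 0, 0], [0.9, 0.9, 0.001, 0.001, 0.9, 0.9]
            ),
            # g3 down in fgfr_dn AND up in mras-vs-fgfr -> mapk_activated_18
            "fgfr_dn_vs_control_18": table(
                [0, 0, 0, -1.7, 0, 0], [0.9, 0.9, 0.9, 0.001, 0.9, 0.9]
            ),
            # microarray-style table: p-value thresholded, not FDR
            "fgfr_dn_vs_control_10": table(
                [0, 0, 0, 0, -1.5, 1.4], [0.9, 0.9, 0.9, 0.9, 0.01, 0.01]
            ),
        }

    def test_foxf_targets_strict_boundary(self, de_tables):
        sets = define_expression_gene_sets(de_tables)
        assert sets["foxf_targets"].members == {"g0"}

    def test_mapk_18hpf_intersections(self, de_tables):
        sets = define_expression_gene_sets(de_tables)
        assert sets["mapk_inhibited_18"].members == {"g2"}
        assert sets["mapk_activated_18"].members == {"g3"}

    def test_microarray_sets_use_raw_p(self, de_tables):
        sets = define_expression_gene_sets(de_tables)
        assert sets["mapk_activated_10"].members == {"g4"}
        assert sets["mapk_inhibited_10"].members == {"g5"}

    def test_empty_table_warns_and_yields_empty_set(self, de_tables):
        tables = dict(de_tables)
        tables["foxf_crispr_vs_control"] = pd.DataFrame(
            columns=["log2fc", "p_value", "fdr"]
        )
        with pytest.warns(UserWarning, match="empty"):
            sets = define_expression_gene_sets(tables)
        assert sets["foxf_targets"].members == set()

    def test_unknown_comparison_rejected(self, de_tables):
        with pytest.raises(KeyError, match="nope"):
            define_expression_gene_sets(
                de_tables,
                {"custom": {"rules": [("nope", "up", 1.0, 0.05, None)],
                            "combine": "union"}},
            )


class TestPrimedDenovoClassification:
    @pytest.fixture
    def setup(self):
        peaks = ["e_card", "e_asm", "e_conflict", "e_flat", "e_card_primed"]
        assoc = pd.DataFrame(
            [
                ("e_card", "g_card", 0),
                ("e_asm", "g_asm", 0),
                ("e_conflict", "g_asm", 0),
                ("e_conflict", "g_card", 0),  # associated with both programs
                ("e_flat", "g_card", 0),
                ("e_card_primed", "g_card", 0),
            ],
            columns=["peak_id", "gene_id", "distance"],
        )
        pg = PeakGeneMap(assoc, 10_000)
        da = {
            "mras_ca_vs_control_18": pd.DataFrame(
                {"log2fc": [-0.8, 0.9, 0.7, 0.0, -0.4],
                 "p_value": 0.5, "fdr": 0.5}, index=peaks
            ),
            "fgfr_dn_vs_control_18": pd.DataFrame(
                {"log2fc": [0.3, -0.6, -0.5, 0.0, 0.2],
                 "p_value": 0.5, "fdr": 0.5}, index=peaks
            ),
        }
        gene_sets = {
            "denovo_cardiac": GeneSet("denovo_cardiac", {"g_card"}, ["truth"]),
            "denovo_asm": GeneSet("denovo_asm", {"g_asm"}, ["truth"]),
        }
        peak_sets = {
            "de_novo": PeakSet("de_novo", {"e_card", "e_asm", "e_conflict", "e_flat"}, ["toy"]),
            "primed": PeakSet("primed", {"e_card_primed"}, ["toy"]),
        }
        return pg, da, gene_sets, peak_sets

    def test_singletons_classified(self, setup):
        out = classify_primed_denovo_elements(*setup)
        assert out["denovo_cardiac_accessible"].members == {"e_card"}
        assert out["denovo_asm_accessible"].members == {"e_asm"}
        assert out["primed_cardiac_accessible"].members == {"e_card_primed"}

    def test_conflicting_association_removed(self, setup):
        out = classify_primed_denovo_elements(*setup)
        # e_conflict has ASM-compatible signs but also a cardiac gene
        assert "e_conflict" not in out["denovo_asm_accessible"].members

    def test_zero_log2fc_fails_strict_sign_rule(self, setup):
        out = classify_primed_denovo_elements(*setup)
        assert "e_flat" not in out["denovo_cardiac_accessible"].members

    def test_missing_prerequisite_set_rejected(self, setup):
        pg, da, gene_sets, peak_sets = setup
        with pytest.raises(KeyError, match="primed"):
            classify_primed_denovo_elements(
                pg, da, gene_sets, {"de_novo": peak_sets["de_novo"]}
            )


def enumeration_binomial(k, n, p0):
    pmf = [math.comb(n, i) * p0**i * (1 - p0) ** (n - i) for i in range(n + 1)]
    return min(sum(p for p in pmf if p <= pmf[k] * (1 + 1e-7)), 1.0)


class TestIntersectionIndependence:
    def universe(self, n):
        intervals = [("chr1", i * 200, i * 200 + 100) for i in range(n)]
        return merge_to_accessome([intervals], {"chr1": 200 * n + 100})

    def test_expectation_met_gives_p_near_one(self):
        acc = self.universe(100)
        ids = list(acc.peak_ids)
        a = PeakSet("A", set(ids[:50]), ["toy"])
        b = PeakSet("B", set(ids[30:70]), ["toy"])  # |A&B| = 20 = 100*0.5*0.4
        out = intersection_independence_test([a, b], acc, min_sets=2)
        assert out["p_value"].iloc[0] == pytest.approx(1.0)

    def test_enriched_intersection_matches_enumeration(self):
        acc = self.universe(100)
        ids = list(acc.peak_ids)
        a = PeakSet("A", set(ids[:50]), ["toy"])
        b = PeakSet("B", set(ids[20:60]), ["toy"])  # |A&B| = 30, p0 = 0.2
        out = intersection_independence_test([a, b], acc, min_sets=2)
        assert out["k"].iloc[0] == 30
        assert out["p_value"].iloc[0] == pytest.approx(
            enumeration_binomial(30, 100, 0.2), abs=1e-12
        )

    def test_disjoint_sets_closed_form(self):
        acc = self.universe(20)
        ids = list(acc.peak_ids)
        a = PeakSet("A", set(ids[:10]), ["toy"])
        b = PeakSet("B", set(ids[10:20]), ["toy"])  # p0 = 0.25, k = 0
        out = intersection_independence_test([a, b], acc, min_sets=2)
        assert out["p_value"].iloc[0] == pytest.approx(
            enumeration_binomial(0, 20, 0.25), abs=1e-12
        )

    def test_single_set_p_is_one(self):
        acc = self.universe(50)
        a = PeakSet("A", set(list(acc.peak_ids)[:20]), ["toy"])
        out = intersection_independence_test([a], acc, min_sets=1)
        assert out["p_value"].iloc[0] == pytest.approx(1.0)

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError, match="empty universe"):
            intersection_independence_test([], set())


class TestSummarizeOverlap:
    def test_printed_ratio_arithmetic(self):
        a = {f"x{i}" for i in range(5_450)}
        b = {f"x{i}" for i in range(3_525)}
        out = summarize_overlap(a, b)
        assert out == {"intersection": 3_525, "size": 5_450, "percentage": 64.7}

    def test_subset_is_hundred_percent(self):
        a = {"p1", "p2"}
        assert summarize_overlap(a, a | {"p3"})["percentage"] == 100.0

    def test_second_printed_ratio(self):
        a = {f"x{i}" for i in range(1_252)}
        b = {f"x{i}" for i in range(486)}
        assert summarize_overlap(a, b)["percentage"] == 38.8

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError):
            summarize_overlap(set(), {"p1"})


def test_threshold_select_requires_valid_sign():
    table = pd.DataFrame({"log2fc": [1.0], "p_value": [0.01], "fdr": [0.01]},
                         index=["p0"])
    with pytest.raises(ValueError, match="sign"):
        threshold_select(table, "sideways", 0.5)


def test_rules_from_yaml_round_trip(tmp_path):
    from accessome.peaksets import rules_from_yaml

    path = tmp_path / "rules.yaml"
    path.write_text(
        "my_set:\n"
        "  rules:\n"
        "  - [foxf_crispr_vs_control, down, 0.75, 0.05, null]\n"
        "  combine: intersect\n"
    )
    rules = rules_from_yaml(path)
    genes = ["g0", "g1"]
    tables = {
        "foxf_crispr_vs_control": pd.DataFrame(
            {"log2fc": [-1.2, 0.0], "p_value": [0.001, 0.9], "fdr": [0.001, 0.9]},
            index=genes,
        )
    }
    sets = define_expression_gene_sets(tables, rules)
    assert sets["my_set"].members == {"g0"}
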