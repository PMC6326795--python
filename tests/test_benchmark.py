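"""Benchmark accounting: TP/FP/FN classification, sensitivity/specificity
formulas, criterion stratification and exact-test enrichment."""

import math

import pytest
from hypothesis import given, settings, strategies as st

from progem import (
    ReferenceAssignment,
    benchmark_run,
    classify_locus,
    criterion_sets,
    fisher_enrichment,
    sensitivity,
    specificity,
)

from oracles import fisher_two_sided


class TestClassifyLocus:
    @pytest.mark.parametrize(
        "candidates, reference, expected",
        [
            ({"A", "B", "C"}, "A", (1, 2, 0)),
            ({"B", "C"}, "A", (0, 2, 1)),
            (set(), "A", (0, 0, 1)),
        ],
    )
    def test_decomposition(self, candidates, reference, expected):
        assert classify_locus(candidates, reference) == expected


class TestSensitivity:
    @pytest.mark.parametrize(
        "n, tp, pct",
        [
            (227, 223, 98),
            (227, 216, 95),
            (227, 194, 85),
            (218, 201, 92),
            (218, 209, 96),
            (218, 180, 83),
            (227, 177, 78),
        ],
    )
    def test_reported_integer_percentages(self, n, tp, pct):
        assert round(sensitivity(n, tp)) == pct

    def test_zero_tp_is_zero(self):
        assert sensitivity(100, 0) == 0.0

    def test_zero_loci_errors(self):
        with pytest.raises(ValueError):
            sensitivity(0, 0)


class TestSpecificity:
    def test_direct_formula_evaluation(self):
        # ΣLG 100, TP 10, FP 30, FN 2 → TN 58, specificity 58/88
        assert specificity(10, 30, 2, 100) == pytest.approx(58 / 88)

    def test_no_false_positives_is_maximal(self):
        assert specificity(5, 0, 0, 50) == 1.0

    def test_zero_tn_with_fp(self):
        assert specificity(5, 10, 1, 16) == 0.0

    def test_undefined_when_tn_and_fp_zero(self):
        assert specificity(5, 0, 0, 5) is None

    def test_total_too_small_errors(self):
        with pytest.raises(ValueError):
            specificity(5, 10, 1, 10)


class TestFisherEnrichment:
    def test_identical_proportions_give_or_one(self):
        res = fisher_enrichment(
            {("l", f"g{i}") for i in range(8)} | {("l", f"t{i}") for i in range(2)},
            truth={("l", f"t{i}") for i in range(2)} | {("m", f"t{i}") for i in range(2)},
            background={("m", f"g{i}") for i in range(8)}
            | {("m", f"t{i}") for i in range(2)},
            n_tests=1,
        )
        assert res.p_raw == pytest.approx(1.0)
        assert res.ci95[0] <= res.odds_ratio <= res.ci95[1]

    def test_bonferroni_scaling(self):
        crit = {("l", "tp")}
        truth = {("l", "tp")}
        bg = {("m", f"g{i}") for i in range(30)} | {("m", "tp2")}
        res = fisher_enrichment(crit, truth | {("m", "tp2")}, crit | bg, n_tests=26)
        assert res.p_bonferroni == pytest.approx(min(1.0, res.p_raw * 26))

    def test_zero_margin_flagged_degenerate(self):
        res = fisher_enrichment(set(), {("l", "g")}, {("l", "g")}, n_tests=5)
        assert res.degenerate
        assert res.p_raw == 1.0
        assert math.isnan(res.odds_ratio)

    @given(
        a=st.integers(0, 12),
        b=st.integers(0, 12),
        c=st.integers(0, 12),
        d=st.integers(0, 12),
    )
    @settings(max_examples=200, deadline=None)
    def test_p_matches_exhaustive_enumeration(self, a, b, c, d):
        # all 2x2 tables with total <= 48; compare against a from-scratch
        # hypergeometric enumeration
        crit = {("c", f"t{i}") for i in range(a)} | {("c", f"f{i}") for i in range(b)}
        bg = {("b", f"t{i}") for i in range(c)} | {("b", f"f{i}") for i in range(d)}
        truth = {("c", f"t{i}") for i in range(a)} | {("b", f"t{i}") for i in range(c)}
        res = fisher_enrichment(crit, truth, crit | bg)
        assert res.table == ((a, b), (c, d))
        if res.degenerate:
            assert min(a + b, c + d, a + c, b + d) == 0
        else:
            assert res.p_raw == pytest.approx(
                fisher_two_sided(((a, b), (c, d))), rel=1e-8
            )


class TestCriterionSets:
    def test_nearest_criterion_one_instance_per_locus(self, sim_reports):
        sets_ = criterion_sets(sim_reports, criteria=["nearest"])
        with_genes = [r for r in sim_reports if r.candidates]
        assert len(sets_["nearest"]) == len(with_genes)

    def test_concurrent_instances_satisfy_flag(self, sim_reports):
        sets_ = criterion_sets(sim_reports, criteria=["concurrent"])
        by_rsid = {r.sentinel.rsid: r for r in sim_reports}
        for rsid, gid in sets_["concurrent"]:
            assert by_rsid[rsid].candidates[gid].is_concurrent

    def test_locus_filter_drops_whole_loci(self, sim_reports):
        moderate = {
            r.sentinel.rsid
            for r in sim_reports
            if r.sentinel_impact_max == "MODERATE"
        }
        assert moderate  # the simulation plants coding sentinels
        sets_ = criterion_sets(
            sim_reports,
            criteria=["nearest"],
            locus_filter=lambda r: r.sentinel_impact_max != "MODERATE",
        )
        assert not {rsid for rsid, _ in sets_["nearest"]} & moderate

    def test_unknown_criterion_errors(self, sim_reports):
        with pytest.raises(ValueError, match="unknown criterion"):
            criterion_sets(sim_reports, criteria=["made_up"])


class TestBenchmarkRun:
    def test_tp_plus_fn_equals_n_for_every_definition(
        self, sim_dataset, sim_reports
    ):
        summaries, _ = benchmark_run(
            sim_reports,
            sim_dataset.references,
            genes=sim_dataset.genes.subset(("protein_coding",)),
        )
        for s in summaries:
            assert s.tp + s.fn == s.n

    def test_nearest_concurrent_set_size_is_locus_count(self, sim_reports):
        sets_ = criterion_sets(sim_reports, criteria=["nearest_concurrent"])
        n_with_assignment = sum(
            1 for r in sim_reports if r.nearest_concurrent is not None
        )
        assert len(sets_["nearest_concurrent"]) == n_with_assignment

    def test_concurrent_more_specific_than_bottom_up(
        self, sim_dataset, sim_reports
    ):
        # concurrent ⊆ bottom-up with the same gene model: fewer FPs can only
        # raise TN/(TN+FP)
        summaries, _ = benchmark_run(
            sim_reports,
            sim_dataset.references,
            genes=sim_dataset.genes.subset(("protein_coding",)),
        )
        by_name = {s.name: s for s in summaries}
        assert by_name["concurrent"].fp <= by_name["bottom_up"].fp
        assert (
            by_name["concurrent"].specificity >= by_name["bottom_up"].specificity
        )

    def test_missing_reference_loci_excluded(self, sim_dataset, sim_reports):
        refs = sim_dataset.references[:10]
        summaries, _ = benchmark_run(
            sim_reports, refs, genes=sim_dataset.genes.subset(("protein_coding",))
        )
        assert all(s.n == 10 for s in summaries)

    def test_pg_mode_uses_candidate_totals(self, sim_dataset, sim_reports):
        summaries, _ = benchmark_run(
            sim_reports, sim_dataset.references, mode="pg"
        )
        total = next(s for s in summaries if s.name == "total")
        n_candidates = sum(len(r.candidates) for r in sim_reports)
        assert total.tp + total.fp + total.fn + total.tn == n_candidates
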