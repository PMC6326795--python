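"""Variant-centric candidate generation: LD ranges, nearest genes, eQTL
targets, IMPACT flags and their union."""

import pytest
from hypothesis import given, settings, strategies as st

from progem import (
    ConsequenceRecord,
    EqtlAssociation,
    GeneModel,
    GeneRecord,
    ProxyVariant,
    SentinelVariant,
    assemble_bottom_up,
    build_ld_range,
    eqtl_target_genes,
    impact_flags,
    ld_overlapping_genes,
    nearest_genes,
)


def proxy(sentinel, rsid, pos, chrom="1", r2=0.9):
    return ProxyVariant(sentinel, rsid, chrom, pos, r2)


class TestLDRange:
    def test_span_covers_proxies_plus_pad(self):
        s = SentinelVariant("rs1", "1", 1_000_000)
        proxies = [proxy("rs1", "p1", 990_000), proxy("rs1", "p2", 1_020_000)]
        r = build_ld_range(s, proxies, pad=5000)
        assert (r.start, r.end) == (985_000, 1_025_000)

    def test_no_proxies_falls_back_to_sentinel(self):
        # rs1801133-style locus: zero proxies, range is sentinel +/- pad
        s = SentinelVariant("rs1801133", "1", 11_856_378)
        r = build_ld_range(s, [], pad=5000)
        assert (r.start, r.end) == (11_851_378, 11_861_378)

    def test_clipped_at_chromosome_start(self):
        s = SentinelVariant("rs1", "1", 3_000)
        r = build_ld_range(s, [], pad=5000)
        assert (r.start, r.end) == (1, 8_000)

    def test_cross_chromosome_proxy_rejected(self):
        s = SentinelVariant("rs1", "1", 1_000_000)
        with pytest.raises(ValueError, match="chromosome"):
            build_ld_range(s, [proxy("rs1", "p1", 999_000, chrom="2")])

    def test_sentinel_included_in_span_by_default(self):
        s = SentinelVariant("rs1", "1", 2_000_000)
        proxies = [proxy("rs1", "p1", 990_000), proxy("rs1", "p2", 1_020_000)]
        r = build_ld_range(s, proxies, pad=0)
        assert r.end == 2_000_000
        r2 = build_ld_range(s, proxies, pad=0, include_sentinel=False)
        assert r2.end == 1_020_000


class TestNearestGenes:
    def test_rank_one_when_inside_gene_body(self):
        model = GeneModel([GeneRecord("A", "A", "1", 100, 200, "+")])
        s = SentinelVariant("rs1", "1", 150)
        [(g, d, rank)] = nearest_genes(s, model, k=3)
        assert (g.gene_id, d, rank) == ("A", 0, 1)

    def test_equidistant_tie_prefers_smaller_start(self):
        model = GeneModel(
            [
                GeneRecord("A", "A", "1", 100, 200, "+"),
                GeneRecord("B", "B", "1", 300, 400, "+"),
            ]
        )
        s = SentinelVariant("rs1", "1", 250)
        got = [(g.gene_id, d, r) for g, d, r in nearest_genes(s, model, k=2)]
        assert got == [("A", 50, 1), ("B", 50, 2)]

    def test_fewer_genes_than_k(self):
        model = GeneModel(
            [
                GeneRecord("A", "A", "1", 100, 200, "+"),
                GeneRecord("B", "B", "1", 300, 400, "+"),
            ]
        )
        s = SentinelVariant("rs1", "1", 150)
        assert len(nearest_genes(s, model, k=3)) == 2

    def test_empty_chromosome_gives_empty_list(self):
        model = GeneModel([GeneRecord("A", "A", "2", 100, 200, "+")])
        s = SentinelVariant("rs1", "1", 150)
        assert nearest_genes(s, model, k=3) == []


class TestOverlapAndEqtl:
    def test_single_shared_base_counts(self):
        model = GeneModel([GeneRecord("A", "A", "1", 100, 200, "+")])
        s = SentinelVariant("rs1", "1", 250)
        r_in = build_ld_range(s, [proxy("rs1", "p", 300, r2=1.0)], pad=50)
        assert r_in.start == 200
        assert [g.gene_id for g in ld_overlapping_genes(r_in, model)] == ["A"]
        model2 = GeneModel([GeneRecord("A", "A", "1", 100, 199, "+")])
        assert ld_overlapping_genes(r_in, model2) == []

    def test_eqtl_union_records_source_class_and_tissue(self):
        s = SentinelVariant("rs1", "1", 100)
        proxies = [proxy("rs1", "p1", 200)]
        eqtls = [
            EqtlAssociation("rs1", "G1", "liver"),
            EqtlAssociation("p1", "G2", "blood"),
            EqtlAssociation("rs_other", "G3", "liver"),
        ]
        out = eqtl_target_genes(s, proxies, eqtls)
        assert set(out) == {"G1", "G2"}
        assert out["G1"] == {"sentinel": {"liver"}, "proxy": set()}
        assert out["G2"] == {"sentinel": set(), "proxy": {"blood"}}

    def test_same_gene_two_tissues_one_entry(self):
        s = SentinelVariant("rs1", "1", 100)
        eqtls = [
            EqtlAssociation("rs1", "G1", "liver"),
            EqtlAssociation("rs1", "G1", "blood"),
        ]
        out = eqtl_target_genes(s, [], eqtls)
        assert out["G1"]["sentinel"] == {"liver", "blood"}


class TestImpactFlags:
    def test_sentinel_and_proxy_tracked_separately(self):
        s = SentinelVariant("rs1", "1", 100)
        proxies = [proxy("rs1", "p1", 200)]
        cons = [
            ConsequenceRecord("rs1", "A", "synonymous_variant", "LOW"),
            ConsequenceRecord("p1", "A", "missense_variant", "MODERATE"),
        ]
        flags = impact_flags(s, proxies, cons)
        assert flags["A"] == ("LOW", "MODERATE")

    def test_missing_gene_absent_from_flags(self):
        s = SentinelVariant("rs1", "1", 100)
        assert impact_flags(s, [], []) == {}


class TestAssembly:
    def make_locus(self):
        genes = GeneModel(
            [
                GeneRecord("A", "A", "1", 90, 120, "+"),
                GeneRecord("B", "B", "1", 500, 600, "+"),
                GeneRecord("C", "C", "1", 900, 1000, "+"),
                GeneRecord("D", "D", "1", 5000, 6000, "+"),
            ]
        )
        s = SentinelVariant("rs1", "1", 100)
        eqtls = [EqtlAssociation("rs1", "D", "liver")]
        cons = [ConsequenceRecord("rs1", "A", "missense_variant", "MODERATE")]
        return s, genes, eqtls, cons

    def test_union_of_three_criteria(self):
        s, genes, eqtls, cons = self.make_locus()
        bu = assemble_bottom_up(s, genes, [], eqtls, cons, k=3, pad=50)
        assert bu.gene_ids == {"A", "B", "C", "D"}
        ev = bu.genes["A"]
        assert ev.ld_overlap and ev.nearest_rank == 1
        assert ev.impact_sentinel == "MODERATE"
        assert bu.genes["D"].eqtl_sentinel_tissues == {"liver"}

    def test_all_criteria_empty_gives_empty_evidence(self):
        genes = GeneModel([GeneRecord("A", "A", "2", 90, 120, "+")])
        s = SentinelVariant("rs1", "1", 100)
        bu = assemble_bottom_up(s, genes, [], [], [], k=3, pad=50)
        assert bu.gene_ids == set()

    def test_nearest_subset_chain(self):
        s, genes, eqtls, cons = self.make_locus()
        one = {g.gene_id for g, _, _ in nearest_genes(s, genes, k=1)}
        three = {g.gene_id for g, _, _ in nearest_genes(s, genes, k=3)}
        bu = assemble_bottom_up(s, genes, [], eqtls, cons, k=3, pad=50)
        assert one <= three <= bu.gene_ids

    @given(
        pad1=st.integers(0, 10_000),
        pad2=st.integers(0, 10_000),
        k1=st.integers(1, 4),
        k2=st.integers(1, 4),
    )
    @settings(max_examples=60, deadline=None)
    def test_widening_pad_or_k_never_shrinks_set(self, pad1, pad2, k1, k2):
        s, genes, eqtls, cons = self.make_locus()
        small = assemble_bottom_up(
            s, genes, [], eqtls, cons, k=min(k1, k2), pad=min(pad1, pad2)
        )
        large = assemble_bottom_up(
            s, genes, [], eqtls, cons, k=max(k1, k2), pad=max(pad1, pad2)
        )
        assert small.gene_ids <= large.gene_ids

    def test_ld_overlap_flags_recheckable(self, sim_dataset, sim_reports):
        # every flagged gene must genuinely intersect the locus's LD range,
        # re-derived here from the raw proxy table
        by_sentinel = {}
        for p in sim_dataset.proxies:
            if p.r2 >= 0.8:
                by_sentinel.setdefault(p.sentinel_rsid, []).append(p)
        checked = 0
        for rep in sim_reports:
            rng = build_ld_range(
                rep.sentinel, by_sentinel.get(rep.sentinel.rsid, []), pad=5000
            )
            for cand in rep.candidates.values():
                if cand.ld_overlap:
                    g = cand.gene
                    assert g.chrom == rng.chrom
                    assert g.start <= rng.end and rng.start <= g.end
                    checked += 1
        assert checked > 0
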