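"""Variant assignment, ESM curation filters, enrichment stats, motif changes."""

import io
import math

import numpy as np
import pandas as pd
import pytest

from vulexmap.annotation import Transcript, build_segments
from vulexmap.variant_enrichment import (
    DEFAULT_MOTIF_SETS,
    VariantError,
    VariantRecord,
    assign_variants,
    esm_enrichment,
    filter_esm_candidates,
    load_variants,
    maf_summary,
    motif_change,
    motif_change_at,
    variant_density,
)
from vulexmap.exon_features import reverse_complement


def bed6(lines):
    return io.StringIO("\n".join(lines))


class TestLoadVariants:
    def test_three_rows_three_records(self):
        recs = load_variants(bed6([
            "chr1\t10\t11\tv1\t0\t+",
            "chr1\t20\t21\tv2\t0\t+",
            "chr2\t30\t31\tv3\t0\t-"]))
        assert len(recs) == 3
        assert recs[0].pos == 10

    def test_hgvs_like_label_parsed_for_ref_alt(self):
        (rec,) = load_variants(bed6(["chr1\t84\t85\tc.85C>A\t0\t+"]))
        assert rec.label == "c.85C>A"
        assert (rec.ref, rec.alt) == ("C", "A")
        assert rec.is_snv

    def test_empty_file_empty_set(self):
        assert load_variants(bed6([])) == []

    def test_wide_snv_interval_warns_uses_start(self):
        with pytest.warns(UserWarning):
            (rec,) = load_variants(bed6(["chr1\t10\t15\tC>T\t0\t+"]))
        assert rec.pos == 10

    def test_malformed_interval_raises(self):
        with pytest.raises(VariantError):
            load_variants(bed6(["chr1\t10\t10\tv\t0\t+"]))


@pytest.fixture
def classified_gene():
    """One 3-exon gene with a classified 101-bp cassette exon at [300,401)."""
    tx = Transcript("NM_1", "G", "chr1", "+", (100, 300, 500), (200, 401, 600))
    segments = build_segments([tx])
    (seg,) = [s for s in segments if s.is_cassette]
    classification = pd.DataFrame(
        [{"segment_id": seg.segment_id, "label": "vulnerable"}])
    return segments, classification


class TestAssignVariants:
    def test_edge_distance_first_base_is_one(self, classified_gene):
        segments, cls = classified_gene
        v = VariantRecord("chr1", 300)
        assign_variants([v], segments, cls)
        assert v.edge_distance == 1
        assert v.host_class == "vulnerable"

    def test_center_of_101bp_exon_distance_51(self, classified_gene):
        segments, cls = classified_gene
        v = VariantRecord("chr1", 350)
        assign_variants([v], segments, cls)
        assert v.edge_distance == 51

    def test_intronic_position_no_host(self, classified_gene):
        segments, cls = classified_gene
        v = VariantRecord("chr1", 250)
        assign_variants([v], segments, cls)
        assert v.host_segment is None

    def test_unannotated_chrom_warns(self, classified_gene):
        segments, cls = classified_gene
        v = VariantRecord("chrUn", 300)
        with pytest.warns(UserWarning):
            assign_variants([v], segments, cls)
        assert v.host_segment is None


class TestEsmFilters:
    def variant(self, edge=10, cls="vulnerable", new_ss=False):
        v = VariantRecord("chr1", 0)
        v.edge_distance = edge
        v.host_class = cls
        v.host_segment = "seg"
        v.creates_splice_site = new_ss
        return v

    def test_edge_variant_excluded(self):
        retained, reasons = filter_esm_candidates([self.variant(edge=2)])
        assert retained == []
        assert reasons[0] == ["splice_site_region"]

    def test_edge_four_vulnerable_retained(self):
        retained, _ = filter_esm_candidates([self.variant(edge=4)])
        assert len(retained) == 1

    def test_alternative_host_excluded(self):
        _, reasons = filter_esm_candidates([self.variant(cls="alternative")])
        assert reasons[0] == ["alternative_exon"]

    def test_new_splice_site_excluded(self):
        _, reasons = filter_esm_candidates([self.variant(new_ss=True)])
        assert reasons[0] == ["new_splice_site"]

    def test_idempotent_and_order_independent(self):
        vs = [self.variant(edge=2), self.variant(edge=10),
              self.variant(cls="alternative")]
        once, _ = filter_esm_candidates(vs)
        twice, _ = filter_esm_candidates(once)
        assert twice == once
        rev, _ = filter_esm_candidates(vs[::-1])
        assert set(id(v) for v in rev) == set(id(v) for v in once)


def fisher_oracle(a, b, c, d):
    """Two-sided Fisher p by hypergeometric enumeration over fixed margins."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2

    def pmf(x):
        return math.comb(r1, x) * math.comb(r2, c1 - x) / math.comb(n, c1)

    p_obs = pmf(a)
    return sum(pmf(x) for x in range(max(0, c1 - r2), min(r1, c1) + 1)
               if pmf(x) <= p_obs * (1 + 1e-10))


class TestEsmEnrichment:
    def test_symmetric_table_unit_stats(self):
        res = esm_enrichment([[10, 10], [10, 10]])
        assert res.odds_ratio == pytest.approx(1.0)
        assert res.fold_difference == pytest.approx(1.0)
        assert res.ci95[0] <= 1.0 <= res.ci95[1]

    def test_published_counts_fold_difference(self):
        res = esm_enrichment([[86, 72], [388, 1505]])
        assert round(res.fold_difference, 2) == 2.66

    def test_odds_ratio_is_cross_product(self):
        res = esm_enrichment([[86, 72], [388, 1505]])
        assert res.odds_ratio == pytest.approx((86 * 1505) / (72 * 388))

    def test_ci_contains_odds_ratio(self):
        res = esm_enrichment([[30, 12], [8, 40]])
        assert res.ci95[0] <= res.odds_ratio <= res.ci95[1]

    @pytest.mark.parametrize("table", [
        (7, 3, 2, 8), (10, 2, 4, 12), (1, 9, 8, 2), (5, 5, 5, 5),
        (12, 1, 3, 14),
    ])
    def test_fisher_p_matches_enumeration_oracle(self, table):
        a, b, c, d = table
        res = esm_enrichment([[a, b], [c, d]])
        assert res.p_fisher == pytest.approx(fisher_oracle(a, b, c, d), rel=1e-9)

    def test_zero_cell_haldane_correction_flagged(self):
        res = esm_enrichment([[10, 0], [5, 5]])
        assert res.zero_cell_corrected
        assert math.isfinite(res.odds_ratio)

    def test_empty_margin_rejected(self):
        with pytest.raises(VariantError):
            esm_enrichment([[0, 0], [5, 5]])


class TestVariantDensity:
    def make(self, n_variants, seg, cls_label="vulnerable", edge=10):
        vs = []
        for i in range(n_variants):
            v = VariantRecord("chr1", 300 + i)
            v.host_segment = seg.segment_id
            v.host_class = cls_label
            v.edge_distance = edge
            v.consequence = "synonymous" if i % 2 == 0 else "missense"
            vs.append(v)
        return vs

    def test_density_per_nucleotide(self, classified_gene):
        segments, cls = classified_gene
        (seg,) = [s for s in segments if s.is_cassette]
        vs = self.make(10, seg)
        df = variant_density(vs, segments, cls).set_index("class")
        assert df.loc["vulnerable", "density_per_nt"] == pytest.approx(10 / 101)

    def test_consequence_filter(self, classified_gene):
        segments, cls = classified_gene
        (seg,) = [s for s in segments if s.is_cassette]
        vs = self.make(10, seg)
        df = variant_density(vs, segments, cls,
                             consequence="synonymous").set_index("class")
        assert df.loc["vulnerable", "n_variants"] == 5

    def test_edge_exclusion_trims_six_bases(self, classified_gene):
        segments, cls = classified_gene
        (seg,) = [s for s in segments if s.is_cassette]
        vs = self.make(4, seg, edge=20)
        df = variant_density(vs, segments, cls,
                             exclude_edges=True).set_index("class")
        assert df.loc["vulnerable", "total_nt"] == 101 - 6
        assert df.loc["vulnerable", "n_variants"] == 4

    def test_duplication_invariance(self, classified_gene):
        segments, cls = classified_gene
        (seg,) = [s for s in segments if s.is_cassette]
        vs = self.make(6, seg)
        d1 = variant_density(vs, segments, cls).set_index("class")
        cls2 = pd.concat([cls, cls.assign(segment_id=cls.segment_id + "x")])
        import copy
        seg2 = copy.deepcopy(seg)
        seg2.segment_id = seg.segment_id + "x"
        d2 = variant_density(vs + self.make(6, seg2), segments + [seg2], cls2
                             ).set_index("class")
        assert d1.loc["vulnerable", "density_per_nt"] == pytest.approx(
            d2.loc["vulnerable", "density_per_nt"])


class TestMafSummary:
    def variant(self, maf, cls="vulnerable", cons="synonymous"):
        v = VariantRecord("chr1", 0, maf=maf)
        v.host_class = cls
        v.consequence = cons
        return v

    def test_single_variant_median_is_value(self):
        df = maf_summary([self.variant(0.07)])
        assert df["median_maf"].iloc[0] == pytest.approx(0.07)

    def test_three_value_median(self):
        df = maf_summary([self.variant(m) for m in (0.1, 0.2, 0.3)])
        assert df["median_maf"].iloc[0] == pytest.approx(0.2)

    def test_strata_split_by_class_and_consequence(self):
        vs = [self.variant(0.1), self.variant(0.2, cls="resilient"),
              self.variant(0.3, cons="missense")]
        df = maf_summary(vs)
        assert len(df) == 3

    def test_out_of_range_maf_warns_but_kept(self):
        with pytest.warns(UserWarning):
            df = maf_summary([self.variant(0.7)])
        assert len(df) == 1


class TestMotifChange:
    def test_tagaca_creation(self):
        # C>T at the start of CAGACA creates the hnRNPA1-binding TAGACA ESS
        mc = motif_change("TTCAGACAAA", 2, "C", "T")
        assert "TAGACA" in mc.created
        assert mc.disrupted == set()

    def test_gaagaa_disruption(self):
        # A>G turning GAAGAA into GAGGAA removes the SRSF1-binding ESE
        mc = motif_change("TTGAAGAATT", 4, "A", "G")
        assert "GAAGAA" in mc.disrupted
        assert mc.mut_window == "TTGAGGAATT"

    def test_tagg_creation_from_tggg(self):
        mc = motif_change("CCTGGGCC", 3, "G", "A")
        assert "TAGG" in mc.created
        assert "GGG" in mc.disrupted

    def test_variant_away_from_motifs_empty(self):
        mc = motif_change("ACACACACAC", 5, "C", "T")
        assert mc.created == set() == mc.disrupted

    def test_motif_elsewhere_in_window_ignored(self):
        # a pre-existing GAAGAA far from the variant must not be reported
        mc = motif_change("GAAGAA" + "CCCCC" + "ACA", 12, "C", "T")
        assert mc.created == set() == mc.disrupted

    def test_created_and_disrupted_disjoint(self):
        mc = motif_change("AGGGA", 1, "G", "A",
                          motif_sets={"g": ("GGG", "AGG")})
        assert not (mc.created & mc.disrupted)

    def test_ref_mismatch_raises(self):
        with pytest.raises(VariantError, match="mismatch"):
            motif_change("AAAA", 1, "C", "T")

    def test_reverse_complement_mirror(self):
        """The mirrored locus with mirrored motifs gives mirrored results."""
        wt, off, ref, alt = "TTCAGACAAA", 2, "C", "T"
        fwd = motif_change(wt, off, ref, alt, motif_sets={"m": ("TAGACA",)})
        rc_wt = reverse_complement(wt)
        rc_off = len(wt) - 1 - off
        mirrored = motif_change(
            rc_wt, rc_off, reverse_complement(ref), reverse_complement(alt),
            motif_sets={"m": (reverse_complement("TAGACA"),)})
        assert mirrored.created == {reverse_complement(m) for m in fwd.created}

    def test_genome_wrapper_minus_strand(self):
        # genome holds the antisense of TTCAGACAAA; variant on '-' recreates it
        genome = {"chrV": reverse_complement("TTCAGACAAA")}
        v = VariantRecord("chrV", 7, ref="G", alt="A", label="x")
        mc = motif_change_at(genome, v, strand="-",
                             motif_sets={"m": ("TAGACA",)}, flank=5)
        assert "TAGACA" in mc.created

    def test_non_snv_skipped_without_mut_window(self):
        genome = {"chrV": "ACGTACGTAC"}
        v = VariantRecord("chrV", 3, ref="TA", alt="T")
        assert motif_change_at(genome, v) is None

    def test_explicit_mut_window_for_non_snv(self):
        mc = motif_change("CCTGGCC", 3, "G", "GG", mut_window="CCTGGGCC")
        assert "GGG" in mc.created
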