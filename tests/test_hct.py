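"""DEG filtering, eligible regions, HCT calling and 2x2 statistics."""

import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hctcall.genes import GeneModel
from hctcall.hct import (
    DEGRecord,
    call_hct,
    call_norbs_hct,
    contingency_2x2,
    filter_degs,
    gene_search_region,
)
from hctcall.intervals import GenomicInterval, PeakSet

SIZES = {"chr1": 1_000_000}


def deg_frame(rows):
    return pd.DataFrame(rows, columns=["gene_id", "log2_fc", "padj"])


class TestFilterDegs:
    def test_inclusive_fc_and_strict_padj_boundaries(self):
        table = deg_frame([
            ("keep_boundary", math.log2(1.8), 0.049),
            ("drop_low_fc", math.log2(1.79), 0.01),
            ("drop_padj_at_threshold", math.log2(3.0), 0.05),
            ("keep_down", -math.log2(2.5), 0.001),
        ])
        kept = {d.gene_id: d for d in filter_degs(table)}
        assert set(kept) == {"keep_boundary", "keep_down"}
        assert kept["keep_down"].direction == "down"
        assert kept["keep_boundary"].fold_change == pytest.approx(1.8)

    def test_linear_fold_change_column_accepted(self):
        table = pd.DataFrame(
            {"gene_id": ["a", "b"], "fold_change": [2.0, 1.1], "padj": [0.01, 0.01]}
        )
        assert [d.gene_id for d in filter_degs(table)] == ["a"]

    def test_missing_column_rejected(self):
        with pytest.raises(ValueError, match="column"):
            filter_degs(pd.DataFrame({"gene_id": ["a"], "padj": [0.1]}))

    def test_padj_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="padj"):
            filter_degs(deg_frame([("a", 1.0, 1.5)]))


def gene_with_structure(gene_id, tx_start, strand="+"):
    """10 kb gene: 2 exons of 2 kb, 6 kb intron, CDS inset by 200/300 bp."""
    tx_end = tx_start + 10_000
    return GeneModel(
        gene_id, "chr1", strand, tx_start, tx_end,
        tx_start + 200, tx_end - 300,
        ((tx_start, tx_start + 2000), (tx_end - 2000, tx_end)),
    )


THREE_GENES = [
    gene_with_structure("geneA", 100_000),
    gene_with_structure("geneB", 300_000),
    gene_with_structure("geneC", 600_000),
]


def covered(intervals, pos):
    return any(iv.start <= pos < iv.end for iv in intervals)


class TestGeneSearchRegion:
    def test_flanks_end_at_neighbour_tx_boundaries(self):
        region = gene_search_region(THREE_GENES[1], THREE_GENES, SIZES)
        # upstream flank: [110_000 (geneA tx_end), 300_000); downstream flank:
        # [310_000, 600_000 (geneC tx_start))
        assert covered(region, 110_000) and covered(region, 299_999)
        assert not covered(region, 109_999)
        assert covered(region, 310_000) and covered(region, 599_999)
        assert not covered(region, 600_000)

    def test_first_gene_flank_reaches_chromosome_start(self):
        region = gene_search_region(THREE_GENES[0], THREE_GENES, SIZES)
        assert covered(region, 0)

    def test_coding_exons_excluded_but_switch_restores_them(self):
        gene = THREE_GENES[0]
        cds_mid = 101_500  # inside first coding exon, beyond the promoter
        region = gene_search_region(gene, THREE_GENES, SIZES)
        assert not covered(region, cds_mid)
        region_cds = gene_search_region(
            gene, THREE_GENES, SIZES, include_cds_exons=True
        )
        assert covered(region_cds, cds_mid)

    def test_intron_utrs_and_promoter_included(self):
        region = gene_search_region(THREE_GENES[0], THREE_GENES, SIZES)
        assert covered(region, 105_000)   # intron
        assert covered(region, 100_100)   # 5'UTR
        assert covered(region, 109_800)   # 3'UTR
        assert covered(region, 99_500)    # promoter (upstream window)

    def test_single_exon_gene_has_no_intron_in_region(self):
        gene = GeneModel(
            "solo", "chr1", "+", 400_000, 402_000, 400_100, 401_900,
            ((400_000, 402_000),),
        )
        region = gene_search_region(gene, [gene], SIZES)
        assert not covered(region, 401_000)  # CDS interior of the single exon
        assert covered(region, 400_050)      # 5'UTR
        assert covered(region, 399_000)      # promoter
        assert covered(region, 500_000)      # downstream flank to chrom end


def peak(start, end, name):
    return GenomicInterval("chr1", start, end, name=name)


class TestCallHct:
    DEGS = [
        DEGRecord("geneA", -2.0, 0.001),
        DEGRecord("geneB", 1.5, 0.002),
        DEGRecord("geneC", 2.0, 0.003),
    ]

    def test_intronic_peak_yields_hct(self):
        peaks = PeakSet("tfbs", [peak(104_000, 104_200, "p1")])
        records, skipped = call_hct(self.DEGS, peaks, THREE_GENES, SIZES)
        assert [r.gene_id for r in records] == ["geneA"]
        assert records[0].direction == "down"
        assert records[0].peak_ids == ["p1"]
        assert not skipped

    def test_coding_exon_peak_does_not_qualify(self):
        peaks = PeakSet("tfbs", [peak(101_400, 101_600, "p1")])  # CDS midpoint
        records, _ = call_hct(self.DEGS, peaks, THREE_GENES, SIZES)
        assert records == []

    def test_peak_one_base_past_neighbour_boundary_excluded(self):
        # geneB's upstream flank is [110_000, 300_000): a peak whose midpoint
        # is 109_999 sits in geneA's 3' flank, not geneB's
        inside = PeakSet("tfbs", [peak(109_900, 110_100, "p_in")])    # mid 110_000
        outside = PeakSet("tfbs", [peak(109_899, 110_099, "p_out")])  # mid 109_999
        rec_in, _ = call_hct([self.DEGS[1]], inside, THREE_GENES, SIZES)
        rec_out, _ = call_hct([self.DEGS[1]], outside, THREE_GENES, SIZES)
        assert [r.gene_id for r in rec_in] == ["geneB"]
        assert rec_out == []

    def test_deg_absent_from_annotation_skipped_with_report(self):
        degs = self.DEGS + [DEGRecord("ghost", 2.0, 0.01)]
        peaks = PeakSet("tfbs", [peak(104_000, 104_200, "p1")])
        _, skipped = call_hct(degs, peaks, THREE_GENES, SIZES)
        assert skipped == ["ghost"]

    def test_adding_peaks_never_removes_hct(self):
        base = PeakSet("tfbs", [peak(104_000, 104_200, "p1")])
        more = PeakSet(
            "tfbs", base.intervals + [peak(304_000, 304_200, "p2"),
                                      peak(604_000, 604_200, "p3")]
        )
        rec_base, _ = call_hct(self.DEGS, base, THREE_GENES, SIZES)
        rec_more, _ = call_hct(self.DEGS, more, THREE_GENES, SIZES)
        assert {r.gene_id for r in rec_base} <= {r.gene_id for r in rec_more}

    def test_norbs_list_disjoint_from_rbs_list(self):
        tfbs = PeakSet("tfbs", [peak(104_000, 104_200, "p1")])
        notfbs = PeakSet(
            "notfbs", [peak(105_000, 105_200, "q1"), peak(304_000, 304_200, "q2")]
        )
        rbs, _ = call_hct(self.DEGS, tfbs, THREE_GENES, SIZES)
        norbs, _ = call_norbs_hct(self.DEGS, rbs, notfbs, THREE_GENES, SIZES)
        assert {r.gene_id for r in rbs} == {"geneA"}
        assert {r.gene_id for r in norbs} == {"geneB"}  # geneA excluded
        assert all(r.evidence == "noRBS" for r in norbs)

    def test_category_profile_attached(self):
        peaks = PeakSet("tfbs", [peak(104_000, 104_200, "p1"),
                                 peak(105_000, 105_200, "p2")])
        records, _ = call_hct(
            self.DEGS, peaks, THREE_GENES, SIZES,
            peak_categories={"p1": 1, "p2": 7},
        )
        assert records[0].category_profile == {1, 7}


def fisher_enumeration_oracle(a, b, c, d):
    """Two-sided Fisher p by exhaustive hypergeometric enumeration with exact
    integer arithmetic (probability-mass method, 1e-7 relative tie slack)."""
    n = a + b + c + d
    r1, c1 = a + b, a + c
    denom = math.comb(n, c1)
    def prob(k):
        return Fraction(math.comb(r1, k) * math.comb(n - r1, c1 - k), denom)
    observed = prob(a)
    total = Fraction(0)
    for k in range(max(0, c1 - (n - r1)), min(r1, c1) + 1):
        p = prob(k)
        if p <= observed or abs(p - observed) <= observed * Fraction(1, 10**7):
            total += p
    return float(total)


class TestContingency:
    def test_hct_proportion_table_statistics(self):
        # down-HCT 86/150 vs up-HCT 158/475: closed form evaluated directly
        res = contingency_2x2(86, 64, 158, 317)
        n, det = 625, 86 * 317 - 64 * 158
        denom = 150 * 475 * 244 * 381
        assert res.chi2_plain == pytest.approx(n * det**2 / denom)
        assert res.chi2_yates == pytest.approx(n * (abs(det) - n / 2) ** 2 / denom)
        assert res.chi2_plain == pytest.approx(27.75, abs=0.01)
        assert res.chi2_yates == pytest.approx(26.75, abs=0.01)
        assert res.fisher_p_two_sided < 1e-5

    def test_homogeneous_table(self):
        res = contingency_2x2(10, 10, 10, 10)
        assert res.chi2_plain == 0 and res.chi2_yates == 0
        assert res.fisher_p_two_sided == pytest.approx(1.0)

    def test_perfect_separation_small_table(self):
        res = contingency_2x2(5, 0, 0, 5)
        assert res.fisher_p_two_sided == pytest.approx(2 / 252, rel=1e-9)

    def test_zero_margin_leaves_chi2_undefined(self):
        res = contingency_2x2(0, 0, 3, 4)
        assert res.chi2_plain is None and res.chi2_yates is None
        assert 0 < res.fisher_p_two_sided <= 1

    def test_negative_cell_rejected(self):
        with pytest.raises(ValueError):
            contingency_2x2(-1, 2, 3, 4)

    @given(st.integers(0, 12), st.integers(0, 12),
           st.integers(0, 12), st.integers(0, 12))
    @settings(deadline=None, max_examples=200)
    def test_fisher_matches_enumeration_and_yates_bounded(self, a, b, c, d):
        res = contingency_2x2(a, b, c, d)
        if a + b + c + d > 0:
            assert res.fisher_p_two_sided == pytest.approx(
                fisher_enumeration_oracle(a, b, c, d), rel=1e-6, abs=1e-12
            )
        if res.chi2_plain is not None:
            assert res.chi2_yates <= res.chi2_plain + 1e-12
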