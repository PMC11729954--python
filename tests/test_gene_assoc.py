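"""Closest-TSS assignment, basal-plus-extension domains, and gene grouping."""

import pytest

from hctcall.gene_assoc import (
    assign_peaks_to_domains,
    build_regulatory_domains,
    closest_tss,
    group_genes_by_location,
)
from hctcall.genes import GeneModel
from hctcall.intervals import GenomicInterval, PeakSet
from hctcall.synthetic import GeneModelSpec, generate_genome


def simple_gene(gene_id, chrom, strand, tx_start, tx_end):
    return GeneModel(
        gene_id, chrom, strand, tx_start, tx_end, tx_start, tx_end,
        ((tx_start, tx_end),),
    )


TWO_GENES = [
    simple_gene("geneA", "chr1", "+", 100_000, 101_000),
    simple_gene("geneB", "chr1", "+", 500_000, 501_000),
]
SIZES = {"chr1": 1_000_000, "chr2": 500_000}


class TestClosestTss:
    def test_nearer_tss_wins(self):
        peak = GenomicInterval("chr1", 300_100, 300_200)  # midpoint 300_150
        gene, dist = closest_tss(peak, TWO_GENES)
        assert gene == "geneB"
        assert dist == 300_150 - 500_000  # upstream of B: negative

    def test_equidistant_tie_lexicographic(self):
        peak = GenomicInterval("chr1", 299_950, 300_050)  # midpoint 300_000
        assert closest_tss(peak, TWO_GENES)[0] == "geneA"

    def test_single_gene(self):
        assert closest_tss(GenomicInterval("chr1", 0, 10), TWO_GENES[:1])[0] == "geneA"

    def test_no_gene_on_chromosome(self):
        assert closest_tss(GenomicInterval("chr2", 0, 10), TWO_GENES) == (None, None)

    def test_signed_distance_respects_strand(self):
        minus = simple_gene("geneM", "chr1", "-", 100_000, 101_000)  # TSS 101_000
        _, dist = closest_tss(GenomicInterval("chr1", 101_200, 101_300), [minus])
        # midpoint 101_250 lies 250 bases beyond the TSS, upstream on '-'
        assert dist == -250


class TestRegulatoryDomains:
    def test_two_gene_worked_example(self):
        domains = build_regulatory_domains(TWO_GENES, SIZES)
        a, b = domains["geneA"], domains["geneB"]
        assert (a.basal.start, a.basal.end) == (95_000, 101_000)
        assert (b.basal.start, b.basal.end) == (495_000, 501_000)
        assert (a.extended.start, a.extended.end) == (0, 495_000)
        assert (b.extended.start, b.extended.end) == (101_000, 1_000_000)

    def test_single_gene_capped_at_1mb(self):
        gene = simple_gene("g", "chr1", "+", 5_000_000, 5_001_000)
        domains = build_regulatory_domains([gene], {"chr1": 10_000_000})
        ext = domains["g"].extended
        assert (ext.start, ext.end) == (4_000_000, 6_000_000)

    def test_overlapping_basal_domains_clip_to_own_basal(self):
        close = [
            simple_gene("g1", "chr1", "+", 100_000, 101_000),
            simple_gene("g2", "chr1", "+", 103_000, 104_000),
        ]
        domains = build_regulatory_domains(close, SIZES)
        # g1 basal [95_000, 101_000); g2 basal [98_000, 104_000) overlaps it
        assert domains["g1"].extended.end == domains["g1"].basal.end
        assert domains["g2"].extended.start == domains["g2"].basal.start

    def test_unknown_chromosome_rejected(self):
        with pytest.raises(ValueError):
            build_regulatory_domains([simple_gene("g", "chrZ", "+", 0, 10)], SIZES)

    def test_domain_invariants_on_synthetic_genome(self):
        genome = generate_genome(
            GeneModelSpec(n_chroms=2, chrom_length=800_000, n_genes=40), seed=4
        )
        domains = build_regulatory_domains(genome.genes, genome.chrom_sizes)
        by_id = {g.gene_id: g for g in genome.genes}
        for dom in domains.values():
            gene = by_id[dom.gene_id]
            assert dom.extended.start <= dom.basal.start
            assert dom.basal.end <= dom.extended.end
            assert dom.extended.start >= max(0, gene.tss - 1_000_000)
            assert dom.extended.end <= min(
                genome.chrom_sizes[gene.chrom], gene.tss + 1_000_000
            )


class TestDomainAssignment:
    def test_midpoint_containment_single_domain(self):
        domains = build_regulatory_domains(TWO_GENES, SIZES)
        # 50_000 lies in geneA's extended domain only (B's extension stops at
        # A's basal domain end, 101_000)
        peaks = PeakSet("x", [GenomicInterval("chr1", 49_900, 50_100, name="p")])
        assigned, unassigned = assign_peaks_to_domains(peaks, domains)
        assert set(assigned) == {"geneA"} and not unassigned

    def test_point_in_overlapping_extensions_hits_both(self):
        domains = build_regulatory_domains(TWO_GENES, SIZES)
        # the span (101_000, 495_000) is covered by A's extension (to B's
        # basal) and by B's extension (to A's basal): extensions may overlap
        peaks = PeakSet("x", [GenomicInterval("chr1", 299_900, 300_100, name="p")])
        assigned, _ = assign_peaks_to_domains(peaks, domains)
        assert set(assigned) == {"geneA", "geneB"}

    def test_peak_on_gene_free_chromosome_unassigned(self):
        domains = build_regulatory_domains(TWO_GENES, SIZES)
        peaks = PeakSet("x", [GenomicInterval("chr2", 0, 100, name="p")])
        assigned, unassigned = assign_peaks_to_domains(peaks, domains)
        assert not assigned and len(unassigned) == 1


class TestGeneGrouping:
    def peaks(self, *specs):
        return [
            GenomicInterval("chr1", i * 1000, i * 1000 + 100, name=n)
            for i, n in enumerate(specs)
        ]

    LOCS = {"p_prom": "promoter", "p_prom2": "promoter",
            "p_int": "intron_intergenic", "p_oth": "other"}

    def test_three_way_grouping(self):
        gene_peaks = {
            "gP": self.peaks("p_prom", "p_prom2"),
            "gI": self.peaks("p_int"),
            "gPI": self.peaks("p_prom", "p_int"),
            "gO": self.peaks("p_oth"),
            "gEmpty": [],
        }
        groups = group_genes_by_location(gene_peaks, self.LOCS)
        assert groups["P_only"] == {"gP"}
        assert groups["I_only"] == {"gI"}
        assert groups["P_I"] == {"gPI"}
        assert groups["other_only"] == {"gO"}

    def test_groups_are_disjoint(self):
        gene_peaks = {
            "g1": self.peaks("p_prom"),
            "g2": self.peaks("p_int", "p_oth"),
        }
        groups = group_genes_by_location(gene_peaks, self.LOCS)
        all_genes = [g for s in groups.values() for g in s]
        assert len(all_genes) == len(set(all_genes)) == 2

    def test_missing_location_rejected(self):
        with pytest.raises(ValueError):
            group_genes_by_location({"g": self.peaks("unknown")}, self.LOCS)
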