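"""Generator contracts: determinism, planted-truth bookkeeping, noise limits."""

import math

import numpy as np
import pandas as pd
import pytest

from hctcall.hct import filter_degs
from hctcall.intervals import GenomicInterval
from hctcall.motifs import expand_iupac, scan_sequence
from hctcall.synthetic import (
    GeneModelSpec,
    PlantedTarget,
    generate_deg_table,
    generate_genome,
    generate_replicate_peaks,
    plant_motifs,
)

SMALL_SPEC = GeneModelSpec(n_chroms=2, chrom_length=400_000, n_genes=20)


class TestGenerateGenome:
    def test_same_seed_is_byte_identical(self):
        g1 = generate_genome(SMALL_SPEC, 5)
        g2 = generate_genome(SMALL_SPEC, 5)
        assert g1.sequences == g2.sequences
        assert g1.genes == g2.genes
        assert g1.chrom_sizes == g2.chrom_sizes

    def test_different_seed_differs(self):
        assert (
            generate_genome(SMALL_SPEC, 5).sequences
            != generate_genome(SMALL_SPEC, 6).sequences
        )

    def test_gene_count_conserved(self):
        assert len(generate_genome(SMALL_SPEC, 1).genes) == 20

    def test_genes_non_overlapping_within_chromosome(self):
        genome = generate_genome(SMALL_SPEC, 2)
        by_chrom = {}
        for g in genome.genes:
            by_chrom.setdefault(g.chrom, []).append(g)
        for genes in by_chrom.values():
            genes.sort(key=lambda g: g.tx_start)
            assert all(a.tx_end <= b.tx_start for a, b in zip(genes, genes[1:]))

    def test_infeasible_packing_rejected(self):
        spec = GeneModelSpec(n_chroms=1, chrom_length=50_000, n_genes=50)
        with pytest.raises(ValueError, match="cannot pack"):
            generate_genome(spec, 1)

    def test_single_exon_genes_have_no_introns(self):
        spec = GeneModelSpec(
            n_chroms=1, chrom_length=400_000, n_genes=10, min_exons=1, max_exons=1
        )
        genome = generate_genome(spec, 3)
        assert all(len(g.exons) == 1 and not g.introns for g in genome.genes)


def _sites_on_uniform_genome(n_sites, width=30, spacing=400, seed=9):
    length = (n_sites + 1) * spacing
    rng = np.random.default_rng(seed)
    seq = "".join(rng.choice(list("ACGT"), size=length))
    sites = [
        GenomicInterval("chr1", (i + 1) * spacing, (i + 1) * spacing + width)
        for i in range(n_sites)
    ]
    return {"chr1": seq}, sites


class TestPlantMotifs:
    WORDS = sorted(expand_iupac("RCCRCA"))

    def test_fraction_one_all_sites_scan_positive(self):
        seqs, sites = _sites_on_uniform_genome(50)
        out, results = plant_motifs(seqs, sites, "RCCRCA", 1.0, seed=1)
        assert all(has for has, _, _ in results)
        for site in sites:
            assert scan_sequence(out["chr1"][site.start:site.end], self.WORDS)

    def test_fraction_zero_no_site_scans_positive(self):
        seqs, sites = _sites_on_uniform_genome(50)
        out, results = plant_motifs(seqs, sites, "RCCRCA", 0.0, seed=1)
        assert not any(has for has, _, _ in results)
        for site in sites:
            assert not scan_sequence(out["chr1"][site.start:site.end], self.WORDS)

    def test_observed_fraction_near_071_on_2000_sites(self):
        # binomial three-sigma band: 0.71 +/- 3*sqrt(0.71*0.29/2000)
        seqs, sites = _sites_on_uniform_genome(2000, spacing=400)
        _, results = plant_motifs(seqs, sites, "RCCRCA", 0.71, seed=2)
        frac = sum(has for has, _, _ in results) / len(results)
        assert abs(frac - 0.71) <= 3 * math.sqrt(0.71 * 0.29 / 2000)

    def test_planted_words_rescanned_at_recorded_positions(self):
        seqs, sites = _sites_on_uniform_genome(200)
        out, results = plant_motifs(seqs, sites, "RCCRCA", 0.71, seed=3)
        for site, (has, word, pos) in zip(sites, results):
            segment = out["chr1"][site.start:site.end]
            hits = [site.start + h for h in scan_sequence(segment, self.WORDS)]
            if has:
                assert pos in hits
                assert out["chr1"][pos:pos + 6] == word
            else:
                assert hits == []

    def test_site_shorter_than_pattern_rejected(self):
        seqs, _ = _sites_on_uniform_genome(1)
        with pytest.raises(ValueError, match="shorter"):
            plant_motifs(seqs, [GenomicInterval("chr1", 10, 14)], "RCCRCA", 1.0, 1)


class TestGenerateReplicatePeaks:
    SIZES = {"chr1": 100_000}
    SITES = [GenomicInterval("chr1", s, s + 200) for s in range(5000, 95000, 5000)]

    def test_noise_free_limit_reproduces_truth(self):
        reps = generate_replicate_peaks(
            self.SITES, self.SIZES, n_reps=3, peak_width=200, seed=4,
            detect_prob=1.0, jitter_sd=0.0, fp_rate=0.0,
        )
        expected = [(iv.chrom, iv.start, iv.end) for iv in self.SITES]
        for rep in reps:
            assert [(iv.chrom, iv.start, iv.end) for iv in rep] == expected

    def test_zero_detection_leaves_only_false_peaks(self):
        reps = generate_replicate_peaks(
            self.SITES, self.SIZES, n_reps=2, peak_width=200, seed=4,
            detect_prob=0.0, jitter_sd=0.0, fp_rate=20.0,
        )
        for rep in reps:
            for iv in rep:
                assert all(not iv.overlaps(site) for site in self.SITES)

    def test_deterministic_given_seed(self):
        kwargs = dict(n_reps=4, peak_width=200, seed=8, detect_prob=0.7,
                      jitter_sd=15.0, fp_rate=2.0)
        r1 = generate_replicate_peaks(self.SITES, self.SIZES, **kwargs)
        r2 = generate_replicate_peaks(self.SITES, self.SIZES, **kwargs)
        assert [
            [(i.chrom, i.start, i.end) for i in rep] for rep in r1
        ] == [[(i.chrom, i.start, i.end) for i in rep] for rep in r2]

    def test_invalid_rep_count_rejected(self):
        with pytest.raises(ValueError):
            generate_replicate_peaks(self.SITES, self.SIZES, 0, 200, 1)


class TestGenerateDegTable:
    GENES = [f"gene{i:03d}" for i in range(100)]
    TARGETS = [
        PlantedTarget("gene005", "down", "RBS"),
        PlantedTarget("gene010", "up", "RBS"),
        PlantedTarget("gene020", "up", "noRBS"),
    ]

    def test_planted_set_recovered_exactly_without_false_positives(self):
        table, fp = generate_deg_table(self.GENES, self.TARGETS, seed=1)
        assert fp == []
        degs = filter_degs(table, min_fc=1.8, max_padj=0.05)
        assert {d.gene_id for d in degs} == {t.gene_id for t in self.TARGETS}
        by_id = {d.gene_id: d.direction for d in degs}
        assert by_id["gene005"] == "down" and by_id["gene010"] == "up"

    def test_deg_count_is_planted_plus_false_positives(self):
        table, fp = generate_deg_table(
            self.GENES, self.TARGETS, seed=2, fp_deg_frac=0.1
        )
        degs = filter_degs(table, min_fc=1.8, max_padj=0.05)
        assert {d.gene_id for d in degs} == {t.gene_id for t in self.TARGETS} | set(fp)

    def test_same_seed_identical_table(self):
        t1, _ = generate_deg_table(self.GENES, self.TARGETS, seed=3)
        t2, _ = generate_deg_table(self.GENES, self.TARGETS, seed=3)
        pd.testing.assert_frame_equal(t1, t2)

    def test_unknown_target_rejected(self):
        with pytest.raises(ValueError):
            generate_deg_table(self.GENES, [PlantedTarget("nope", "up", "RBS")], 1)
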