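import pytest

from hctcall.genes import GeneModel
from hctcall.study import StudyConfig, build_study
from hctcall.synthetic import GeneModelSpec


@pytest.fixture
def chrom_sizes():
    return {"chr1": 1_000_000, "chr2": 500_000}


@pytest.fixture
def three_gene_layout():
    """Three well-separated genes on chr1 with known structure.

    geneA (+): tx 100_000-110_000, exons at both ends, CDS inset.
    geneB (+): tx 300_000-310_000.
    geneC (-): tx 600_000-612_000.
    """
    def make(gene_id, strand, tx_start, tx_end):
        # two exons of 2 kb with one intron spanning the middle
        exons = ((tx_start, tx_start + 2000), (tx_end - 2000, tx_end))
        return GeneModel(
            gene_id=gene_id,
            chrom="chr1",
            strand=strand,
            tx_start=tx_start,
            tx_end=tx_end,
            cds_start=tx_start + 200,
            cds_end=tx_end - 300,
            exons=exons,
        )

    return [
        make("geneA", "+", 100_000, 110_000),
        make("geneB", "+", 300_000, 310_000),
        make("geneC", "-", 600_000, 612_000),
    ]


SMALL_STUDY = StudyConfig(
    genome=GeneModelSpec(n_chroms=2, chrom_length=1_500_000, n_genes=120),
    n_rbs_targets_down=8,
    n_rbs_targets_up=12,
    n_norbs_targets_down=2,
    n_norbs_targets_up=3,
    n_extra_degs_down=5,
    n_extra_degs_up=20,
    n_bg_focal_sites=60,
    n_brn3a_sites=120,
    n_isl1_sites=40,
    n_bg_atac_sites=120,
    n_bg_k27_sites=30,
    n_repeat_regions=30,
    n_blacklist_regions=5,
    n_decoy_sites=6,
)

NOISELESS_STUDY = StudyConfig(
    genome=GeneModelSpec(n_chroms=2, chrom_length=1_500_000, n_genes=120),
    n_rbs_targets_down=8,
    n_rbs_targets_up=12,
    n_norbs_targets_down=2,
    n_norbs_targets_up=3,
    n_extra_degs_down=0,
    n_extra_degs_up=0,
    n_bg_focal_sites=0,
    n_brn3a_sites=30,
    n_isl1_sites=10,
    n_bg_atac_sites=40,
    n_bg_k27_sites=10,
    n_repeat_regions=0,
    n_blacklist_regions=0,
    n_decoy_sites=0,
    detect_prob=1.0,
    jitter_sd=0.0,
    fp_rate=0.0,
)


@pytest.fixture(scope="session")
def small_study():
    """A reduced-size synthetic study shared across integration tests."""
    return build_study(7, SMALL_STUDY)


@pytest.fixture(scope="session")
def noiseless_study():
    """Noise-free study: detection certain, no jitter, no false peaks, no
    background sites — planted truth must be recovered exactly."""
    return build_study(11, NOISELESS_STUDY)
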