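"""Assembly of a full synthetic study and the end-to-end pipeline over it.

:func:`build_study` emulates, at desk scale, a replicated CUT&RUN / ATAC /
H3K27Ac / RNA-seq experiment on a miniature genome: planted binding sites
for a focal TF (Runx3) and two partner TFs (Brn3a, Isl1) with co-binding
structure, chromatin co-marking drawn per site class, repeat/blacklist decoy
tracks, and a DEG table whose direct targets are planted inside the genes'
eligible regions. :func:`run_pipeline` then executes every stage of the
analysis — consensus, filtering, motif annotation, location/state/category
classification, regulatory domains, HCT calling, clustering and statistics —
returning all intermediate products for inspection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .annotate import (
    CooccupancyResult,
    LocationAnnotator,
    assign_chromatin_state,
    categorize_cooccupancy,
    coarse_location,
)
from .config import PipelineConfig
from .consensus import consensus_peaks, filter_blacklist, filter_repeat_overlap
from .cluster_report import build_category_matrix, kmeans_cluster, ks_two_sample
from .gene_assoc import (
    assign_peaks_to_domains,
    build_regulatory_domains,
    group_genes_by_location,
)
from .genes import GeneModel
from .hct import (
    DEGRecord,
    HCTRecord,
    call_hct,
    call_norbs_hct,
    contingency_2x2,
    filter_degs,
)
from .intervals import (
    ChromSizes,
    GenomicInterval,
    PeakIndex,
    PeakSet,
    merge_union,
    resize_centered,
)
from .motifs import MotifSpec, scan_peak_motifs, split_by_motif
from .synthetic import (
    GeneModelSpec,
    PlantedSite,
    PlantedTarget,
    SyntheticGenome,
    SyntheticTruth,
    child_seed,
    generate_deg_table,
    generate_genome,
    generate_replicate_peaks,
    generate_signal_table,
    plant_motifs,
)

__all__ = ["StudyConfig", "StudyData", "PipelineResult", "build_study", "run_pipeline",
           "recovery_metrics"]


@dataclass
class StudyConfig:
    """Scaled-down study conditions for the synthetic experiment.

    Defaults emulate the structure of the real study at roughly 1/40 of its
    genomic scale: a 12 Mb genome with 600 genes, ~540 focal-TF sites of
    which 71% bear the consensus motif, replicate designs of 8/3/5/3/2
    (focal TF / open chromatin / H3K27Ac / Isl1 / Brn3a), and ~200 DEGs of
    which 92 are planted direct targets.
    """

    genome: GeneModelSpec = field(default_factory=GeneModelSpec)
    # planted targets (direct-regulation truth)
    n_rbs_targets_down: int = 28
    n_rbs_targets_up: int = 52
    n_norbs_targets_down: int = 4
    n_norbs_targets_up: int = 8
    # DEGs without a planted focal-TF site, split by direction to mirror the
    # down/up asymmetry of the emulated experiment
    n_extra_degs_down: int = 18
    n_extra_degs_up: int = 98
    fp_deg_frac: float = 0.0
    fc_effect: float = 2.0
    # planted binding sites (densities per gene mirror the emulated study)
    n_bg_focal_sites: int = 250
    focal_promoter_frac: float = 0.35  # background focal sites in promoters
    n_brn3a_sites: int = 700
    n_isl1_sites: int = 150
    site_width: int = 200
    rbs_fraction: float = 0.71
    partner_motif_fraction: float = 0.72
    cobind_brn3a: float = 0.30         # P(partner co-binds a focal site)
    cobind_isl1_given_brn3a: float = 0.57
    cobind_isl1_alone: float = 0.05
    brn3a_isl1_pair_frac: float = 0.25  # Brn3a-only sites that get an Isl1 partner
    # chromatin co-marking per site class (promoter vs intron/intergenic)
    promoter_state_probs: Dict[str, float] = field(
        default_factory=lambda: {"ATAC_K27": 0.90, "ATAC_only": 0.08, "none": 0.02}
    )
    distal_state_probs: Dict[str, float] = field(
        default_factory=lambda: {
            "ATAC_K27": 0.35,
            "ATAC_only": 0.26,
            "K27_only": 0.04,
            "none": 0.35,
        }
    )
    p_promoter_atac: float = 0.85      # background accessible gene promoters
    p_promoter_k27_given_atac: float = 0.88
    n_bg_atac_sites: int = 600
    p_bg_atac_k27: float = 0.44
    n_bg_k27_sites: int = 100
    # replicate noise model
    detect_prob: float = 0.8
    jitter_sd: float = 20.0
    fp_rate: float = 0.5               # false peaks per Mb per replicate
    replicate_design: Dict[str, int] = field(
        default_factory=lambda: {
            "Runx3": 8, "ATAC": 3, "H3K27Ac": 5, "Isl1": 3, "Brn3a": 2
        }
    )
    peak_widths: Dict[str, int] = field(
        default_factory=lambda: {
            "Runx3": 200, "ATAC": 400, "H3K27Ac": 600, "Isl1": 200, "Brn3a": 200
        }
    )
    # decoy artefact tracks
    n_repeat_regions: int = 120
    n_blacklist_regions: int = 15
    n_decoy_sites: int = 20            # focal-TF sites planted inside repeats


@dataclass
class StudyData:
    seed: int
    genome: SyntheticGenome
    replicates: Dict[str, List[PeakSet]]
    repeats: PeakSet
    blacklist: PeakSet
    deg_table: pd.DataFrame
    truth: SyntheticTruth
    config: StudyConfig


@dataclass
class PipelineResult:
    consensus: Dict[str, PeakSet]
    focal_tfbs: PeakSet
    focal_notfbs: PeakSet
    partner_tfbs: Dict[str, PeakSet]
    peak_locations: Dict[str, str]          # focal consensus peak -> fine location
    peak_states: Dict[str, str]             # focal TFBS peak -> chromatin state
    cooccupancy: CooccupancyResult
    gene_groups: Dict[str, Set[str]]        # P_only / I_only / P_I over focal TFBS
    degs: List[DEGRecord]
    hct_rbs: List[HCTRecord]
    hct_norbs: List[HCTRecord]
    skipped_degs: List[str]
    clusters: Dict[str, pd.Series]
    contingency: object
    signal_table: pd.DataFrame
    ks_signal: Tuple[float, float]


def _place_nonoverlapping(
    n: int,
    width: int,
    chrom_sizes: ChromSizes,
    rng: np.random.Generator,
    occupied: List[GenomicInterval],
    within: Optional[List[GenomicInterval]] = None,
) -> List[GenomicInterval]:
    """Uniformly place ``n`` intervals avoiding ``occupied`` (and each other),
    optionally restricted to the ``within`` intervals."""
    index = PeakIndex(occupied)
    chroms = list(chrom_sizes)
    weights = np.array([chrom_sizes[c] for c in chroms], dtype=float)
    weights /= weights.sum()
    placed: List[GenomicInterval] = []
    tries = 0
    while len(placed) < n:
        tries += 1
        if tries > 200 * max(1, n):
            raise RuntimeError("could not place sites without overlap")
        if within:
            host = within[int(rng.integers(0, len(within)))]
            if len(host) <= width:
                continue
            start = int(rng.integers(host.start, host.end - width))
            candidate = GenomicInterval(host.chrom, start, start + width)
        else:
            chrom = chroms[int(rng.choice(len(chroms), p=weights))]
            start = int(rng.integers(0, chrom_sizes[chrom] - width))
            candidate = GenomicInterval(chrom, start, start + width)
        if index.any_overlap(candidate):
            continue
        placed.append(candidate)
        occupied.append(candidate)
        index.add(candidate)
    return placed


def _offset_site(
    site: GenomicInterval, rng: np.random.Generator, chrom_sizes: ChromSizes,
    width: int, max_shift: int = 50
) -> GenomicInterval:
    centre = site.midpoint + int(rng.integers(-max_shift, max_shift + 1))
    start = max(0, centre - width // 2)
    end = min(chrom_sizes[site.chrom], start + width)
    return GenomicInterval(site.chrom, start, end)


def build_study(seed: int, cfg: Optional[StudyConfig] = None) -> StudyData:
    """Generate a complete synthetic study with its ground-truth manifest."""
    cfg = cfg or StudyConfig()
    genome = generate_genome(cfg.genome, seed)
    chrom_sizes = genome.chrom_sizes
    rng = np.random.default_rng(child_seed(seed, 10))
    genes = genome.genes
    gene_ids = [g.gene_id for g in genes]

    # --- planted direct targets: one focal-TF site in an intron (or the
    # promoter window for intron-less genes) of each target gene
    n_targets = (
        cfg.n_rbs_targets_down
        + cfg.n_rbs_targets_up
        + cfg.n_norbs_targets_down
        + cfg.n_norbs_targets_up
    )
    n_extra = cfg.n_extra_degs_down + cfg.n_extra_degs_up
    if n_targets + n_extra > len(genes):
        raise ValueError("not enough genes for the requested targets/DEGs")
    chosen = rng.choice(len(genes), size=n_targets + n_extra, replace=False)
    target_genes = [genes[i] for i in chosen[:n_targets]]
    extra_deg_genes = [genes[i].gene_id for i in chosen[n_targets:]]
    extra_deg_directions = dict(
        zip(
            extra_deg_genes,
            ["down"] * cfg.n_extra_degs_down + ["up"] * cfg.n_extra_degs_up,
        )
    )

    directions = (
        ["down"] * cfg.n_rbs_targets_down
        + ["up"] * cfg.n_rbs_targets_up
        + ["down"] * cfg.n_norbs_targets_down
        + ["up"] * cfg.n_norbs_targets_up
    )
    evidences = (
        ["RBS"] * (cfg.n_rbs_targets_down + cfg.n_rbs_targets_up)
        + ["noRBS"] * (cfg.n_norbs_targets_down + cfg.n_norbs_targets_up)
    )

    occupied: List[GenomicInterval] = []
    target_sites: List[GenomicInterval] = []
    planted_targets: List[PlantedTarget] = []
    site_flags: List[bool] = []
    for gene, direction, evidence in zip(target_genes, directions, evidences):
        hosts = [iv for iv in gene.introns if len(iv) >= cfg.site_width + 40]
        host = (
            hosts[int(rng.integers(0, len(hosts)))]
            if hosts
            else gene.promoter(1000, 1000, chrom_sizes)
        )
        start = int(rng.integers(host.start, host.end - cfg.site_width))
        site = GenomicInterval(gene.chrom, start, start + cfg.site_width)
        target_sites.append(site)
        occupied.append(site)
        planted_targets.append(PlantedTarget(gene.gene_id, direction, evidence))
        site_flags.append(evidence == "RBS")

    # --- background focal-TF sites (a promoter-resident fraction mirrors the
    # emulated TF's genomic distribution) and decoys inside repeat regions
    promoter_windows = [g.promoter(1000, 1000, chrom_sizes) for g in genes]
    n_bg_prom = int(round(cfg.focal_promoter_frac * cfg.n_bg_focal_sites))
    bg_sites = _place_nonoverlapping(
        n_bg_prom, cfg.site_width, chrom_sizes, rng, occupied,
        within=promoter_windows,
    )
    bg_sites += _place_nonoverlapping(
        cfg.n_bg_focal_sites - n_bg_prom, cfg.site_width, chrom_sizes, rng, occupied
    )
    repeat_regions = _place_nonoverlapping(
        cfg.n_repeat_regions, 2000, chrom_sizes, rng, occupied
    )
    decoy_sites = []
    for _ in range(cfg.n_decoy_sites):
        host = repeat_regions[int(rng.integers(0, len(repeat_regions)))]
        start = int(rng.integers(host.start, host.end - cfg.site_width))
        decoy_sites.append(GenomicInterval(host.chrom, start, start + cfg.site_width))
    blacklist_regions = _place_nonoverlapping(
        cfg.n_blacklist_regions, 3000, chrom_sizes, rng, occupied
    )

    focal_sites = target_sites + bg_sites + decoy_sites
    focal_flags: List[Optional[bool]] = list(site_flags) + [None] * (
        len(bg_sites) + len(decoy_sites)
    )

    # --- partner TF sites: co-binding at focal sites plus independent sites
    brn3a_sites: List[GenomicInterval] = []
    isl1_sites: List[GenomicInterval] = []
    for site in focal_sites:
        has_b = rng.random() < cfg.cobind_brn3a
        p_i = cfg.cobind_isl1_given_brn3a if has_b else cfg.cobind_isl1_alone
        has_i = rng.random() < p_i
        if has_b:
            brn3a_sites.append(
                _offset_site(site, rng, chrom_sizes, cfg.site_width)
            )
        if has_i:
            isl1_sites.append(_offset_site(site, rng, chrom_sizes, cfg.site_width))
    indep_brn3a = _place_nonoverlapping(
        cfg.n_brn3a_sites, cfg.site_width, chrom_sizes, rng, occupied
    )
    brn3a_sites += indep_brn3a
    for site in indep_brn3a:
        if rng.random() < cfg.brn3a_isl1_pair_frac:
            isl1_sites.append(_offset_site(site, rng, chrom_sizes, cfg.site_width))
    isl1_sites += _place_nonoverlapping(
        cfg.n_isl1_sites, cfg.site_width, chrom_sizes, rng, occupied
    )

    # --- plant motifs (focal pattern RCCRCA; partner placeholder patterns)
    from .config import DEFAULT_MOTIFS

    def word_intervals(sites, results, k):
        return [
            GenomicInterval(site.chrom, pos, pos + k)
            for site, (has, _, pos) in zip(sites, results)
            if has
        ]

    seqs, focal_results = plant_motifs(
        genome.sequences, focal_sites, DEFAULT_MOTIFS["Runx3"],
        cfg.rbs_fraction, child_seed(seed, 11), force_flags=focal_flags,
    )
    planted_words = word_intervals(
        focal_sites, focal_results, len(DEFAULT_MOTIFS["Runx3"])
    )
    seqs, brn3a_results = plant_motifs(
        seqs, brn3a_sites, DEFAULT_MOTIFS["Brn3a"],
        cfg.partner_motif_fraction, child_seed(seed, 12),
        protected=planted_words,
    )
    planted_words += word_intervals(
        brn3a_sites, brn3a_results, len(DEFAULT_MOTIFS["Brn3a"])
    )
    seqs, isl1_results = plant_motifs(
        seqs, isl1_sites, DEFAULT_MOTIFS["Isl1"],
        cfg.partner_motif_fraction, child_seed(seed, 13),
        protected=planted_words,
    )
    genome = SyntheticGenome(chrom_sizes, genes, seqs)

    # --- chromatin-mark truth sites
    promoter_index = PeakIndex(g.promoter(1000, 1000, chrom_sizes) for g in genes)

    def site_class(iv: GenomicInterval) -> str:
        return "promoter" if promoter_index.at_point(iv.chrom, iv.midpoint) else "distal"

    atac_sites: List[GenomicInterval] = []
    k27_sites: List[GenomicInterval] = []
    for g in genes:
        if rng.random() < cfg.p_promoter_atac:
            prom = g.promoter(200, 200, chrom_sizes)
            atac_sites.append(prom)
            if rng.random() < cfg.p_promoter_k27_given_atac:
                k27_sites.append(g.promoter(300, 300, chrom_sizes))
    for site in focal_sites + brn3a_sites + isl1_sites:
        probs = (
            cfg.promoter_state_probs
            if site_class(site) == "promoter"
            else cfg.distal_state_probs
        )
        states = sorted(probs)
        draw = str(rng.choice(states, p=[probs[s] for s in states]))
        if draw in ("ATAC_only", "ATAC_K27"):
            atac_sites.append(site)
        if draw in ("K27_only", "ATAC_K27"):
            k27_sites.append(site)
    atac_sites += _place_nonoverlapping(
        cfg.n_bg_atac_sites, 300, chrom_sizes, rng, occupied
    )
    for site in atac_sites[-cfg.n_bg_atac_sites:]:
        if rng.random() < cfg.p_bg_atac_k27:
            k27_sites.append(site)
    k27_sites += _place_nonoverlapping(
        cfg.n_bg_k27_sites, 400, chrom_sizes, rng, occupied
    )

    # --- replicates
    replicates: Dict[str, List[PeakSet]] = {}
    site_map = {
        "Runx3": focal_sites,
        "Brn3a": brn3a_sites,
        "Isl1": isl1_sites,
        "ATAC": atac_sites,
        "H3K27Ac": k27_sites,
    }
    for ds, sites in site_map.items():
        replicates[ds] = generate_replicate_peaks(
            sites,
            chrom_sizes,
            n_reps=cfg.replicate_design[ds],
            peak_width=cfg.peak_widths[ds],
            seed=child_seed(seed, 20 + list(site_map).index(ds)),
            detect_prob=cfg.detect_prob,
            jitter_sd=cfg.jitter_sd,
            fp_rate=cfg.fp_rate,
            label=ds,
        )

    # --- DEG table
    deg_table, fp_genes = generate_deg_table(
        gene_ids,
        planted_targets,
        seed=child_seed(seed, 30),
        fc_effect=cfg.fc_effect,
        extra_degs=extra_deg_directions,
        fp_deg_frac=cfg.fp_deg_frac,
    )

    truth = SyntheticTruth(
        seed=seed,
        planted_sites={
            "Runx3": [
                PlantedSite("Runx3", iv, has, word, pos, site_class(iv))
                for iv, (has, word, pos) in zip(focal_sites, focal_results)
            ],
            "Brn3a": [
                PlantedSite("Brn3a", iv, has, word, pos)
                for iv, (has, word, pos) in zip(brn3a_sites, brn3a_results)
            ],
            "Isl1": [
                PlantedSite("Isl1", iv, has, word, pos)
                for iv, (has, word, pos) in zip(isl1_sites, isl1_results)
            ],
        },
        planted_targets=planted_targets,
        detect_prob=cfg.detect_prob,
        fp_rate=cfg.fp_rate,
        jitter_sd=cfg.jitter_sd,
        rbs_fraction=cfg.rbs_fraction,
        comark_probs={
            "promoter": dict(cfg.promoter_state_probs),
            "distal": dict(cfg.distal_state_probs),
        },
        deg_false_positives=fp_genes,
        extra_degs=extra_deg_genes,
    )
    return StudyData(
        seed=seed,
        genome=genome,
        replicates=replicates,
        repeats=PeakSet("repeats", repeat_regions).sorted(),
        blacklist=PeakSet("blacklist", blacklist_regions).sorted(),
        deg_table=deg_table,
        truth=truth,
        config=cfg,
    )


def run_pipeline(
    study: StudyData, cfg: Optional[PipelineConfig] = None
) -> PipelineResult:
    """Execute every analysis stage on a study's data."""
    cfg = cfg or PipelineConfig()
    chrom_sizes = study.genome.chrom_sizes
    genes = study.genome.genes

    # 1. consensus + artefact filters per dataset
    consensus: Dict[str, PeakSet] = {}
    for ds, reps in study.replicates.items():
        quorum, n_expected = cfg.quorum_table[ds]
        cons = consensus_peaks(reps, quorum=quorum, share_frac=cfg.share_frac)
        cons = filter_repeat_overlap(cons, study.repeats, cfg.repeat_max_frac)
        cons = filter_blacklist(cons, study.blacklist)
        consensus[ds] = cons.with_ids(prefix=ds)

    # 2. motif annotation and TFBS / noTFBS split
    focal = consensus["Runx3"]
    focal_spec = MotifSpec("Runx3", cfg.motifs["Runx3"])
    focal_ann = scan_peak_motifs(study.genome.sequences, focal, focal_spec)
    focal_tfbs, focal_notfbs = split_by_motif(focal, focal_ann)
    partner_tfbs: Dict[str, PeakSet] = {}
    for tf in ("Brn3a", "Isl1"):
        ann = scan_peak_motifs(
            study.genome.sequences, consensus[tf], MotifSpec(tf, cfg.motifs[tf])
        )
        partner_tfbs[tf], _ = split_by_motif(consensus[tf], ann)

    # 3. width normalisation for overlap analyses
    def extend(ps: PeakSet, width: int) -> PeakSet:
        return PeakSet(
            ps.label, [resize_centered(iv, width, chrom_sizes) for iv in ps]
        )

    focal_tfbs_ext = extend(focal_tfbs, cfg.tf_extend)
    brn3a_ext = extend(partner_tfbs["Brn3a"], cfg.tf_extend)
    isl1_ext = extend(partner_tfbs["Isl1"], cfg.tf_extend)
    atac_ext = extend(consensus["ATAC"], cfg.atac_extend)
    k27_ext = extend(consensus["H3K27Ac"], cfg.k27_extend)

    # 4. location, chromatin state, co-occupancy category
    annotator = LocationAnnotator(genes, cfg.promoter_up, cfg.promoter_down)
    peak_locations = {iv.name: annotator.locate(iv) for iv in focal}
    atac_index = PeakIndex(atac_ext.intervals)
    k27_index = PeakIndex(k27_ext.intervals)
    peak_states = {
        iv.name: assign_chromatin_state(iv, atac_index, k27_index)
        for iv in focal_tfbs_ext
    }
    cooccupancy = categorize_cooccupancy([focal_tfbs_ext, brn3a_ext, isl1_ext])

    # 5. regulatory domains and promoter/distal gene grouping (focal TFBS peaks)
    domains = build_regulatory_domains(
        genes, chrom_sizes, cfg.basal_up, cfg.basal_down, cfg.max_ext
    )
    gene_peaks, _ = assign_peaks_to_domains(focal_tfbs, domains)
    coarse = {name: coarse_location(loc) for name, loc in peak_locations.items()}
    gene_groups = group_genes_by_location(gene_peaks, coarse)

    # 6. DEG filtering and HCT calling
    degs = filter_degs(study.deg_table, cfg.min_fc, cfg.max_padj)
    hct_rbs, skipped = call_hct(
        degs,
        focal_tfbs,
        genes,
        chrom_sizes,
        peak_categories=cooccupancy.peak_category,
        peak_states=peak_states,
        promoter_up=cfg.promoter_up,
        promoter_down=cfg.promoter_down,
        include_cds_exons=cfg.include_cds_exons,
    )
    hct_norbs, _ = call_norbs_hct(
        degs,
        hct_rbs,
        focal_notfbs,
        genes,
        chrom_sizes,
        promoter_up=cfg.promoter_up,
        promoter_down=cfg.promoter_down,
        include_cds_exons=cfg.include_cds_exons,
    )

    # 7. proportion statistics: down- vs up-regulated HCT among DEGs
    n_down = sum(1 for d in degs if d.direction == "down")
    n_up = sum(1 for d in degs if d.direction == "up")
    hct_down = sum(1 for r in hct_rbs if r.direction == "down")
    hct_up = sum(1 for r in hct_rbs if r.direction == "up")
    contingency = contingency_2x2(
        hct_down, n_down - hct_down, hct_up, n_up - hct_up
    )

    # 8. k-means clustering of category profiles
    clusters: Dict[str, pd.Series] = {}
    for direction, k in (("up", cfg.kmeans_k_up), ("down", cfg.kmeans_k_down)):
        matrix = build_category_matrix(hct_rbs, direction)
        if len(matrix) == 0:
            continue
        k_eff = min(k, matrix.drop_duplicates().shape[0])
        clusters[direction] = kmeans_cluster(
            matrix, k_eff, seed=child_seed(study.seed, 40), n_init=cfg.kmeans_n_init
        )

    # 9. signal-strength comparison: open-chromatin peaks at focal-TF-bound
    # vs unbound regions (two-sample KS on linear values)
    focal_index = PeakIndex(focal.intervals)
    signal_table = generate_signal_table(
        consensus["ATAC"], focal_index, seed=child_seed(study.seed, 50)
    )
    bound = signal_table.loc[signal_table["group"] == "bound", "signal"]
    unbound = signal_table.loc[signal_table["group"] == "unbound", "signal"]
    ks_signal = (
        ks_two_sample(bound.tolist(), unbound.tolist())
        if len(bound) and len(unbound)
        else (float("nan"), float("nan"))
    )

    return PipelineResult(
        consensus=consensus,
        focal_tfbs=focal_tfbs,
        focal_notfbs=focal_notfbs,
        partner_tfbs=partner_tfbs,
        peak_locations=peak_locations,
        peak_states=peak_states,
        cooccupancy=cooccupancy,
        gene_groups=gene_groups,
        degs=degs,
        hct_rbs=hct_rbs,
        hct_norbs=hct_norbs,
        skipped_degs=skipped,
        clusters=clusters,
        contingency=contingency,
        signal_table=signal_table,
        ks_signal=ks_signal,
    )


def write_study(study: StudyData, out_dir: str) -> Dict[str, str]:
    """Write a study's inputs to disk: FASTA, chrom.sizes, refFlat annotation,
    per-replicate BEDs, repeat/blacklist BEDs, DEG TSV and the truth manifest.

    Intended for scratch space — the genome FASTA is megabytes; pipelines can
    equally re-build the study from its seed.
    """
    import os

    from .genes import write_refflat
    from .intervals import write_bed, write_chrom_sizes

    os.makedirs(out_dir, exist_ok=True)
    paths: Dict[str, str] = {}

    paths["fasta"] = os.path.join(out_dir, "genome.fa")
    with open(paths["fasta"], "w") as fh:
        for chrom, seq in study.genome.sequences.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")
    paths["chrom_sizes"] = os.path.join(out_dir, "genome.chrom.sizes")
    with open(paths["chrom_sizes"], "w") as fh:
        fh.write(write_chrom_sizes(study.genome.chrom_sizes))
    paths["annotation"] = os.path.join(out_dir, "annotation.refflat.tsv")
    with open(paths["annotation"], "w") as fh:
        fh.write(write_refflat(study.genome.genes))
    for ds, reps in study.replicates.items():
        for i, rep in enumerate(reps, 1):
            key = f"{ds}_rep{i}"
            paths[key] = os.path.join(out_dir, f"{key}.bed")
            with open(paths[key], "w") as fh:
                fh.write(write_bed(rep))
    for name, track in (("repeats", study.repeats), ("blacklist", study.blacklist)):
        paths[name] = os.path.join(out_dir, f"{name}.bed")
        with open(paths[name], "w") as fh:
            fh.write(write_bed(track))
    paths["deg"] = os.path.join(out_dir, "deg_table.tsv")
    study.deg_table.to_csv(paths["deg"], sep="\t", index=False)
    paths["truth"] = os.path.join(out_dir, "truth.json")
    with open(paths["truth"], "w") as fh:
        fh.write(study.truth.to_json() + "\n")
    return paths


def recovery_metrics(
    truth_genes: Set[str], called_genes: Set[str]
) -> Tuple[float, float]:
    """(sensitivity, precision) of a called gene set against planted truth."""
    tp = len(truth_genes & called_genes)
    sens = tp / len(truth_genes) if truth_genes else float("nan")
    prec = tp / len(called_genes) if called_genes else float("nan")
    return sens, prec
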