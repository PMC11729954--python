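"""Synthetic genome, annotation, peak-replicate and DEG generation.

Everything the pipeline consumes can be generated here with known ground
truth: a miniature genome with non-overlapping gene models, uniform random
background sequence, planted TF binding sites with a controllable
motif-bearing fraction, replicate peak sets with per-replicate detection
probability / coordinate jitter / false-peak rate, chromatin-mark tracks,
and a differential-expression table with planted direct targets. All outputs
are bit-reproducible under a fixed seed; per-component child seeds are
spawned from the one global seed.

The generator emulates the *statistical* structure of replicated CUT&RUN /
ATAC experiments (site reproducibility, motif fractions, co-marking rates);
it does not model reads, fragment lengths, mappability or GC composition.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .intervals import ChromSizes, GenomicInterval, PeakIndex, PeakSet
from .genes import GeneModel
from .motifs import expand_iupac, scan_sequence

__all__ = [
    "GeneModelSpec",
    "SyntheticGenome",
    "PlantedSite",
    "PlantedTarget",
    "SyntheticTruth",
    "generate_genome",
    "plant_motifs",
    "generate_replicate_peaks",
    "generate_deg_table",
    "generate_signal_table",
    "child_seed",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def child_seed(seed: int, stream: int) -> int:
    """Deterministic per-component child seed below 2**31."""
    ss = np.random.SeedSequence([int(seed), int(stream)])
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


@dataclass
class GeneModelSpec:
    """Layout parameters for the synthetic genome."""

    n_chroms: int = 3
    chrom_length: int = 4_000_000
    n_genes: int = 600
    min_exons: int = 2
    max_exons: int = 6
    exon_length: Tuple[int, int] = (150, 400)
    intron_length: Tuple[int, int] = (500, 3000)
    utr5_length: Tuple[int, int] = (50, 120)
    utr3_length: Tuple[int, int] = (100, 300)
    intergenic_spacing: Tuple[int, int] = (5000, 15000)

    def __post_init__(self) -> None:
        if self.min_exons < 1 or self.max_exons < self.min_exons:
            raise ValueError("invalid exon count range")
        if self.n_chroms < 1 or self.n_genes < 1 or self.chrom_length < 1:
            raise ValueError("genome dimensions must be positive")


@dataclass
class SyntheticGenome:
    chrom_sizes: ChromSizes
    genes: List[GeneModel]
    sequences: Dict[str, str]


@dataclass
class PlantedSite:
    """A true binding site with its motif flag (the truth for recovery tests)."""

    tf: str
    interval: GenomicInterval
    has_motif: bool
    motif_word: Optional[str] = None
    motif_pos: Optional[int] = None  # absolute genomic start of the planted word
    site_class: str = "intergenic"   # promoter / intron / intergenic


@dataclass
class PlantedTarget:
    gene_id: str
    direction: str   # up / down
    evidence: str    # RBS / noRBS


@dataclass
class SyntheticTruth:
    """Ground-truth manifest: all recovery metrics are computed against this."""

    seed: int
    planted_sites: Dict[str, List[PlantedSite]] = field(default_factory=dict)
    planted_targets: List[PlantedTarget] = field(default_factory=list)
    detect_prob: float = 0.8
    fp_rate: float = 0.5        # expected false peaks per Mb per replicate
    jitter_sd: float = 20.0     # bp
    rbs_fraction: float = 0.71
    comark_probs: Dict[str, Dict[str, float]] = field(default_factory=dict)
    deg_false_positives: List[str] = field(default_factory=list)
    extra_degs: List[str] = field(default_factory=list)

    def targets_by_evidence(self, evidence: str) -> List[PlantedTarget]:
        return [t for t in self.planted_targets if t.evidence == evidence]

    def to_json(self) -> str:
        def site(s: PlantedSite) -> dict:
            return {
                "tf": s.tf,
                "chrom": s.interval.chrom,
                "start": s.interval.start,
                "end": s.interval.end,
                "has_motif": s.has_motif,
                "motif_word": s.motif_word,
                "motif_pos": s.motif_pos,
                "site_class": s.site_class,
            }

        payload = {
            "seed": self.seed,
            "detect_prob": self.detect_prob,
            "fp_rate": self.fp_rate,
            "jitter_sd": self.jitter_sd,
            "rbs_fraction": self.rbs_fraction,
            "comark_probs": self.comark_probs,
            "planted_sites": {
                tf: [site(s) for s in sites]
                for tf, sites in self.planted_sites.items()
            },
            "planted_targets": [
                {"gene_id": t.gene_id, "direction": t.direction, "evidence": t.evidence}
                for t in self.planted_targets
            ],
            "deg_false_positives": self.deg_false_positives,
            "extra_degs": self.extra_degs,
        }
        return json.dumps(payload, indent=2, sort_keys=True)


def generate_genome(spec: GeneModelSpec, seed: int) -> SyntheticGenome:
    """Deterministic miniature genome: uniform A/C/G/T background sequence and
    non-overlapping gene models packed along each chromosome.

    Raises a configuration error when the requested genes cannot fit.
    """
    rng = np.random.default_rng(child_seed(seed, 0))
    chrom_sizes = {
        f"chr{i + 1}": spec.chrom_length for i in range(spec.n_chroms)
    }
    sequences = {}
    for chrom in chrom_sizes:
        codes = rng.integers(0, 4, size=spec.chrom_length)
        sequences[chrom] = _BASES[codes].tobytes().decode("ascii")

    genes: List[GeneModel] = []
    chrom_names = list(chrom_sizes)
    chrom_idx = 0
    pos = int(rng.integers(*spec.intergenic_spacing))
    margin = 2000  # keep promoters on-chromosome
    n_placed = 0
    while n_placed < spec.n_genes:
        n_exons = int(rng.integers(spec.min_exons, spec.max_exons + 1))
        exon_lens = rng.integers(*spec.exon_length, size=n_exons)
        intron_lens = (
            rng.integers(*spec.intron_length, size=n_exons - 1)
            if n_exons > 1
            else np.array([], dtype=int)
        )
        length = int(exon_lens.sum() + intron_lens.sum())
        start = max(pos, margin)
        if start + length + margin > spec.chrom_length:
            chrom_idx += 1
            if chrom_idx >= len(chrom_names):
                raise ValueError(
                    f"cannot pack {spec.n_genes} genes into "
                    f"{spec.n_chroms} x {spec.chrom_length} bp (placed {n_placed})"
                )
            pos = int(rng.integers(*spec.intergenic_spacing))
            continue
        chrom = chrom_names[chrom_idx]
        exons = []
        p = start
        for i in range(n_exons):
            exons.append((p, p + int(exon_lens[i])))
            p += int(exon_lens[i])
            if i < n_exons - 1:
                p += int(intron_lens[i])
        tx_start, tx_end = exons[0][0], exons[-1][1]
        strand = "+" if rng.random() < 0.5 else "-"
        utr_left = int(rng.integers(*(spec.utr5_length if strand == "+" else spec.utr3_length)))
        utr_right = int(rng.integers(*(spec.utr3_length if strand == "+" else spec.utr5_length)))
        utr_left = min(utr_left, exons[0][1] - exons[0][0] - 10)
        utr_right = min(utr_right, exons[-1][1] - exons[-1][0] - 10)
        if n_exons == 1:  # single exon: UTRs must leave room for a CDS
            utr_right = max(0, min(utr_right, (tx_end - tx_start) - utr_left - 10))
        genes.append(
            GeneModel(
                gene_id=f"gene{n_placed:04d}",
                chrom=chrom,
                strand=strand,
                tx_start=tx_start,
                tx_end=tx_end,
                cds_start=tx_start + max(0, utr_left),
                cds_end=tx_end - max(0, utr_right),
                exons=tuple(exons),
            )
        )
        n_placed += 1
        pos = tx_end + int(rng.integers(*spec.intergenic_spacing))
    return SyntheticGenome(chrom_sizes, genes, sequences)


def _scrub_pattern(
    seq: bytearray,
    start: int,
    end: int,
    words: Sequence[str],
    rng: np.random.Generator,
    protected: Optional[set] = None,
) -> None:
    """Mutate single bases until ``seq[start:end]`` contains no word of the
    set, never touching ``protected`` positions (previously planted words)."""
    bases = b"ACGT"
    k = len(words[0])
    for _ in range(400):
        segment = seq[start:end].decode("ascii")
        hits = scan_sequence(segment, words)
        if protected:
            hits = [
                h for h in hits
                if any(start + h + j not in protected for j in range(k))
            ]
        if not hits:
            return
        candidates = [
            start + hits[0] + j
            for j in range(k)
            if not protected or start + hits[0] + j not in protected
        ]
        pos = candidates[len(candidates) // 2]
        old = seq[pos]
        choices = [b for b in bases if b != old]
        seq[pos] = choices[int(rng.integers(0, len(choices)))]
    raise RuntimeError("failed to scrub motif occurrences (pathological sequence)")


def plant_motifs(
    sequences: Dict[str, str],
    sites: Sequence[GenomicInterval],
    pattern: str,
    rbs_fraction: float,
    seed: int,
    force_flags: Optional[Sequence[Optional[bool]]] = None,
    scrub_margin: int = 150,
    protected: Optional[Sequence[GenomicInterval]] = None,
) -> Tuple[Dict[str, str], List[Tuple[bool, Optional[str], Optional[int]]]]:
    """Write one concrete word of the IUPAC pattern into a Bernoulli subset of
    sites; scrub chance occurrences from the remaining sites.

    For each chosen site a word is drawn uniformly from the strand-unioned
    expansion of ``pattern`` and written at a uniform position inside the
    site. Non-chosen sites (and a ``scrub_margin`` flank, so that jittered
    peak boundaries stay motif-free) are mutated until they contain no word
    of the set. ``force_flags`` overrides the Bernoulli draw per site
    (True = plant, False = scrub, None = draw). ``protected`` intervals
    (e.g. words planted for another factor at a co-bound site) are never
    mutated and never overwritten.

    Returns the edited sequences and, per site, ``(has_motif, word,
    absolute_start)``.
    """
    if not (0 <= rbs_fraction <= 1):
        raise ValueError("rbs_fraction must be in [0, 1]")
    words = sorted(expand_iupac(pattern, both_strands=True))
    k = len(words[0])
    rng = np.random.default_rng(child_seed(seed, 1))
    buffers = {c: bytearray(s.encode("ascii")) for c, s in sequences.items()}
    protected_pos: Dict[str, set] = {}
    for iv in protected or ():
        protected_pos.setdefault(iv.chrom, set()).update(range(iv.start, iv.end))
    plans: List[Tuple[bool, Optional[str], Optional[int]]] = []
    # pass 1: decide flags and scrub every site (plus flank) of chance hits,
    # so that later scrubbing can never destroy an already-planted word
    for i, site in enumerate(sites):
        if site.chrom not in buffers or site.end > len(buffers[site.chrom]):
            raise ValueError(f"site {site.chrom}:{site.start}-{site.end} out of bounds")
        if len(site) < k:
            raise ValueError(f"site shorter than motif length {k}")
        flag = force_flags[i] if force_flags is not None else None
        plant = bool(rng.random() < rbs_fraction) if flag is None else flag
        buf = buffers[site.chrom]
        lo = max(0, site.start - scrub_margin)
        hi = min(len(buf), site.end + scrub_margin)
        prot = protected_pos.get(site.chrom)
        _scrub_pattern(buf, lo, hi, words, rng, prot)
        if plant:
            word = words[int(rng.integers(0, len(words)))]
            for _ in range(100):
                offset = int(rng.integers(site.start, site.end - k + 1))
                if not prot or not any(p in prot for p in range(offset, offset + k)):
                    break
            else:
                raise RuntimeError("no unprotected position left in site")
            plans.append((True, word, offset))
        else:
            plans.append((False, None, None))
    # pass 2: write the planted words
    for site, (plant, word, offset) in zip(sites, plans):
        if plant:
            buffers[site.chrom][offset : offset + k] = word.encode("ascii")
    return {c: b.decode("ascii") for c, b in buffers.items()}, plans


def generate_replicate_peaks(
    sites: Sequence[GenomicInterval],
    chrom_sizes: ChromSizes,
    n_reps: int,
    peak_width: int,
    seed: int,
    detect_prob: float = 0.8,
    jitter_sd: float = 20.0,
    fp_rate: float = 0.5,
    label: str = "peaks",
) -> List[PeakSet]:
    """Replicate peak sets around true sites.

    Each replicate contains each site independently with ``detect_prob``, its
    centre jittered by rounded Gaussian noise, plus Poisson false peaks at
    ``fp_rate`` per Mb placed uniformly outside the true sites.
    """
    if n_reps < 1:
        raise ValueError("need n_reps >= 1")
    rng = np.random.default_rng(child_seed(seed, 2))
    site_index = PeakIndex(sites)
    genome_mb = sum(chrom_sizes.values()) / 1e6
    chroms = list(chrom_sizes)
    weights = np.array([chrom_sizes[c] for c in chroms], dtype=float)
    weights /= weights.sum()
    replicates = []
    for rep in range(n_reps):
        intervals: List[GenomicInterval] = []
        for site in sites:
            if rng.random() >= detect_prob:
                continue
            jitter = int(round(rng.normal(0.0, jitter_sd))) if jitter_sd > 0 else 0
            centre = site.midpoint + jitter
            half = peak_width // 2
            start = max(0, centre - half)
            end = min(chrom_sizes[site.chrom], start + peak_width)
            if end - start > 0:
                intervals.append(GenomicInterval(site.chrom, start, end))
        n_fp = int(rng.poisson(fp_rate * genome_mb)) if fp_rate > 0 else 0
        placed = 0
        while placed < n_fp:
            chrom = chroms[int(rng.choice(len(chroms), p=weights))]
            start = int(rng.integers(0, chrom_sizes[chrom] - peak_width))
            candidate = GenomicInterval(chrom, start, start + peak_width)
            if not site_index.any_overlap(candidate):
                intervals.append(candidate)
                placed += 1
        replicates.append(PeakSet(f"{label}_rep{rep + 1}", intervals).sorted())
    return replicates


def generate_deg_table(
    gene_ids: Sequence[str],
    planted_targets: Sequence[PlantedTarget],
    seed: int,
    fc_effect: float = 2.0,
    extra_degs: Sequence[str] = (),
    fp_deg_frac: float = 0.0,
    threshold_fc: float = 1.8,
    threshold_padj: float = 0.05,
):
    """Differential-expression table with planted direct targets.

    Planted targets (and ``extra_degs``, differentially expressed genes that
    are not direct targets, given as a gene->direction mapping or a plain
    sequence for random directions) receive a linear fold-change magnitude of
    at least ``fc_effect`` with padj below the threshold, in their planted
    direction. Remaining genes stay below the DEG thresholds except a
    ``fp_deg_frac`` fraction that is made threshold-passing in a random
    direction (recorded as DEG false positives).

    Returns ``(DataFrame[gene_id, log2_fc, padj], fp_gene_ids)``.
    """
    import pandas as pd

    ids = list(gene_ids)
    target_dir = {t.gene_id: t.direction for t in planted_targets}
    unknown = set(target_dir) - set(ids)
    if unknown:
        raise ValueError(f"planted targets not in gene list: {sorted(unknown)[:5]}")
    rng = np.random.default_rng(child_seed(seed, 3))
    extra_dir = (
        dict(extra_degs)
        if isinstance(extra_degs, dict)
        else {g: None for g in extra_degs}
    )
    extra = set(extra_dir) - set(target_dir)
    candidates = [g for g in ids if g not in target_dir and g not in extra]
    n_fp = int(round(fp_deg_frac * len(candidates)))
    fp_genes = (
        sorted(rng.choice(candidates, size=n_fp, replace=False).tolist())
        if n_fp
        else []
    )
    fp_set = set(fp_genes)
    log2_thresh = float(np.log2(threshold_fc))
    rows = []
    for g in ids:
        if g in target_dir or g in extra or g in fp_set:
            if g in target_dir:
                direction = target_dir[g]
            elif g in extra and extra_dir.get(g) is not None:
                direction = extra_dir[g]
            else:
                direction = "up" if rng.random() < 0.5 else "down"
            sign = 1.0 if direction == "up" else -1.0
            magnitude = float(np.log2(fc_effect)) + float(rng.exponential(0.5))
            padj = float(rng.uniform(1e-8, threshold_padj * 0.9))
            rows.append((g, sign * magnitude, padj))
        else:
            lfc = float(rng.normal(0.0, 0.3))
            padj = float(rng.uniform(0.0, 1.0))
            if abs(lfc) >= log2_thresh and padj < threshold_padj:
                padj = float(rng.uniform(threshold_padj, 1.0))
            rows.append((g, lfc, padj))
    table = pd.DataFrame(rows, columns=["gene_id", "log2_fc", "padj"])
    return table, fp_genes


def generate_signal_table(
    peaks: PeakSet,
    bound_index: PeakIndex,
    seed: int,
    mu_bound: float = 1.6,
    mu_unbound: float = 1.0,
    sigma: float = 0.5,
):
    """Synthetic per-peak signal values (RPKM-like, linear scale).

    Peaks overlapping the ``bound_index`` form the TF-bound group and draw
    from a log-normal with the larger location parameter.
    """
    import pandas as pd

    rng = np.random.default_rng(child_seed(seed, 4))
    rows = []
    for iv in peaks:
        bound = bound_index.any_overlap(iv)
        mu = mu_bound if bound else mu_unbound
        value = float(np.exp(rng.normal(mu, sigma)))
        rows.append(
            (iv.name or f"{iv.chrom}:{iv.start}-{iv.end}",
             value,
             "bound" if bound else "unbound")
        )
    return pd.DataFrame(rows, columns=["peak_id", "signal", "group"])
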