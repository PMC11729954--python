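"""High-confidence target (HCT) calling and 2x2 proportion statistics.

A differentially expressed gene (DEG) is called a high-confidence direct
target of the focal TF when at least one motif-bearing consensus peak of that
TF falls (by midpoint) in the gene's *eligible region*: its promoter window,
introns, 5'/3' UTRs, and the flanking intergenic intervals reaching to the
nearest neighbouring gene's transcription span on each side (to the
chromosome edge when there is no neighbour). Coding exons are excluded by
default. DEGs not called this way but carrying a motif-lacking peak of the
focal TF in the same eligible region form a secondary, noRBS-evidence list.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .genes import GeneModel, genes_by_chrom
from .intervals import ChromSizes, GenomicInterval, PeakSet, merge_union

__all__ = [
    "DEGRecord",
    "HCTRecord",
    "ContingencyResult",
    "filter_degs",
    "gene_search_region",
    "call_hct",
    "call_norbs_hct",
    "contingency_2x2",
]


@dataclass(frozen=True)
class DEGRecord:
    gene_id: str
    log2_fc: float
    padj: float

    @property
    def direction(self) -> str:
        return "up" if self.log2_fc > 0 else "down"

    @property
    def fold_change(self) -> float:
        """Linear fold-change magnitude (>= 1)."""
        return 2.0 ** abs(self.log2_fc)


@dataclass
class HCTRecord:
    gene_id: str
    direction: str
    evidence: str  # "RBS" (motif-bearing peak) or "noRBS"
    peak_ids: List[str]
    category_profile: Set[int] = field(default_factory=set)
    chromatin_states: Dict[str, str] = field(default_factory=dict)  # peak -> state


@dataclass
class ContingencyResult:
    table: Tuple[Tuple[int, int], Tuple[int, int]]
    chi2_plain: Optional[float]
    chi2_yates: Optional[float]
    fisher_p_two_sided: float


def filter_degs(
    table: pd.DataFrame, min_fc: float = 1.8, max_padj: float = 0.05
) -> List[DEGRecord]:
    """Threshold a differential-expression table.

    ``table`` must have ``gene_id``, ``padj`` and either ``log2_fc`` (signed)
    or ``fold_change`` (linear ratio > 0). A record is kept when its linear
    fold-change magnitude is >= ``min_fc`` (inclusive) and padj < ``max_padj``
    (strict).
    """
    if "gene_id" not in table.columns or "padj" not in table.columns:
        raise ValueError("DEG table must have gene_id and padj columns")
    if "log2_fc" in table.columns:
        log2fc = table["log2_fc"].astype(float)
    elif "fold_change" in table.columns:
        fc = table["fold_change"].astype(float)
        if (fc <= 0).any():
            raise ValueError("linear fold changes must be > 0")
        log2fc = np.log2(fc)
    else:
        raise ValueError("DEG table must have a log2_fc or fold_change column")
    padj = table["padj"].astype(float)
    if ((padj < 0) | (padj > 1)).any():
        raise ValueError("padj values must lie in [0, 1]")
    threshold = math.log2(min_fc)
    # tiny tolerance keeps the inclusive boundary inclusive after log2 round-trip
    keep = (log2fc.abs() >= threshold - 1e-12) & (padj < max_padj)
    return [
        DEGRecord(str(g), float(l), float(p))
        for g, l, p in zip(table["gene_id"][keep], log2fc[keep], padj[keep])
    ]


def gene_search_region(
    gene: GeneModel,
    all_genes: Sequence[GeneModel],
    chrom_sizes: ChromSizes,
    promoter_up: int = 1000,
    promoter_down: int = 1000,
    include_cds_exons: bool = False,
) -> List[GenomicInterval]:
    """Eligible intervals in which a peak counts as targeting this gene.

    Promoter window, introns, UTRs and the two flanking intergenic intervals
    reaching to the nearest neighbouring gene's transcription-span boundary
    (or chromosome edge). Coding exons are excluded unless
    ``include_cds_exons``. Returns a merged, sorted interval list.
    """
    chrom_len = chrom_sizes[gene.chrom]
    parts: List[GenomicInterval] = [
        gene.promoter(promoter_up, promoter_down, chrom_sizes)
    ]
    parts += gene.introns
    parts += gene.utr5
    parts += gene.utr3
    if include_cds_exons:
        parts += gene.coding_exons

    # flanking intergenic intervals to the nearest neighbour tx boundary
    left_bound, right_bound = 0, chrom_len
    for other in all_genes:
        if other.chrom != gene.chrom or other.gene_id == gene.gene_id:
            continue
        if other.tx_end <= gene.tx_start:
            left_bound = max(left_bound, other.tx_end)
        elif other.tx_start >= gene.tx_end:
            right_bound = min(right_bound, other.tx_start)
    if left_bound < gene.tx_start:
        parts.append(GenomicInterval(gene.chrom, left_bound, gene.tx_start))
    if gene.tx_end < right_bound:
        parts.append(GenomicInterval(gene.chrom, gene.tx_end, right_bound))
    return merge_union(PeakSet(f"{gene.gene_id}_eligible", parts)).intervals


def _peaks_in_region(
    peaks: PeakSet, region: Sequence[GenomicInterval]
) -> List[GenomicInterval]:
    """Peaks whose midpoint falls in any of the (disjoint sorted) intervals."""
    hits = []
    for iv in peaks:
        mid = iv.midpoint
        for r in region:
            if r.chrom == iv.chrom and r.start <= mid < r.end:
                hits.append(iv)
                break
    return hits


def call_hct(
    degs: Sequence[DEGRecord],
    tf_tfbs_peaks: PeakSet,
    genes: Sequence[GeneModel],
    chrom_sizes: ChromSizes,
    peak_categories: Optional[Mapping[str, int]] = None,
    peak_states: Optional[Mapping[str, str]] = None,
    promoter_up: int = 1000,
    promoter_down: int = 1000,
    include_cds_exons: bool = False,
    evidence: str = "RBS",
) -> Tuple[List[HCTRecord], List[str]]:
    """Call high-confidence targets among DEGs.

    A DEG becomes an HCT iff at least one peak of ``tf_tfbs_peaks`` has its
    midpoint inside the gene's eligible region. Returns the sorted HCT list
    and the DEG gene ids that were absent from the annotation (skipped).
    """
    gene_by_id = {g.gene_id: g for g in genes}
    by_chrom = genes_by_chrom(list(genes))
    # midpoints per chromosome for fast range counting
    mids: Dict[str, np.ndarray] = {}
    names: Dict[str, List[str]] = {}
    for chrom in {iv.chrom for iv in tf_tfbs_peaks}:
        ivs = sorted(
            (iv for iv in tf_tfbs_peaks if iv.chrom == chrom),
            key=lambda x: x.midpoint,
        )
        mids[chrom] = np.array([iv.midpoint for iv in ivs], dtype=np.int64)
        names[chrom] = [iv.name or f"{iv.chrom}:{iv.start}-{iv.end}" for iv in ivs]

    records: List[HCTRecord] = []
    skipped: List[str] = []
    for deg in degs:
        gene = gene_by_id.get(deg.gene_id)
        if gene is None:
            skipped.append(deg.gene_id)
            continue
        region = gene_search_region(
            gene,
            by_chrom[gene.chrom],
            chrom_sizes,
            promoter_up,
            promoter_down,
            include_cds_exons,
        )
        chrom_mids = mids.get(gene.chrom)
        if chrom_mids is None or chrom_mids.size == 0:
            continue
        supporting: List[str] = []
        for r in region:
            lo = np.searchsorted(chrom_mids, r.start, side="left")
            hi = np.searchsorted(chrom_mids, r.end - 1, side="right")
            supporting.extend(names[gene.chrom][lo:hi])
        if supporting:
            supporting = sorted(set(supporting))
            profile = (
                {peak_categories[p] for p in supporting if p in peak_categories}
                if peak_categories
                else set()
            )
            chromatin = (
                {p: peak_states[p] for p in supporting if p in peak_states}
                if peak_states
                else {}
            )
            records.append(
                HCTRecord(
                    deg.gene_id, deg.direction, evidence, supporting, profile, chromatin
                )
            )
    records.sort(key=lambda r: r.gene_id)
    return records, skipped


def call_norbs_hct(
    degs: Sequence[DEGRecord],
    hct_rbs: Sequence[HCTRecord],
    tf_notfbs_peaks: PeakSet,
    genes: Sequence[GeneModel],
    chrom_sizes: ChromSizes,
    **kwargs,
) -> Tuple[List[HCTRecord], List[str]]:
    """Secondary HCT list from motif-lacking peaks.

    Considers only DEGs not already called with motif evidence; a gene
    qualifies when a motif-lacking focal-TF peak midpoint lies in its
    eligible region.
    """
    called = {r.gene_id for r in hct_rbs}
    remaining = [d for d in degs if d.gene_id not in called]
    return call_hct(
        remaining, tf_notfbs_peaks, genes, chrom_sizes, evidence="noRBS", **kwargs
    )


def contingency_2x2(a: int, b: int, c: int, d: int) -> ContingencyResult:
    """Chi-square (plain and Yates-corrected) and two-sided Fisher exact test
    for the 2x2 table ``[[a, b], [c, d]]``.

    chi2 = N (ad - bc)^2 / (r1 r2 c1 c2); Yates subtracts N/2 from |ad - bc|
    (floored at zero). With a zero margin the chi-square statistics are
    undefined (``None``); the Fisher p-value is always computed
    (probability-mass two-sided method).
    """
    cells = (a, b, c, d)
    if any(x < 0 for x in cells):
        raise ValueError("contingency cells must be non-negative")
    n = a + b + c + d
    r1, r2, c1, c2 = a + b, c + d, a + c, b + d
    if 0 in (r1, r2, c1, c2) or n == 0:
        chi2_plain = chi2_yates = None
    else:
        det = a * d - b * c
        denom = r1 * r2 * c1 * c2
        chi2_plain = n * det * det / denom
        corrected = max(0.0, abs(det) - n / 2)
        chi2_yates = n * corrected * corrected / denom
    fisher_p = float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])
    return ContingencyResult(((a, b), (c, d)), chi2_plain, chi2_yates, fisher_p)
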