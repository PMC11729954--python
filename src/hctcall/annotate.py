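"""Peak annotation: genomic location, chromatin state, TF co-occupancy category.

Location is decided by the peak midpoint with precedence
promoter > UTR > coding exon > intron > intergenic. Chromatin state records
overlap (>= 1 bp, after width normalisation) with open-chromatin (ATAC) and
H3K27Ac tracks. Co-occupancy divides the union of three TF_TFBS peak sets
into seven categories: single-TF regions are 1, 2, 3 (first, second, third
set), pairwise overlaps 4 (1+2), 5 (1+3), 6 (2+3) and triple overlaps 7.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, FrozenSet, List, Optional, Sequence, Tuple

from .genes import GeneModel
from .intervals import GenomicInterval, PeakIndex, PeakSet, merge_union

__all__ = [
    "LOCATIONS",
    "CHROMATIN_STATES",
    "CATEGORY_BY_MEMBERS",
    "LocationAnnotator",
    "coarse_location",
    "assign_chromatin_state",
    "categorize_cooccupancy",
    "CooccupancyResult",
]

LOCATIONS = ("promoter", "utr5", "utr3", "exon_cds", "intron", "intergenic")
CHROMATIN_STATES = ("none", "ATAC_only", "K27_only", "ATAC_K27")

#: Category code by the subset of TF slots (0, 1, 2) present in a region.
CATEGORY_BY_MEMBERS: Dict[FrozenSet[int], int] = {
    frozenset({0}): 1,
    frozenset({1}): 2,
    frozenset({2}): 3,
    frozenset({0, 1}): 4,
    frozenset({0, 2}): 5,
    frozenset({1, 2}): 6,
    frozenset({0, 1, 2}): 7,
}


class LocationAnnotator:
    """Midpoint-based location labelling against a gene annotation.

    Promoter windows are strand-aware around each TSS (default +/- 1 kb).
    """

    def __init__(
        self,
        genes: Sequence[GeneModel],
        promoter_up: int = 1000,
        promoter_down: int = 1000,
    ):
        self._promoters = PeakIndex(
            g.promoter(promoter_up, promoter_down) for g in genes
        )
        self._utr5 = PeakIndex(iv for g in genes for iv in g.utr5)
        self._utr3 = PeakIndex(iv for g in genes for iv in g.utr3)
        self._cds = PeakIndex(iv for g in genes for iv in g.coding_exons)
        self._introns = PeakIndex(iv for g in genes for iv in g.introns)

    def locate(self, peak: GenomicInterval) -> str:
        mid = peak.midpoint
        for label, index in (
            ("promoter", self._promoters),
            ("utr5", self._utr5),
            ("utr3", self._utr3),
            ("exon_cds", self._cds),
            ("intron", self._introns),
        ):
            if index.at_point(peak.chrom, mid):
                return label
        return "intergenic"


def coarse_location(location: str) -> str:
    """Collapse the fine location label to promoter / intron_intergenic / other."""
    if location == "promoter":
        return "promoter"
    if location in ("intron", "intergenic"):
        return "intron_intergenic"
    if location in LOCATIONS:
        return "other"
    raise ValueError(f"unknown location label {location!r}")


def assign_chromatin_state(
    peak: GenomicInterval, atac: PeakIndex, k27: PeakIndex
) -> str:
    """Chromatin state from >= 1 bp overlap with the (pre-extended) tracks."""
    has_atac = atac.any_overlap(peak)
    has_k27 = k27.any_overlap(peak)
    if has_atac and has_k27:
        return "ATAC_K27"
    if has_atac:
        return "ATAC_only"
    if has_k27:
        return "K27_only"
    return "none"


@dataclass
class CooccupancyResult:
    """Seven-way co-occupancy classification of the union of three TF peak sets."""

    regions: List[GenomicInterval]                 # union-merged regions
    region_category: List[int]                     # parallel to regions
    peak_category: Dict[str, int]                  # input peak name -> category
    counts: Dict[int, int]                         # category -> n regions

    def category_of(self, peak_name: str) -> Optional[int]:
        return self.peak_category.get(peak_name)


def categorize_cooccupancy(
    tf_sets: Sequence[PeakSet],
) -> CooccupancyResult:
    """Classify the union-merge of three TF_TFBS peak sets into categories 1-7.

    Each merged region receives the subset of TF sets contributing at least
    one overlapping peak; overlap chains are transitive (a region is one
    merged run of touching peaks). Every input peak inherits the category of
    the region containing it. Input peaks must carry names.
    """
    if len(tf_sets) != 3:
        raise ValueError("co-occupancy classification expects exactly 3 peak sets")
    pooled = PeakSet("pooled", [iv for s in tf_sets for iv in s.intervals])
    regions = merge_union(pooled).intervals
    region_index = PeakIndex(regions)
    members: Dict[Tuple[str, int, int], set] = {
        (r.chrom, r.start, r.end): set() for r in regions
    }
    peak_region: Dict[str, Tuple[str, int, int]] = {}
    for slot, peak_set in enumerate(tf_sets):
        for iv in peak_set:
            hits = region_index.overlapping(iv)
            # every peak lies entirely within exactly one union region
            key = (hits[0].chrom, hits[0].start, hits[0].end)
            members[key].add(slot)
            if iv.name is not None:
                peak_region[iv.name] = key
    region_category = [
        CATEGORY_BY_MEMBERS[frozenset(members[(r.chrom, r.start, r.end)])]
        for r in regions
    ]
    cat_by_key = {
        (r.chrom, r.start, r.end): c for r, c in zip(regions, region_category)
    }
    counts: Dict[int, int] = {c: 0 for c in range(1, 8)}
    for c in region_category:
        counts[c] += 1
    return CooccupancyResult(
        regions=regions,
        region_category=region_category,
        peak_category={name: cat_by_key[key] for name, key in peak_region.items()},
        counts=counts,
    )
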