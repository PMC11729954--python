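"""Peak-to-gene association: closest TSS and basal-plus-extension domains.

Two association strategies are provided. ``closest_tss`` assigns each peak to
the single gene whose TSS is nearest its midpoint. ``build_regulatory_domains``
constructs GREAT-style territories: a basal window 5 kb upstream / 1 kb
downstream of the TSS, extended on each side up to the nearest neighbouring
gene's basal domain, capped at 1 Mb from the TSS and the chromosome edge.
Genes are then grouped by where their associated peaks fall (promoter-only,
intron/intergenic-only, or both).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

from .genes import GeneModel, genes_by_chrom
from .intervals import ChromSizes, GenomicInterval, PeakIndex, PeakSet

__all__ = [
    "RegulatoryDomain",
    "closest_tss",
    "build_regulatory_domains",
    "assign_peaks_to_domains",
    "group_genes_by_location",
]


@dataclass(frozen=True)
class RegulatoryDomain:
    gene_id: str
    basal: GenomicInterval
    extended: GenomicInterval

    def __post_init__(self) -> None:
        if not (
            self.extended.start <= self.basal.start
            and self.basal.end <= self.extended.end
        ):
            raise ValueError(f"{self.gene_id}: basal not within extended domain")


def closest_tss(
    peak: GenomicInterval, genes: Sequence[GeneModel]
) -> Tuple[Optional[str], Optional[int]]:
    """Gene with the TSS nearest the peak midpoint; ties go to the
    lexicographically smallest gene id.

    Returns ``(gene_id, signed_distance)`` where the distance is negative when
    the midpoint is upstream of the TSS in the gene's orientation, or
    ``(None, None)`` when the chromosome has no genes.
    """
    mid = peak.midpoint
    best: Optional[GeneModel] = None
    best_dist = None
    for g in genes:
        if g.chrom != peak.chrom:
            continue
        d = abs(mid - g.tss)
        if best is None or d < best_dist or (d == best_dist and g.gene_id < best.gene_id):
            best, best_dist = g, d
    if best is None:
        return None, None
    offset = mid - best.tss
    signed = offset if best.strand == "+" else -offset
    return best.gene_id, signed


def _basal_window(
    g: GeneModel, basal_up: int, basal_down: int, chrom_len: int
) -> GenomicInterval:
    if g.strand == "+":
        s, e = g.tss - basal_up, g.tss + basal_down
    else:
        s, e = g.tss - basal_down, g.tss + basal_up
    return GenomicInterval(g.chrom, max(0, s), min(chrom_len, e), g.strand, g.gene_id)


def build_regulatory_domains(
    genes: Sequence[GeneModel],
    chrom_sizes: ChromSizes,
    basal_up: int = 5000,
    basal_down: int = 1000,
    max_ext: int = 1_000_000,
) -> Dict[str, RegulatoryDomain]:
    """Basal-plus-extension regulatory domain per gene.

    Extension on each side stops at the nearest other gene's basal domain
    boundary (regardless of strand), at ``max_ext`` from the TSS, or at the
    chromosome edge, and is never smaller than the basal domain itself.
    """
    for g in genes:
        if g.chrom not in chrom_sizes:
            raise ValueError(f"unknown chromosome {g.chrom!r} for gene {g.gene_id}")
    basals = {
        g.gene_id: _basal_window(g, basal_up, basal_down, chrom_sizes[g.chrom])
        for g in genes
    }
    domains: Dict[str, RegulatoryDomain] = {}
    for chrom, chrom_genes in genes_by_chrom(list(genes)).items():
        chrom_len = chrom_sizes[chrom]
        for g in chrom_genes:
            basal = basals[g.gene_id]
            left_limit = max(0, g.tss - max_ext)
            right_limit = min(chrom_len, g.tss + max_ext)
            for other in chrom_genes:
                if other.gene_id == g.gene_id:
                    continue
                ob = basals[other.gene_id]
                if ob.end <= basal.start:
                    left_limit = max(left_limit, ob.end)
                elif ob.start >= basal.end:
                    right_limit = min(right_limit, ob.start)
                else:
                    # neighbour basal intrudes into this basal: no extension
                    # beyond the basal on the side(s) it blocks
                    if ob.start < basal.start:
                        left_limit = basal.start
                    if ob.end > basal.end:
                        right_limit = basal.end
            # extension never shrinks below the basal domain
            ext = GenomicInterval(
                chrom,
                min(left_limit, basal.start),
                max(right_limit, basal.end),
                g.strand,
                g.gene_id,
            )
            domains[g.gene_id] = RegulatoryDomain(g.gene_id, basal, ext)
    return domains


def assign_peaks_to_domains(
    peaks: PeakSet, domains: Mapping[str, RegulatoryDomain]
) -> Tuple[Dict[str, List[GenomicInterval]], List[GenomicInterval]]:
    """Assign each peak (by midpoint) to every gene whose extended domain
    contains it. Returns ``(gene_id -> peaks, unassigned peaks)``."""
    index = PeakIndex(d.extended for d in domains.values())
    assigned: Dict[str, List[GenomicInterval]] = {}
    unassigned: List[GenomicInterval] = []
    for iv in peaks:
        hits = index.at_point(iv.chrom, iv.midpoint)
        if not hits:
            unassigned.append(iv)
            continue
        for dom in hits:
            assigned.setdefault(dom.name, []).append(iv)
    return assigned, unassigned


def group_genes_by_location(
    gene_peaks: Mapping[str, Sequence[GenomicInterval]],
    peak_coarse_location: Mapping[str, str],
) -> Dict[str, Set[str]]:
    """Group genes into P_only / I_only / P_I by the coarse locations of their
    associated peaks; genes whose peaks are all in 'other' locations are
    reported under ``other_only``. Genes with zero peaks are excluded."""
    groups: Dict[str, Set[str]] = {
        "P_only": set(),
        "I_only": set(),
        "P_I": set(),
        "other_only": set(),
    }
    for gene_id, peaks in gene_peaks.items():
        if not peaks:
            continue
        locs = set()
        for iv in peaks:
            if iv.name is None or iv.name not in peak_coarse_location:
                raise ValueError(f"peak {iv.name!r} lacks a coarse location")
            locs.add(peak_coarse_location[iv.name])
        has_p = "promoter" in locs
        has_i = "intron_intergenic" in locs
        if has_p and has_i:
            groups["P_I"].add(gene_id)
        elif has_p:
            groups["P_only"].add(gene_id)
        elif has_i:
            groups["I_only"].add(gene_id)
        else:
            groups["other_only"].add(gene_id)
    return groups
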