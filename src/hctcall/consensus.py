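"""Consensus peak construction from replicates, with repeat/blacklist filters.

A consensus peak is a union-merged candidate region supported by at least a
quorum of replicates, where a replicate supports a candidate if it contributes
a peak at least half-contained (``share_frac``) in the candidate. Peaks
covered more than ``repeat_max_frac`` of their length by repeat elements, or
touching a blacklist region by a single base, are then removed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

from .intervals import GenomicInterval, PeakIndex, PeakSet, merge_union, overlap_fraction

__all__ = [
    "ConsensusConfig",
    "DEFAULT_QUORUMS",
    "consensus_peaks",
    "filter_repeat_overlap",
    "filter_blacklist",
]

#: Per-dataset (quorum, n_replicates) used in the study design: half of the
#: replicates must support a region, rounded up.
DEFAULT_QUORUMS: Dict[str, Tuple[int, int]] = {
    "Runx3": (4, 8),
    "ATAC": (2, 3),
    "H3K27Ac": (3, 5),
    "Isl1": (2, 3),
    "Brn3a": (2, 2),
}


@dataclass
class ConsensusConfig:
    quorum: int = 2
    share_frac: float = 0.5
    repeat_max_frac: float = 0.6
    quorum_table: Dict[str, Tuple[int, int]] = field(
        default_factory=lambda: dict(DEFAULT_QUORUMS)
    )

    def __post_init__(self) -> None:
        if self.quorum < 1:
            raise ValueError("quorum must be >= 1")
        if not (0 < self.share_frac <= 1):
            raise ValueError("share_frac must be in (0, 1]")
        if not (0 < self.repeat_max_frac <= 1):
            raise ValueError("repeat_max_frac must be in (0, 1]")


def consensus_peaks(
    replicates: Sequence[PeakSet], quorum: int, share_frac: float = 0.5
) -> PeakSet:
    """Quorum consensus over replicate peak sets.

    Candidate regions are the union-merge of all replicate peaks; a replicate
    supports a candidate when it has a peak ``p`` with
    ``overlap_fraction(p, candidate) >= share_frac``; candidates supported by
    at least ``quorum`` replicates are kept.
    """
    if not replicates:
        raise ValueError("need at least one replicate")
    if not (1 <= quorum <= len(replicates)):
        raise ValueError(
            f"quorum {quorum} impossible with {len(replicates)} replicates"
        )
    pooled = PeakSet(
        "pooled", [iv for rep in replicates for iv in rep.intervals]
    )
    candidates = merge_union(pooled)
    cand_index = PeakIndex(candidates.intervals)
    support: Dict[Tuple[str, int, int], int] = {}
    for rep in replicates:
        seen = set()
        for p in rep:
            for cand in cand_index.overlapping(p):
                key = (cand.chrom, cand.start, cand.end)
                if key not in seen and overlap_fraction(p, cand) >= share_frac:
                    seen.add(key)
        for key in seen:
            support[key] = support.get(key, 0) + 1
    kept = [
        iv
        for iv in candidates
        if support.get((iv.chrom, iv.start, iv.end), 0) >= quorum
    ]
    label = replicates[0].label.rsplit("_rep", 1)[0]
    return PeakSet(f"{label}_consensus", kept).sorted()


def filter_repeat_overlap(
    peaks: PeakSet, repeats: PeakSet, max_frac: float = 0.6
) -> PeakSet:
    """Drop peaks whose summed repeat-element coverage exceeds ``max_frac``
    (strictly greater) of the peak length. The repeat track is union-merged
    internally, so overlapping repeat records are not double counted."""
    repeat_index = PeakIndex(merge_union(repeats).intervals)
    kept = [
        iv
        for iv in peaks
        if repeat_index.total_overlap(iv) / len(iv) <= max_frac
    ]
    return PeakSet(peaks.label, kept)


def filter_blacklist(peaks: PeakSet, blacklist: PeakSet) -> PeakSet:
    """Drop peaks overlapping any blacklist interval by >= 1 base."""
    bl_index = PeakIndex(blacklist.intervals)
    return PeakSet(peaks.label, [iv for iv in peaks if not bl_index.any_overlap(iv)])
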