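"""Genomic interval algebra and BED/chrom.sizes I/O.

All coordinates are 0-based half-open (BED convention). Every downstream
stage of the pipeline — consensus building, motif scanning, co-occupancy
classification, regulatory-domain association — operates on the
:class:`GenomicInterval` / :class:`PeakSet` types defined here.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, Iterator, List, Optional

from intervaltree import IntervalTree

__all__ = [
    "GenomicInterval",
    "PeakSet",
    "PeakIndex",
    "read_chrom_sizes",
    "write_chrom_sizes",
    "parse_bed",
    "write_bed",
    "merge_union",
    "overlap_fraction",
    "resize_centered",
]

#: Mapping from chromosome name to its length in bases.
ChromSizes = Dict[str, int]


class BedParseError(ValueError):
    """A BED line could not be parsed (message names the line number)."""


@dataclass(frozen=True, slots=True)
class GenomicInterval:
    """A half-open genomic interval ``chrom:[start, end)``.

    ``strand`` is ``"+"``, ``"-"`` or ``"."`` (unstranded). ``name`` and
    ``score`` are optional BED columns 4 and 5.
    """

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: Optional[str] = None
    score: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        """Lower-median midpoint, ``floor((start + end) / 2)``."""
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def intersection_length(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass
class PeakSet:
    """A labelled collection of :class:`GenomicInterval`."""

    label: str
    intervals: List[GenomicInterval] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def sorted(self) -> "PeakSet":
        return PeakSet(
            self.label,
            sorted(self.intervals, key=lambda iv: (iv.chrom, iv.start, iv.end)),
        )

    def with_ids(self, prefix: str = "peak") -> "PeakSet":
        """Return a sorted copy whose intervals carry sequential names."""
        ivs = sorted(self.intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
        width = max(5, len(str(len(ivs))))
        return PeakSet(
            self.label,
            [replace(iv, name=f"{prefix}_{i:0{width}d}") for i, iv in enumerate(ivs)],
        )


class PeakIndex:
    """Per-chromosome interval tree over a peak collection for overlap queries."""

    def __init__(self, intervals: Iterable[GenomicInterval]):
        self._trees: Dict[str, IntervalTree] = {}
        for iv in intervals:
            self._trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, iv)

    def add(self, iv: GenomicInterval) -> None:
        self._trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, iv)

    def overlapping(self, iv: GenomicInterval) -> List[GenomicInterval]:
        tree = self._trees.get(iv.chrom)
        if tree is None:
            return []
        return sorted(
            (hit.data for hit in tree.overlap(iv.start, iv.end)),
            key=lambda x: (x.start, x.end),
        )

    def any_overlap(self, iv: GenomicInterval) -> bool:
        tree = self._trees.get(iv.chrom)
        return tree is not None and bool(tree.overlap(iv.start, iv.end))

    def total_overlap(self, iv: GenomicInterval) -> int:
        """Summed length of the intersections of ``iv`` with all indexed intervals.

        Overlapping indexed intervals are counted on their union, so the result
        never exceeds ``len(iv)``.
        """
        tree = self._trees.get(iv.chrom)
        if tree is None:
            return 0
        segs = sorted(
            (max(h.begin, iv.start), min(h.end, iv.end))
            for h in tree.overlap(iv.start, iv.end)
        )
        total = 0
        cur_s: Optional[int] = None
        cur_e = 0
        for s, e in segs:
            if cur_s is None:
                cur_s, cur_e = s, e
            elif s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                total += cur_e - cur_s
                cur_s, cur_e = s, e
        if cur_s is not None:
            total += cur_e - cur_s
        return total

    def at_point(self, chrom: str, pos: int) -> List[GenomicInterval]:
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        return [h.data for h in tree.at(pos)]


def read_chrom_sizes(path_or_text: str) -> ChromSizes:
    """Read a two-column ``chrom.sizes`` TSV (path or raw text)."""
    import os

    text = path_or_text
    if os.path.exists(path_or_text):
        with open(path_or_text) as fh:
            text = fh.read()
    sizes: ChromSizes = {}
    for i, line in enumerate(text.splitlines(), 1):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) < 2:
            raise ValueError(f"chrom.sizes line {i}: expected 2 columns")
        length = int(fields[1])
        if length <= 0:
            raise ValueError(f"chrom.sizes line {i}: non-positive length")
        sizes[fields[0]] = length
    return sizes


def write_chrom_sizes(sizes: ChromSizes) -> str:
    return "".join(f"{c}\t{n}\n" for c, n in sizes.items())


def parse_bed(
    text: str,
    chrom_sizes: Optional[ChromSizes] = None,
    label: str = "peaks",
) -> PeakSet:
    """Parse BED3/BED6/narrowPeak lines into a :class:`PeakSet`.

    Columns beyond name (4), score (5) and strand (6) are ignored. When
    ``chrom_sizes`` is given, unknown chromosomes and intervals exceeding the
    chromosome length are rejected.
    """
    intervals: List[GenomicInterval] = []
    for i, line in enumerate(text.splitlines(), 1):
        stripped = line.strip()
        if not stripped or stripped.startswith(("#", "track", "browser")):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise BedParseError(f"BED line {i}: expected >= 3 tab-separated fields")
        try:
            start, end = int(fields[1]), int(fields[2])
        except ValueError as exc:
            raise BedParseError(f"BED line {i}: non-integer coordinates") from exc
        name = fields[3] if len(fields) > 3 and fields[3] != "." else None
        score: Optional[float] = None
        if len(fields) > 4 and fields[4] not in (".", ""):
            try:
                score = float(fields[4])
            except ValueError as exc:
                raise BedParseError(f"BED line {i}: non-numeric score") from exc
        strand = fields[5] if len(fields) > 5 and fields[5] in ("+", "-") else "."
        try:
            iv = GenomicInterval(fields[0], start, end, strand, name, score)
        except ValueError as exc:
            raise ValueError(f"BED line {i}: {exc}") from exc
        if chrom_sizes is not None:
            if iv.chrom not in chrom_sizes:
                raise ValueError(f"BED line {i}: unknown chromosome {iv.chrom!r}")
            if iv.end > chrom_sizes[iv.chrom]:
                raise ValueError(
                    f"BED line {i}: interval end {iv.end} exceeds "
                    f"{iv.chrom} length {chrom_sizes[iv.chrom]}"
                )
        intervals.append(iv)
    return PeakSet(label, intervals)


def write_bed(peaks: PeakSet) -> str:
    """Serialise a PeakSet as BED (3–6 columns depending on populated fields)."""
    lines = []
    for iv in peaks.sorted():
        fields = [iv.chrom, str(iv.start), str(iv.end)]
        if iv.name is not None or iv.score is not None or iv.strand != ".":
            fields.append(iv.name if iv.name is not None else ".")
        if iv.score is not None or iv.strand != ".":
            fields.append(f"{iv.score:g}" if iv.score is not None else ".")
        if iv.strand != ".":
            fields.append(iv.strand)
        lines.append("\t".join(fields))
    return "\n".join(lines) + ("\n" if lines else "")


def merge_union(peaks: PeakSet, gap: int = 0) -> PeakSet:
    """Union-merge a peak set: minimal non-overlapping cover of the same bases.

    Intervals separated by ``<= gap`` bases are joined. Output is sorted by
    (chrom, start); names/scores of inputs are dropped.
    """
    if gap < 0:
        raise ValueError("gap must be >= 0")
    merged: List[GenomicInterval] = []
    for iv in sorted(peaks.intervals, key=lambda x: (x.chrom, x.start, x.end)):
        if (
            merged
            and merged[-1].chrom == iv.chrom
            and iv.start <= merged[-1].end + gap
        ):
            if iv.end > merged[-1].end:
                merged[-1] = GenomicInterval(iv.chrom, merged[-1].start, iv.end)
        else:
            merged.append(GenomicInterval(iv.chrom, iv.start, iv.end))
    return PeakSet(peaks.label, merged)


def overlap_fraction(a: GenomicInterval, b: GenomicInterval) -> float:
    """Fraction of ``a`` covered by ``b`` (directional, like bedtools ``-f``/``-F``)."""
    return a.intersection_length(b) / len(a)


def resize_centered(
    interval: GenomicInterval, width: int, chrom_sizes: ChromSizes
) -> GenomicInterval:
    """Return an interval of ``width`` bases centred on the input midpoint.

    Clamping at chromosome ends shortens (never shifts) the result.
    """
    if width <= 0:
        raise ValueError("width must be > 0")
    if interval.chrom not in chrom_sizes:
        raise ValueError(f"unknown chromosome {interval.chrom!r}")
    mid = interval.midpoint
    raw_start = mid - width // 2
    raw_end = raw_start + width
    start = max(0, raw_start)
    end = min(chrom_sizes[interval.chrom], raw_end)
    return GenomicInterval(
        interval.chrom, start, end, interval.strand, interval.name, interval.score
    )
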