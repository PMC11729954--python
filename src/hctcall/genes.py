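"""Gene models and refFlat-like annotation I/O.

One transcript model per gene id. Derived features (TSS, promoter window,
introns, UTRs, coding exons) are computed strand-aware from the exon layout
and CDS bounds, all in 0-based half-open coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

from .intervals import ChromSizes, GenomicInterval

__all__ = ["GeneModel", "read_refflat", "write_refflat", "genes_by_chrom"]


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    chrom: str
    strand: str  # "+" or "-"
    tx_start: int
    tx_end: int
    cds_start: int
    cds_end: int
    exons: Tuple[Tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError("gene strand must be + or -")
        if not (self.tx_start <= self.cds_start <= self.cds_end <= self.tx_end):
            raise ValueError(f"{self.gene_id}: CDS not within transcription span")
        prev_end = None
        for s, e in self.exons:
            if not (self.tx_start <= s < e <= self.tx_end):
                raise ValueError(f"{self.gene_id}: exon outside transcription span")
            if prev_end is not None and s < prev_end:
                raise ValueError(f"{self.gene_id}: exons overlap or unsorted")
            prev_end = e
        if not self.exons:
            raise ValueError(f"{self.gene_id}: gene must have >= 1 exon")
        if self.exons[0][0] != self.tx_start or self.exons[-1][1] != self.tx_end:
            raise ValueError(f"{self.gene_id}: exons must span tx bounds")

    @property
    def tss(self) -> int:
        """Transcription start site: tx_start on +, tx_end on - (position of the
        first transcribed base; on - the TSS base is tx_end - 1, and windows
        below are anchored at tx_end for half-open symmetry)."""
        return self.tx_start if self.strand == "+" else self.tx_end

    def promoter(
        self, up: int = 1000, down: int = 1000, chrom_sizes: Optional[ChromSizes] = None
    ) -> GenomicInterval:
        """Strand-aware promoter window: ``up`` bases upstream through ``down``
        bases downstream of the TSS."""
        if self.strand == "+":
            s, e = self.tss - up, self.tss + down
        else:
            s, e = self.tss - down, self.tss + up
        s = max(0, s)
        if chrom_sizes is not None:
            e = min(e, chrom_sizes[self.chrom])
        return GenomicInterval(self.chrom, s, e, self.strand, f"{self.gene_id}_prom")

    @property
    def introns(self) -> List[GenomicInterval]:
        out = []
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if e1 < s2:
                out.append(GenomicInterval(self.chrom, e1, s2, self.strand))
        return out

    def _utr_intervals(self, left: bool) -> List[GenomicInterval]:
        # Left: exonic sequence in [tx_start, cds_start); right: [cds_end, tx_end).
        out = []
        for s, e in self.exons:
            if left:
                lo, hi = max(s, self.tx_start), min(e, self.cds_start)
            else:
                lo, hi = max(s, self.cds_end), min(e, self.tx_end)
            if lo < hi:
                out.append(GenomicInterval(self.chrom, lo, hi, self.strand))
        return out

    @property
    def utr5(self) -> List[GenomicInterval]:
        return self._utr_intervals(left=self.strand == "+")

    @property
    def utr3(self) -> List[GenomicInterval]:
        return self._utr_intervals(left=self.strand == "-")

    @property
    def coding_exons(self) -> List[GenomicInterval]:
        out = []
        for s, e in self.exons:
            lo, hi = max(s, self.cds_start), min(e, self.cds_end)
            if lo < hi:
                out.append(GenomicInterval(self.chrom, lo, hi, self.strand))
        return out

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(
            self.chrom, self.tx_start, self.tx_end, self.strand, self.gene_id
        )


def read_refflat(path_or_text: str) -> List[GeneModel]:
    """Read a refFlat-like TSV: gene_id, chrom, strand, txStart, txEnd,
    cdsStart, cdsEnd, exonCount, exonStarts, exonEnds (comma-separated)."""
    import os

    text = path_or_text
    if os.path.exists(path_or_text):
        with open(path_or_text) as fh:
            text = fh.read()
    genes = []
    for i, line in enumerate(text.splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        f = line.rstrip("\n").split("\t")
        if len(f) < 10:
            raise ValueError(f"annotation line {i}: expected 10 columns")
        starts = [int(x) for x in f[8].rstrip(",").split(",")]
        ends = [int(x) for x in f[9].rstrip(",").split(",")]
        if len(starts) != int(f[7]) or len(ends) != int(f[7]):
            raise ValueError(f"annotation line {i}: exonCount mismatch")
        genes.append(
            GeneModel(
                gene_id=f[0],
                chrom=f[1],
                strand=f[2],
                tx_start=int(f[3]),
                tx_end=int(f[4]),
                cds_start=int(f[5]),
                cds_end=int(f[6]),
                exons=tuple(zip(starts, ends)),
            )
        )
    return genes


def write_refflat(genes: List[GeneModel]) -> str:
    lines = []
    for g in genes:
        starts = ",".join(str(s) for s, _ in g.exons) + ","
        ends = ",".join(str(e) for _, e in g.exons) + ","
        lines.append(
            "\t".join(
                [
                    g.gene_id,
                    g.chrom,
                    g.strand,
                    str(g.tx_start),
                    str(g.tx_end),
                    str(g.cds_start),
                    str(g.cds_end),
                    str(len(g.exons)),
                    starts,
                    ends,
                ]
            )
        )
    return "\n".join(lines) + ("\n" if lines else "")


def genes_by_chrom(genes: List[GeneModel]) -> Dict[str, List[GeneModel]]:
    """Group genes per chromosome, sorted by transcription start."""
    out: Dict[str, List[GeneModel]] = {}
    for g in genes:
        out.setdefault(g.chrom, []).append(g)
    for chrom in out:
        out[chrom].sort(key=lambda g: (g.tx_start, g.tx_end, g.gene_id))
    return out
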