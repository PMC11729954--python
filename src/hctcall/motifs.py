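"""IUPAC consensus motif scanning of peak sequences.

A consensus pattern such as the RUNX site RCCRCA (R = A/G) is expanded to its
concrete DNA words; with both strands requested the reverse complements are
unioned in, which for RCCRCA yields exactly eight words. Peaks are then
scanned for any word of the expanded set, counting each start position once,
and split into motif-bearing (TF_TFBS) and motif-lacking (TF_noTFBS) subsets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Dict, Iterable, List, Mapping, Sequence, Set, Tuple

import numpy as np

from .intervals import GenomicInterval, PeakSet

__all__ = [
    "IUPAC",
    "MotifSpec",
    "MotifAnnotation",
    "expand_iupac",
    "reverse_complement",
    "scan_sequence",
    "scan_peak_motifs",
    "split_by_motif",
    "get_sequence",
]

IUPAC: Dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def reverse_complement(word: str) -> str:
    return word.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class MotifSpec:
    """A named IUPAC consensus motif."""

    tf_name: str
    pattern: str
    both_strands: bool = True

    def __post_init__(self) -> None:
        if not self.pattern:
            raise ValueError("motif pattern must be non-empty")
        for ch in self.pattern.upper():
            if ch not in IUPAC:
                raise ValueError(f"invalid IUPAC letter {ch!r} in pattern")

    @property
    def words(self) -> frozenset:
        return frozenset(expand_iupac(self.pattern, self.both_strands))


@dataclass
class MotifAnnotation:
    """Per-peak motif hit record. ``has_motif`` iff ``count >= 1``."""

    peak_id: str
    count: int
    positions: List[int] = field(default_factory=list)  # offsets within the peak

    @property
    def has_motif(self) -> bool:
        return self.count >= 1


def expand_iupac(pattern: str, both_strands: bool = True) -> Set[str]:
    """All concrete DNA words matching an IUPAC pattern (upper-case).

    With ``both_strands`` the reverse complements are unioned in; set
    semantics deduplicate palindromic words.
    """
    pattern = pattern.upper()
    try:
        choices = [IUPAC[ch] for ch in pattern]
    except KeyError as exc:
        raise ValueError(f"invalid IUPAC letter {exc.args[0]!r}") from exc
    words = {"".join(w) for w in product(*choices)}
    if both_strands:
        words |= {reverse_complement(w) for w in words}
    return words


_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


def _encode(seq: str) -> np.ndarray:
    """Encode a sequence as uint8; non-ACGT letters get code 255 (never match)."""
    table = np.full(256, 255, dtype=np.uint8)
    for base, code in _BASE_CODE.items():
        table[ord(base)] = code
        table[ord(base.lower())] = code
    return table[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def scan_sequence(seq: str, words: Iterable[str]) -> List[int]:
    """Start offsets (0-based) where any word of the set occurs in ``seq``.

    Overlapping occurrences are all reported; each start position is counted
    once against the whole word set. Case-insensitive; positions containing
    non-ACGT letters never match.
    """
    words = list(words)
    if not words:
        return []
    k = len(words[0])
    if any(len(w) != k for w in words):
        raise ValueError("all words in a scan set must have equal length")
    n = len(seq)
    if n < k:
        return []
    enc = _encode(seq)
    n_pos = n - k + 1
    hit = np.zeros(n_pos, dtype=bool)
    for word in words:
        acc = np.ones(n_pos, dtype=bool)
        for j, ch in enumerate(word.upper()):
            acc &= enc[j : j + n_pos] == _BASE_CODE[ch]
            if not acc.any():
                break
        hit |= acc
    return np.flatnonzero(hit).tolist()


def get_sequence(genome, chrom: str, start: int, end: int) -> str:
    """Fetch ``chrom:[start, end)`` from a dict of strings or a pyfaidx.Fasta."""
    record = genome[chrom]
    if isinstance(record, str):
        if end > len(record):
            raise ValueError(
                f"interval {chrom}:{start}-{end} beyond sequence end {len(record)}"
            )
        return record[start:end]
    if end > len(record):
        raise ValueError(
            f"interval {chrom}:{start}-{end} beyond sequence end {len(record)}"
        )
    return str(record[start:end])


def scan_peak_motifs(
    genome, peaks: PeakSet, spec: MotifSpec
) -> Dict[str, MotifAnnotation]:
    """Scan every peak for the motif; returns annotations keyed by peak name.

    Peaks must carry names (use :meth:`PeakSet.with_ids` first).
    """
    words = sorted(spec.words)
    out: Dict[str, MotifAnnotation] = {}
    for iv in peaks:
        if iv.name is None:
            raise ValueError("peaks must carry names before motif scanning")
        seq = get_sequence(genome, iv.chrom, iv.start, iv.end)
        positions = scan_sequence(seq, words)
        out[iv.name] = MotifAnnotation(iv.name, len(positions), positions)
    return out


def split_by_motif(
    peaks: PeakSet, annotations: Mapping[str, MotifAnnotation]
) -> Tuple[PeakSet, PeakSet]:
    """Partition peaks into (TF_TFBS, TF_noTFBS) by ``has_motif``."""
    with_motif: List[GenomicInterval] = []
    without: List[GenomicInterval] = []
    for iv in peaks:
        if iv.name is None or iv.name not in annotations:
            raise ValueError(f"peak {iv.name!r} lacks a motif annotation")
        (with_motif if annotations[iv.name].has_motif else without).append(iv)
    return (
        PeakSet(f"{peaks.label}_TFBS", with_motif),
        PeakSet(f"{peaks.label}_noTFBS", without),
    )
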