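"""Core coordinate and sequence types.

All internal coordinates are 0-based half-open on the forward genomic
strand; 1-based inclusive conventions (GTF, printed coordinates) are
converted at I/O boundaries only.  Strand is ``"+"`` or ``"-"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Tuple

import numpy as np

STRANDS = ("+", "-")

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A stranded, 0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def contains(self, other: "GenomicInterval", stranded: bool = False) -> bool:
        if self.chrom != other.chrom:
            return False
        if stranded and self.strand != other.strand:
            return False
        return self.start <= other.start and other.end <= self.end

    def overlaps(self, other: "GenomicInterval", stranded: bool = True) -> bool:
        if self.chrom != other.chrom:
            return False
        if stranded and self.strand != other.strand:
            return False
        return self.start < other.end and other.start < self.end

    def shift(self, delta: int) -> "GenomicInterval":
        return GenomicInterval(self.chrom, self.start + delta, self.end + delta, self.strand)

    @property
    def acceptor_pos(self) -> int:
        """Genomic offset of the 3'SS boundary (exon 5' end in transcript order)."""
        return self.start if self.strand == "+" else self.end

    @property
    def donor_pos(self) -> int:
        """Genomic offset of the 5'SS boundary (exon 3' end in transcript order)."""
        return self.end if self.strand == "+" else self.start


@dataclass
class ReadAlignment:
    """One trapped product: its genomic span plus aligned blocks.

    A single block is a simple exon; two blocks are a candidate doublet
    (two exons trapped from one fragment).
    """

    interval: GenomicInterval
    blocks: List[GenomicInterval]
    mapq: int = 60
    clipped: bool = False
    library_id: str = "lib1"
    vector_id: str = "vec0"

    def __post_init__(self) -> None:
        iv = self.interval
        prev_end = -1
        for b in self.blocks:
            if b.chrom != iv.chrom or b.strand != iv.strand:
                raise ValueError("block chrom/strand must match interval")
            if b.start < prev_end:
                raise ValueError("blocks must be sorted and non-overlapping")
            if b.start < iv.start or b.end > iv.end:
                raise ValueError("blocks must lie within the read interval")
            prev_end = b.end


@dataclass
class ExonCluster:
    """A candidate exon: collapsed reads with identical ends."""

    interval: GenomicInterval
    counts_by_library: Dict[str, int] = field(default_factory=dict)

    @property
    def total_reads(self) -> int:
        return sum(self.counts_by_library.values())

    @property
    def acceptor_pos(self) -> int:
        return self.interval.acceptor_pos

    @property
    def donor_pos(self) -> int:
        return self.interval.donor_pos

    def key(self) -> Tuple[str, int, int, str]:
        iv = self.interval
        return (iv.chrom, iv.start, iv.end, iv.strand)


@dataclass
class TranscriptModel:
    gene_id: str
    transcript_id: str
    gene_type: str  # protein_coding, lncRNA, other
    strand: str
    exons: List[GenomicInterval]

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"transcript {self.transcript_id} has zero exons")
        self.exons = sorted(self.exons, key=lambda e: (e.start, e.end))
        chrom = self.exons[0].chrom
        prev_end = -1
        for e in self.exons:
            if e.chrom != chrom or e.strand != self.strand:
                raise ValueError(
                    f"transcript {self.transcript_id}: exons on mixed chrom/strand"
                )
            if e.start < prev_end:
                raise ValueError(
                    f"transcript {self.transcript_id}: overlapping exons"
                )
            prev_end = e.end

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.exons[0].start, self.exons[-1].end, self.strand)

    def exons_in_transcription_order(self) -> List[GenomicInterval]:
        return self.exons if self.strand == "+" else list(reversed(self.exons))


@dataclass
class ScoreTrack:
    """Per-base real values over one chromosome (NaN marks missing)."""

    chrom: str
    strand: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    def __len__(self) -> int:
        return len(self.values)

    def mean_ignoring_missing(self, start: int, end: int) -> float:
        window = self.values[start:end]
        finite = window[np.isfinite(window)]
        return float(finite.mean()) if finite.size else float("nan")


@dataclass
class RepeatInstance:
    """A genomic hit of a repeat family, with its span on the family's
    consensus model.  ``interval.strand`` is the hit orientation."""

    family: str
    interval: GenomicInterval
    consensus_start: int
    consensus_end: int
    consensus_length: int

    def __post_init__(self) -> None:
        if not (0 <= self.consensus_start < self.consensus_end <= self.consensus_length):
            raise ValueError("invalid consensus span")


class Genome:
    """In-memory genome: chromosome name -> uppercase sequence string."""

    def __init__(self, sequences: Mapping[str, str]):
        self._seqs = {name: seq.upper() for name, seq in sequences.items()}

    @classmethod
    def from_fasta(cls, path: str) -> "Genome":
        from pyfaidx import Fasta

        fa = Fasta(str(path), as_raw=True, sequence_always_upper=True)
        return cls({name: str(fa[name][:]) for name in fa.keys()})

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._seqs

    def chroms(self) -> List[str]:
        return list(self._seqs)

    def length(self, chrom: str) -> int:
        return len(self._seqs[chrom])

    @property
    def chrom_sizes(self) -> Dict[str, int]:
        return {c: len(s) for c, s in self._seqs.items()}

    def sequence(self, chrom: str) -> str:
        return self._seqs[chrom]

    def fetch(self, chrom: str, start: int, end: int, strand: str = "+") -> str:
        """Sequence of [start, end); reverse-complemented for the minus strand."""
        if chrom not in self._seqs:
            raise KeyError(f"unknown chromosome {chrom!r}")
        if start < 0 or end > len(self._seqs[chrom]):
            raise IndexError(
                f"window {chrom}:{start}-{end} outside chromosome of length "
                f"{len(self._seqs[chrom])}"
            )
        seq = self._seqs[chrom][start:end]
        return reverse_complement(seq) if strand == "-" else seq

    def fetch_interval(self, iv: GenomicInterval) -> str:
        """Transcribed-orientation sequence of an interval."""
        return self.fetch(iv.chrom, iv.start, iv.end, iv.strand)


def validate_intervals(intervals: Iterable[GenomicInterval], chrom_sizes: Optional[Mapping[str, int]] = None) -> None:
    """Walk pipeline outputs and assert every interval is well formed."""
    for iv in intervals:
        # construction already enforces 0 <= start < end and a legal strand
        if chrom_sizes is not None:
            if iv.chrom not in chrom_sizes:
                raise ValueError(f"interval on unknown chromosome {iv.chrom!r}")
            if iv.end > chrom_sizes[iv.chrom]:
                raise ValueError(
                    f"interval {iv} extends past chromosome end {chrom_sizes[iv.chrom]}"
                )
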