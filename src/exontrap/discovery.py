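"""De novo exon prediction from splice-site score tracks.

An exon is predicted wherever an acceptor position and a donor position
both score at or above the threshold and sit an internal-exon length
apart (63-222 bp by default, the 10th/90th percentiles of annotated
internal mRNA exon lengths).  The same scan on a dinucleotide-shuffled
sequence gives the fortuitous-site null.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np

from .core import Genome, GenomicInterval, ScoreTrack
from .regions import venn_counts
from .signals import SpliceSiteModel
from .simulate import shuffle_dinucleotide


@dataclass
class FinderConfig:
    score_threshold: float = 6.0
    min_spacing: int = 63
    max_spacing: int = 222
    reduce: str = "all_pairs"  # or best_per_acceptor

    def __post_init__(self) -> None:
        if not (0 < self.min_spacing <= self.max_spacing):
            raise ValueError("require 0 < min_spacing <= max_spacing")
        if self.reduce not in ("all_pairs", "best_per_acceptor"):
            raise ValueError(f"unknown reduce mode {self.reduce!r}")


@dataclass
class PredictedExon:
    interval: GenomicInterval
    acceptor_score: float
    donor_score: float


def find_exons_from_tracks(
    donor: ScoreTrack, acceptor: ScoreTrack, config: FinderConfig
) -> List[PredictedExon]:
    """All (acceptor, donor) position pairs with both scores >= threshold
    and an exon length within the spacing band.  ``best_per_acceptor``
    keeps the max-donor-score partner per acceptor (tie: shortest exon)."""
    if donor.chrom != acceptor.chrom or donor.strand != acceptor.strand:
        raise ValueError("donor and acceptor tracks must share chrom and strand")
    strand = donor.strand
    thr = config.score_threshold
    d_vals, a_vals = donor.values, acceptor.values
    with np.errstate(invalid="ignore"):
        d_pos = np.flatnonzero(d_vals >= thr)
        a_pos = np.flatnonzero(a_vals >= thr)
    out: List[PredictedExon] = []
    for a in a_pos:
        if strand == "+":
            lo = np.searchsorted(d_pos, a + config.min_spacing, side="left")
            hi = np.searchsorted(d_pos, a + config.max_spacing, side="right")
            partners = d_pos[lo:hi]
        else:
            lo = np.searchsorted(d_pos, a - config.max_spacing, side="left")
            hi = np.searchsorted(d_pos, a - config.min_spacing, side="right")
            partners = d_pos[lo:hi][::-1]  # nearest (shortest exon) first
        if partners.size == 0:
            continue
        if config.reduce == "best_per_acceptor":
            scores = d_vals[partners]
            partners = partners[[int(np.argmax(scores))]]  # argmax -> first=shortest on tie
        for d in partners:
            start, end = (a, d) if strand == "+" else (d, a)
            out.append(
                PredictedExon(
                    GenomicInterval(donor.chrom, int(start), int(end), strand),
                    acceptor_score=float(a_vals[a]),
                    donor_score=float(d_vals[d]),
                )
            )
    out.sort(key=lambda p: (p.interval.start, p.interval.end))
    return out


def find_exons_in_genome(
    model: SpliceSiteModel, genome: Genome, config: FinderConfig, strands: str = "+-"
) -> List[PredictedExon]:
    """Score every base of every chromosome and run the finder."""
    out: List[PredictedExon] = []
    for chrom in genome.chroms():
        for strand in strands:
            donor, acceptor = model.score_tracks(genome, chrom, strand)
            out.extend(find_exons_from_tracks(donor, acceptor, config))
    return out


def null_exon_scan(
    seq: str, model: SpliceSiteModel, config: FinderConfig, seed: int
) -> Tuple[int, int]:
    """(exons found on seq, exons found on its dinucleotide-preserving
    shuffle); the forward strand is scanned."""
    n_real = _count_on_sequence(seq, model, config)
    n_shuffled = _count_on_sequence(shuffle_dinucleotide(seq, seed), model, config)
    return n_real, n_shuffled


def _count_on_sequence(seq: str, model: SpliceSiteModel, config: FinderConfig) -> int:
    genome = Genome({"q": seq})
    donor, acceptor = model.score_tracks(genome, "q", "+")
    return len(find_exons_from_tracks(donor, acceptor, config))


def compare_exon_sets(
    sets: Mapping[str, Sequence[GenomicInterval]], mode: str = "perfect"
) -> Dict[Tuple[str, ...], int]:
    """Venn cell counts over 2-4 labeled exon sets."""
    if len(sets) > 4:
        raise ValueError("compare_exon_sets accepts at most 4 sets")
    return venn_counts(sets, mode)
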