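"""Splice-site scoring, enhancer-motif counting and positional profiles.

Splice sites are scored over the standard fixed windows: the donor (5'SS)
window is 9 bases (3 exonic + 6 intronic, exon|GTxxxx), the acceptor
(3'SS) window is 23 bases (20 intronic + 3 exonic, ...AG|exon).  Two
scorer back ends share this interface: a position log-odds matrix trained
from example windows, and an exhaustive window->score lookup table so
externally computed score tables (e.g. maximum-entropy scores) can be
used bit-exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .core import Genome, GenomicInterval, ScoreTrack, reverse_complement

logger = logging.getLogger("exontrap")

DONOR_WIDTH = 9
DONOR_EXONIC = 3  # window = [boundary-3, boundary+6) on +
ACCEPTOR_WIDTH = 23
ACCEPTOR_INTRONIC = 20  # window = [boundary-20, boundary+3) on +

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}


def _encode(seq: str) -> np.ndarray:
    """A=0 C=1 G=2 T=3, anything else -1."""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    out = np.full(arr.shape, -1, dtype=np.int8)
    for base, idx in _BASE_INDEX.items():
        out[arr == ord(base)] = idx
    return out


@dataclass
class MotifSet:
    name: str
    hexamers: frozenset

    def __post_init__(self) -> None:
        self.hexamers = frozenset(h.upper() for h in self.hexamers)
        for h in self.hexamers:
            if len(h) != 6 or any(c not in BASES for c in h):
                raise ValueError(f"motif {h!r} is not an ACGT hexamer")

    def __contains__(self, word: str) -> bool:
        return word in self.hexamers


@dataclass
class SignalProfile:
    """Mean signal per offset around a splice site; positive offsets run
    exon-ward from the boundary."""

    offsets: np.ndarray
    values: np.ndarray
    n: int


@dataclass
class SpliceSiteModel:
    """Donor/acceptor site scorer.

    ``donor_matrix``/``acceptor_matrix`` are per-position log2-odds over
    ACGT.  When ``tables`` is set the model is an exhaustive lookup and
    matrix scoring is bypassed.
    """

    donor_matrix: Optional[np.ndarray] = None
    acceptor_matrix: Optional[np.ndarray] = None
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    pseudocount: float = 1.0
    source: str = "trained"
    tables: Optional[Dict[str, Dict[str, float]]] = None

    # -- constructors -------------------------------------------------------

    @classmethod
    def train(
        cls,
        donor_examples: Sequence[str],
        acceptor_examples: Sequence[str],
        background: Optional[Sequence[float]] = None,
        pseudocount: float = 1.0,
    ) -> "SpliceSiteModel":
        """Position log-odds from example windows.

        Entry = log2((count + pseudocount*bg) / (n + pseudocount) / bg).
        """
        bg = np.full(4, 0.25) if background is None else np.asarray(background, float)
        if pseudocount <= 0:
            raise ValueError("pseudocount must be > 0")

        def fit(examples: Sequence[str], width: int, kind: str) -> np.ndarray:
            if not examples:
                raise ValueError(f"need at least one {kind} example")
            counts = np.zeros((width, 4))
            for i, ex in enumerate(examples):
                if len(ex) != width:
                    raise ValueError(
                        f"{kind} example {i} has length {len(ex)}, expected {width}"
                    )
                code = _encode(ex.upper())
                for pos, b in enumerate(code):
                    if b >= 0:
                        counts[pos, b] += 1
            n = len(examples)
            probs = (counts + pseudocount * bg) / (n + pseudocount)
            return np.log2(probs / bg)

        return cls(
            donor_matrix=fit(donor_examples, DONOR_WIDTH, "donor"),
            acceptor_matrix=fit(acceptor_examples, ACCEPTOR_WIDTH, "acceptor"),
            background=bg,
            pseudocount=pseudocount,
            source="trained",
        )

    @classmethod
    def from_probabilities(
        cls,
        donor_probs: np.ndarray,
        acceptor_probs: np.ndarray,
        background: Optional[Sequence[float]] = None,
    ) -> "SpliceSiteModel":
        """Log2-odds model straight from generating position probabilities."""
        bg = np.full(4, 0.25) if background is None else np.asarray(background, float)
        with np.errstate(divide="ignore"):
            dm = np.log2(np.asarray(donor_probs, float) / bg)
            am = np.log2(np.asarray(acceptor_probs, float) / bg)
        return cls(donor_matrix=dm, acceptor_matrix=am, background=bg, source="trained")

    @classmethod
    def from_score_table(cls, tables: Mapping[str, Mapping[str, float]]) -> "SpliceSiteModel":
        tbl = {k: dict(v) for k, v in tables.items()}
        for kind, width in (("donor", DONOR_WIDTH), ("acceptor", ACCEPTOR_WIDTH)):
            for w in tbl.get(kind, {}):
                if len(w) != width:
                    raise ValueError(f"{kind} table window {w!r} has wrong width")
        return cls(tables=tbl, source="loaded")

    # -- scoring ------------------------------------------------------------

    def _matrix(self, kind: str) -> np.ndarray:
        m = self.donor_matrix if kind == "donor" else self.acceptor_matrix
        if m is None:
            raise ValueError(f"model has no {kind} matrix")
        return m

    def score_window(self, kind: str, window: str) -> float:
        window = window.upper()
        if self.tables is not None:
            return self.tables.get(kind, {}).get(window, float("nan"))
        m = self._matrix(kind)
        if len(window) != m.shape[0]:
            raise ValueError(f"{kind} window must have length {m.shape[0]}")
        code = _encode(window)
        if (code < 0).any():
            return float("nan")
        return float(m[np.arange(len(code)), code].sum())

    def max_score(self, kind: str) -> float:
        return float(self._matrix(kind).max(axis=1).sum())

    def window_interval(self, kind: str, pos: int, strand: str) -> Tuple[int, int]:
        """Genomic span of the scoring window for a site boundary at pos."""
        if kind == "donor":
            up, down = DONOR_EXONIC, DONOR_WIDTH - DONOR_EXONIC
        elif kind == "acceptor":
            up, down = ACCEPTOR_INTRONIC, ACCEPTOR_WIDTH - ACCEPTOR_INTRONIC
        else:
            raise ValueError(f"unknown site kind {kind!r}")
        if strand == "+":
            return pos - up, pos + down
        return pos - down, pos + up

    def score_site(self, genome: Genome, chrom: str, pos: int, strand: str, kind: str) -> float:
        """Score the site whose exon boundary sits at genomic offset ``pos``."""
        lo, hi = self.window_interval(kind, pos, strand)
        if lo < 0 or hi > genome.length(chrom):
            logger.debug("site window %s:%d-%d out of range", chrom, lo, hi)
            return float("nan")
        return self.score_window(kind, genome.fetch(chrom, lo, hi, strand))

    def score_exon(self, genome: Genome, exon: GenomicInterval) -> Tuple[float, float]:
        """(acceptor_score, donor_score) for an exon interval."""
        a = self.score_site(genome, exon.chrom, exon.acceptor_pos, exon.strand, "acceptor")
        d = self.score_site(genome, exon.chrom, exon.donor_pos, exon.strand, "donor")
        return a, d

    # -- whole-chromosome tracks -------------------------------------------

    def score_tracks(self, genome: Genome, chrom: str, strand: str) -> Tuple[ScoreTrack, ScoreTrack]:
        """(donor, acceptor) per-base tracks: value at p = score of a site
        whose exon boundary is at p."""
        seq = genome.sequence(chrom)
        if self.tables is not None:
            donor = self._table_track(genome, chrom, strand, "donor")
            acceptor = self._table_track(genome, chrom, strand, "acceptor")
            return donor, acceptor
        donor = self._matrix_track(seq, strand, "donor")
        acceptor = self._matrix_track(seq, strand, "acceptor")
        return (
            ScoreTrack(chrom, strand, donor),
            ScoreTrack(chrom, strand, acceptor),
        )

    def _matrix_track(self, seq: str, strand: str, kind: str) -> np.ndarray:
        m = self._matrix(kind)
        width = m.shape[0]
        up = DONOR_EXONIC if kind == "donor" else ACCEPTOR_INTRONIC
        code = _encode(seq)
        if strand == "-":
            # score on the reverse complement, then map boundary positions back
            code = 3 - code[::-1]
            code[code > 3] = -1  # former N (-1 -> 4)
        L = len(code)
        total = np.zeros(max(L - width + 1, 0))
        bad = np.zeros(max(L - width + 1, 0), dtype=bool)
        for w in range(width):
            col = code[w : L - width + 1 + w]
            bad |= col < 0
            total += m[w][np.clip(col, 0, 3)]
        total[bad] = np.nan
        vals = np.full(L, np.nan)
        # window start s corresponds to boundary p = s + up (plus-orientation)
        starts = np.arange(len(total))
        p = starts + up
        keep = p < L
        vals[p[keep]] = total[keep]
        if strand == "-":
            out = np.full(L, np.nan)
            # boundary at reverse-orientation offset p' maps to genome p = L - p'
            pprime = np.arange(L)
            genome_p = L - pprime
            keep = (genome_p >= 0) & (genome_p < L)
            out[genome_p[keep]] = vals[pprime[keep]]
            return out
        return vals

    def _table_track(self, genome: Genome, chrom: str, strand: str, kind: str) -> ScoreTrack:
        L = genome.length(chrom)
        vals = np.full(L, np.nan)
        for p in range(L):
            lo, hi = self.window_interval(kind, p, strand)
            if lo < 0 or hi > L:
                continue
            vals[p] = self.score_window(kind, genome.fetch(chrom, lo, hi, strand))
        return ScoreTrack(chrom, strand, vals)


# ---------------------------------------------------------------------------
# training-window extraction
# ---------------------------------------------------------------------------

def site_windows(genome: Genome, exons: Iterable[GenomicInterval]) -> Tuple[List[str], List[str]]:
    """(donor_windows, acceptor_windows) for internal-exon boundaries,
    skipping windows that run off the chromosome or contain N."""
    donors, acceptors = [], []
    probe = SpliceSiteModel(donor_matrix=np.zeros((DONOR_WIDTH, 4)), acceptor_matrix=np.zeros((ACCEPTOR_WIDTH, 4)))
    for exon in exons:
        for kind, pos, sink in (
            ("donor", exon.donor_pos, donors),
            ("acceptor", exon.acceptor_pos, acceptors),
        ):
            lo, hi = probe.window_interval(kind, pos, exon.strand)
            if lo < 0 or hi > genome.length(exon.chrom):
                continue
            w = genome.fetch(exon.chrom, lo, hi, exon.strand)
            if "N" not in w:
                sink.append(w)
    return donors, acceptors


# ---------------------------------------------------------------------------
# enhancer/silencer motifs
# ---------------------------------------------------------------------------

def ese_density(seq: str, motifs: MotifSet) -> Tuple[int, float]:
    """Overlapping hexamer matches and the count per 100 bp of sequence."""
    seq = seq.upper()
    n = len(seq)
    if n < 6:
        return 0, 0.0
    count = sum(1 for p in range(n - 5) if seq[p : p + 6] in motifs)
    return count, 100.0 * count / n


def offset_control_interval(
    exon: GenomicInterval,
    offset: int,
    chrom_sizes: Optional[Mapping[str, int]] = None,
) -> Optional[GenomicInterval]:
    """Length-matched control region: shifted downstream of forward-strand
    exons (+offset) and upstream of reverse-strand exons (-offset) in
    genome coordinates."""
    delta = offset if exon.strand == "+" else -offset
    start, end = exon.start + delta, exon.end + delta
    if start < 0 or (chrom_sizes is not None and end > chrom_sizes.get(exon.chrom, np.inf)):
        logger.warning("control interval for %s out of range", exon)
        return None
    return GenomicInterval(exon.chrom, start, end, exon.strand)


def _motif_window(genome: Genome, exon: GenomicInterval, anchor: str, offset: int) -> Optional[str]:
    """Transcribed 6-mer covering exon-ward offsets [offset, offset+6) of
    the anchored boundary."""
    chrom = exon.chrom
    if anchor == "acceptor":
        pos, exonward = exon.acceptor_pos, (1 if exon.strand == "+" else -1)
    else:
        pos, exonward = exon.donor_pos, (-1 if exon.strand == "+" else 1)
    if exonward == 1:
        lo, hi = pos + offset, pos + offset + 6
    else:
        lo, hi = pos - offset - 6, pos - offset
    if lo < 0 or hi > genome.length(chrom):
        return None
    seq = genome.fetch(chrom, lo, hi)
    if exon.strand == "-":
        seq = reverse_complement(seq)
    # donor anchors read exon-ward against transcription; fetch above already
    # yields the transcribed 5'->3' sequence for both anchors
    return seq


def moving_average(values: np.ndarray, width: int) -> np.ndarray:
    """Centered moving average; shrinks the window at the edges so a
    constant input maps to itself."""
    if width <= 1:
        return np.asarray(values, float)
    v = np.asarray(values, float)
    mask = np.isfinite(v)
    kernel = np.ones(width)
    sums = np.convolve(np.where(mask, v, 0.0), kernel, mode="same")
    counts = np.convolve(mask.astype(float), kernel, mode="same")
    with np.errstate(invalid="ignore"):
        return np.where(counts > 0, sums / counts, np.nan)


def motif_frequency_profile(
    exons: Sequence[GenomicInterval],
    genome: Genome,
    motifs: MotifSet,
    anchor: str = "acceptor",
    halfwidth: int = 50,
    smooth: int = 19,
    exclude: Optional[Sequence[GenomicInterval]] = None,
) -> SignalProfile:
    """Per-offset fraction of exons carrying a motif at that position,
    smoothed with a centered moving average (default 19 bp).  ``exclude``
    drops exons overlapping any of the given intervals (e.g. repeats)."""
    if smooth % 2 == 0:
        raise ValueError("smooth width must be odd")
    if exclude:
        exons = [e for e in exons if not any(e.overlaps(r, stranded=False) for r in exclude)]
    if not exons:
        raise ValueError("no exons to profile")
    offsets = np.arange(-halfwidth, halfwidth)
    hits = np.zeros(len(offsets))
    n_seen = np.zeros(len(offsets))
    for exon in exons:
        for i, o in enumerate(offsets):
            w = _motif_window(genome, exon, anchor, int(o))
            if w is None or "N" in w:
                continue
            n_seen[i] += 1
            if w in motifs:
                hits[i] += 1
    with np.errstate(invalid="ignore"):
        raw = np.where(n_seen > 0, hits / n_seen, np.nan)
    return SignalProfile(offsets, moving_average(raw, smooth), len(exons))


def track_profile(
    exons: Sequence[GenomicInterval],
    track_by_chrom: Mapping[str, ScoreTrack],
    anchor: str = "acceptor",
    halfwidth: int = 50,
) -> SignalProfile:
    """Mean track value per exon-ward offset across exons; missing track
    values are excluded per offset."""
    if not exons:
        raise ValueError("no exons to profile")
    offsets = np.arange(-halfwidth, halfwidth)
    sums = np.zeros(len(offsets))
    counts = np.zeros(len(offsets))
    for exon in exons:
        track = track_by_chrom[exon.chrom]
        if anchor == "acceptor":
            pos, exonward = exon.acceptor_pos, (1 if exon.strand == "+" else -1)
        else:
            pos, exonward = exon.donor_pos, (-1 if exon.strand == "+" else 1)
        if exonward == 1:
            g = pos + offsets
        else:
            g = pos - 1 - offsets
        valid = (g >= 0) & (g < len(track.values))
        vals = np.full(len(offsets), np.nan)
        vals[valid] = track.values[g[valid]]
        finite = np.isfinite(vals)
        sums[finite] += vals[finite]
        counts[finite] += 1
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / counts, np.nan)
    return SignalProfile(offsets, means, len(exons))


STOP_CODONS = ("TAA", "TAG", "TGA")


def exon_properties(exon: GenomicInterval, genome: Genome) -> Tuple[int, float, Dict[int, bool]]:
    """(length, GC fraction, stop_by_frame) of an exon's transcribed body.

    ``stop_by_frame[f]`` is True iff a stop codon starts at a transcribed
    position congruent to f mod 3."""
    seq = genome.fetch_interval(exon)
    n = len(seq)
    gc = (seq.count("G") + seq.count("C")) / n if n else 0.0
    stops = {0: False, 1: False, 2: False}
    for p in range(n - 2):
        if seq[p : p + 3] in STOP_CODONS:
            stops[p % 3] = True
    return n, gc, stops
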