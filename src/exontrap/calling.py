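"""From filtered alignments to the trapped-exon catalog.

The chain mirrors the reporter-assay bookkeeping: quality filtering and
dark-cycle terminus restoration, collapse of identical-ended reads into
clusters, pooling across libraries, a single splice-site-guided terminus
adjustment of up to two bases followed by one re-collapse, removal of
reporter-intron artifacts, and selection of one primary exon per group of
overlapping clusters sharing a 3'SS (groups below the read threshold are
dropped).
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .core import ExonCluster, Genome, GenomicInterval, ReadAlignment
from .signals import SpliceSiteModel

logger = logging.getLogger("exontrap")


@dataclass
class CallingConfig:
    min_mapq: int = 20
    drop_clipped: bool = True
    dark_cycle_trim_by_library: Dict[str, int] = field(default_factory=dict)
    max_terminus_shift: int = 2
    min_group_reads: int = 100
    reporter_intron: Optional[GenomicInterval] = None

    def __post_init__(self) -> None:
        if self.max_terminus_shift < 0:
            raise ValueError("max_terminus_shift must be >= 0")
        if self.min_group_reads < 1:
            raise ValueError("min_group_reads must be >= 1")
        for lib, trim in self.dark_cycle_trim_by_library.items():
            if trim not in (3, 4):
                raise ValueError(f"dark-cycle trim for {lib!r} must be 3 or 4")


@dataclass
class PrimaryExon:
    """The representative (highest-count) exon of a shared-3'SS group."""

    exon: ExonCluster
    group_total: int
    members: int

    @property
    def interval(self) -> GenomicInterval:
        return self.exon.interval


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def preprocess_alignments(
    reads: Iterable[ReadAlignment], config: CallingConfig
) -> List[ReadAlignment]:
    """Filter on mapping quality and clipping, then extend the
    acceptor-side terminus outward by the library's dark-cycle trim."""
    out: List[ReadAlignment] = []
    dropped: Counter = Counter()
    for read in reads:
        if read.mapq < config.min_mapq:
            dropped["low_mapq"] += 1
            continue
        if config.drop_clipped and read.clipped:
            dropped["clipped"] += 1
            continue
        trim = config.dark_cycle_trim_by_library.get(read.library_id)
        if trim is None:
            raise ValueError(
                f"no dark-cycle trim configured for library {read.library_id!r}"
            )
        iv = read.interval
        if iv.strand == "+":
            new_iv = GenomicInterval(iv.chrom, iv.start - trim, iv.end, iv.strand)
        else:
            new_iv = GenomicInterval(iv.chrom, iv.start, iv.end + trim, iv.strand)
        blocks = list(read.blocks)
        if blocks:
            if iv.strand == "+":
                b = blocks[0]
                blocks[0] = GenomicInterval(b.chrom, new_iv.start, b.end, b.strand)
            else:
                b = blocks[-1]
                blocks[-1] = GenomicInterval(b.chrom, b.start, new_iv.end, b.strand)
        out.append(
            ReadAlignment(new_iv, blocks, read.mapq, read.clipped, read.library_id, read.vector_id)
        )
    if dropped:
        logger.info("preprocess_alignments dropped: %s", dict(dropped))
    return out


# ---------------------------------------------------------------------------
# collapse and pooling
# ---------------------------------------------------------------------------

def collapse_reads(reads: Iterable[ReadAlignment]) -> List[ExonCluster]:
    """One cluster per distinct (chrom, start, end, strand) with
    per-library read tallies; sorted by coordinates."""
    tallies: Dict[Tuple[str, int, int, str], Counter] = defaultdict(Counter)
    for read in reads:
        iv = read.interval
        tallies[(iv.chrom, iv.start, iv.end, iv.strand)][read.library_id] += 1
    clusters = [
        ExonCluster(GenomicInterval(*key), dict(counts)) for key, counts in tallies.items()
    ]
    clusters.sort(key=lambda c: c.key())
    return clusters


def pool_clusters(cluster_lists: Sequence[Sequence[ExonCluster]]) -> List[ExonCluster]:
    """Merge cluster lists by summing per-library counts of identical ends."""
    merged: Dict[Tuple[str, int, int, str], Counter] = defaultdict(Counter)
    for clusters in cluster_lists:
        for c in clusters:
            merged[c.key()].update(c.counts_by_library)
    out = [ExonCluster(GenomicInterval(*key), dict(cnt)) for key, cnt in merged.items()]
    out.sort(key=lambda c: c.key())
    return out


# ---------------------------------------------------------------------------
# splice-site-guided terminus adjustment
# ---------------------------------------------------------------------------

def _candidate_deltas(max_shift: int) -> List[int]:
    # tie-break order: smaller |delta| first, negative before positive
    out = []
    for mag in range(1, max_shift + 1):
        out.extend([-mag, mag])
    return out


def _adjust_terminus(
    scorer: SpliceSiteModel,
    genome: Genome,
    chrom: str,
    pos: int,
    strand: str,
    kind: str,
    max_shift: int,
) -> int:
    current = scorer.score_site(genome, chrom, pos, strand, kind)
    if np.isnan(current):
        logger.debug("terminus %s:%d window out of range; left unadjusted", chrom, pos)
        return pos
    best_pos, best_score = pos, current
    for delta in _candidate_deltas(max_shift):
        cand = scorer.score_site(genome, chrom, pos + delta, strand, kind)
        if np.isnan(cand):
            continue
        if cand > best_score:  # strict improvement; first-in-order wins ties
            best_pos, best_score = pos + delta, cand
    return best_pos


def adjust_and_merge(
    cluster_lists: Sequence[Sequence[ExonCluster]],
    scorer: SpliceSiteModel,
    genome: Genome,
    config: CallingConfig,
) -> List[ExonCluster]:
    """Pool libraries, shift each cluster terminus by up to
    ``max_terminus_shift`` bases toward a strictly higher-scoring splice
    site (acceptor score at the acceptor terminus, donor at the donor),
    then re-collapse newly identical clusters.  Applied once."""
    pooled = pool_clusters(cluster_lists)
    adjusted: List[ExonCluster] = []
    for c in pooled:
        iv = c.interval
        new_acc = _adjust_terminus(
            scorer, genome, iv.chrom, iv.acceptor_pos, iv.strand, "acceptor", config.max_terminus_shift
        )
        new_don = _adjust_terminus(
            scorer, genome, iv.chrom, iv.donor_pos, iv.strand, "donor", config.max_terminus_shift
        )
        if iv.strand == "+":
            start, end = new_acc, new_don
        else:
            start, end = new_don, new_acc
        if start >= end:  # degenerate after shifting; keep the original
            start, end = iv.start, iv.end
        adjusted.append(ExonCluster(GenomicInterval(iv.chrom, start, end, iv.strand), c.counts_by_library))
    return pool_clusters([adjusted])


# ---------------------------------------------------------------------------
# reporter removal and primary selection
# ---------------------------------------------------------------------------

def remove_reporter_exons(
    clusters: Sequence[ExonCluster], reporter: Optional[GenomicInterval]
) -> List[ExonCluster]:
    """Drop clusters fully contained in the reporter's native intron
    (any strand: reporter-derived products are artifacts whichever way
    they map)."""
    if reporter is None:
        return list(clusters)
    kept = [
        c
        for c in clusters
        if not reporter.contains(c.interval, stranded=False)
    ]
    n_removed = len(clusters) - len(kept)
    if n_removed:
        logger.info("removed %d reporter-intron clusters", n_removed)
    return kept


def group_clusters(clusters: Sequence[ExonCluster]) -> List[List[ExonCluster]]:
    """Connected components of the 'overlaps and shares the 3'SS position
    on the same strand' relation."""
    n = len(clusters)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri

    by_acceptor: Dict[Tuple[str, str, int], List[int]] = defaultdict(list)
    for i, c in enumerate(clusters):
        iv = c.interval
        by_acceptor[(iv.chrom, iv.strand, iv.acceptor_pos)].append(i)
    for bucket in by_acceptor.values():
        for i in bucket:
            for j in bucket:
                if i < j and clusters[i].interval.overlaps(clusters[j].interval):
                    union(i, j)
    groups: Dict[int, List[ExonCluster]] = defaultdict(list)
    for i, c in enumerate(clusters):
        groups[find(i)].append(c)
    return list(groups.values())


def call_primary_exons(
    clusters: Sequence[ExonCluster], config: CallingConfig
) -> List[PrimaryExon]:
    """Groups with >= ``min_group_reads`` pooled reads emit their
    max-count member as the primary exon (ties: longer, then leftmost)."""
    out: List[PrimaryExon] = []
    for group in group_clusters(clusters):
        total = sum(c.total_reads for c in group)
        if total < config.min_group_reads:
            continue
        primary = max(
            group,
            key=lambda c: (c.total_reads, c.interval.length, -c.interval.start),
        )
        out.append(PrimaryExon(primary, total, len(group)))
    out.sort(key=lambda p: p.exon.key())
    return out


def detect_doublets(
    reads: Iterable[ReadAlignment], max_span: int = 1000
) -> List[Tuple[GenomicInterval, GenomicInterval, int]]:
    """Candidate two-exon products: reads with exactly two blocks on one
    strand whose outer span fits in a library fragment."""
    tally: Counter = Counter()
    for read in reads:
        if len(read.blocks) != 2:
            continue
        if read.interval.length > max_span:
            continue
        b1, b2 = read.blocks
        tally[(b1.chrom, b1.start, b1.end, b2.start, b2.end, b1.strand)] += 1
    out = []
    for (chrom, s1, e1, s2, e2, strand), count in sorted(tally.items()):
        out.append(
            (
                GenomicInterval(chrom, s1, e1, strand),
                GenomicInterval(chrom, s2, e2, strand),
                count,
            )
        )
    return out


def call_exons(
    alignments_by_library: Mapping[str, Sequence[ReadAlignment]],
    scorer: SpliceSiteModel,
    genome: Genome,
    config: CallingConfig,
) -> Tuple[List[ExonCluster], List[PrimaryExon]]:
    """The full chain: preprocess -> collapse per library -> pool/adjust ->
    reporter removal -> primary selection.  Returns (all clusters,
    primary exons)."""
    per_library = []
    for _lib, reads in sorted(alignments_by_library.items()):
        per_library.append(collapse_reads(preprocess_alignments(reads, config)))
    pooled = adjust_and_merge(per_library, scorer, genome, config)
    pooled = remove_reporter_exons(pooled, config.reporter_intron)
    return pooled, call_primary_exons(pooled, config)
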