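"""Enrichment and summary statistics over trapped exons.

Repeat-family enrichment follows the base-level hypergeometric scheme:
with M stranded genome bases, n exon bases, N family bases and k exon
bases overlapping the family, the reported log p-value is the
hypergeometric log point-probability of k, and the enrichment ratio is
(k/N)/(n/M) — the family's exon rate relative to the global exon rate.
An upper-tail log survival value is also exposed for users wanting a
conventional one-sided test.
"""

from __future__ import annotations

import logging
from collections import Counter
from math import lgamma
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple, Union

import numpy as np
from scipy import stats as sps

from .core import Genome, GenomicInterval, RepeatInstance
from .regions import ClassifiedExon
from .signals import exon_properties
from .signals import moving_average

logger = logging.getLogger("exontrap")


# ---------------------------------------------------------------------------
# hypergeometric
# ---------------------------------------------------------------------------

def _log_choose(n: int, k: int) -> float:
    return lgamma(n + 1) - lgamma(k + 1) - lgamma(n - k + 1)


def hypergeometric_log_pmf(k: int, M: int, n: int, N: int) -> float:
    """Natural-log point probability of drawing k marked bases when N of
    M bases are drawn and n are marked (log-gamma arithmetic; stable for
    very large M).  Outside the support, -inf by convention."""
    if n > M or N > M:
        raise ValueError("require n <= M and N <= M")
    lo, hi = max(0, n + N - M), min(n, N)
    if not (lo <= k <= hi):
        logger.info("hypergeometric point %d outside support [%d, %d]", k, lo, hi)
        return float("-inf")
    return _log_choose(N, k) + _log_choose(M - N, n - k) - _log_choose(M, n)


def hypergeometric_log_sf(k: int, M: int, n: int, N: int) -> float:
    """Upper-tail log P(X >= k); the conventional enrichment test."""
    return float(sps.hypergeom.logsf(k - 1, M, n, N))


# ---------------------------------------------------------------------------
# repeat enrichment
# ---------------------------------------------------------------------------

@dataclass
class EnrichmentResult:
    family: str
    M: int
    n: int
    N: int
    k: int
    ratio: float
    log_p: float
    log_p_upper: float = float("nan")


def _stranded_bitmaps(
    intervals: Iterable[GenomicInterval], chrom_sizes: Mapping[str, int]
) -> Dict[Tuple[str, str], np.ndarray]:
    maps = {
        (c, s): np.zeros(size, dtype=bool)
        for c, size in chrom_sizes.items()
        for s in "+-"
    }
    for iv in intervals:
        maps[(iv.chrom, iv.strand)][iv.start : iv.end] = True
    return maps


def repeat_enrichment(
    exons: Sequence[GenomicInterval],
    repeat_instances: Sequence[RepeatInstance],
    chrom_sizes: Mapping[str, int],
) -> List[EnrichmentResult]:
    """Base-level exon enrichment per repeat family, ranked by log
    point-probability.  Bases are deduplicated before counting so nested
    or overlapping instances never double-count."""
    M = 2 * sum(chrom_sizes.values())
    exon_maps = _stranded_bitmaps(exons, chrom_sizes)
    n = int(sum(m.sum() for m in exon_maps.values()))
    families: Dict[str, List[RepeatInstance]] = {}
    for inst in repeat_instances:
        families.setdefault(inst.family, []).append(inst)
    out: List[EnrichmentResult] = []
    for family, instances in sorted(families.items()):
        fam_maps = _stranded_bitmaps((i.interval for i in instances), chrom_sizes)
        N = int(sum(m.sum() for m in fam_maps.values()))
        if N == 0:
            logger.info("family %s has zero genome bases; skipped", family)
            continue
        k = int(sum((fam_maps[key] & exon_maps[key]).sum() for key in fam_maps))
        ratio = (k / N) / (n / M) if n else float("nan")
        out.append(
            EnrichmentResult(
                family=family,
                M=M,
                n=n,
                N=N,
                k=k,
                ratio=ratio,
                log_p=hypergeometric_log_pmf(k, M, n, N),
                log_p_upper=hypergeometric_log_sf(k, M, n, N),
            )
        )
    out.sort(key=lambda r: r.log_p)
    return out


# ---------------------------------------------------------------------------
# consensus-coordinate pileup
# ---------------------------------------------------------------------------

@dataclass
class ConsensusPileup:
    consensus: str
    length: int
    coverage: np.ndarray


WeightedInterval = Union[GenomicInterval, Tuple[GenomicInterval, float]]


def _as_weighted(items: Iterable[object]) -> List[Tuple[GenomicInterval, float]]:
    out = []
    for item in items:
        if isinstance(item, GenomicInterval):
            out.append((item, 1.0))
        elif isinstance(item, tuple):
            out.append((item[0], float(item[1])))
        elif hasattr(item, "interval") and hasattr(item, "total_reads"):
            out.append((item.interval, float(item.total_reads)))
        elif hasattr(item, "interval"):
            out.append((item.interval, 1.0))
        else:
            raise TypeError(f"cannot interpret {item!r} as a weighted interval")
    return out


def consensus_pileup(
    exons_or_reads: Sequence[object],
    repeat_instances: Sequence[RepeatInstance],
) -> Dict[str, ConsensusPileup]:
    """Project genome overlaps onto repeat consensus coordinates.

    Each overlap between an item (weight = read count for clusters, 1
    for bare intervals) and an instance is mapped to the consensus by
    linear interpolation between the instance's genome span and its
    consensus span, flipped end-for-end for reverse-orientation hits.
    """
    weighted = _as_weighted(exons_or_reads)
    pileups: Dict[str, ConsensusPileup] = {}
    for inst in repeat_instances:
        if inst.family not in pileups:
            pileups[inst.family] = ConsensusPileup(
                inst.family, inst.consensus_length, np.zeros(inst.consensus_length)
            )
        giv = inst.interval
        g_len = giv.length
        if g_len == 0:
            continue
        c_len = inst.consensus_end - inst.consensus_start
        scale = c_len / g_len
        cov = pileups[inst.family].coverage
        for iv, weight in weighted:
            if iv.chrom != giv.chrom:
                continue
            os_, oe = max(iv.start, giv.start), min(iv.end, giv.end)
            if os_ >= oe:
                continue
            if giv.strand == "+":
                c1 = inst.consensus_start + (os_ - giv.start) * scale
                c2 = inst.consensus_start + (oe - giv.start) * scale
            else:
                c1 = inst.consensus_end - (oe - giv.start) * scale
                c2 = inst.consensus_end - (os_ - giv.start) * scale
            lo = int(round(c1))
            hi = max(int(round(c2)), lo + 1)
            cov[lo : min(hi, inst.consensus_length)] += weight
    return pileups


# ---------------------------------------------------------------------------
# nonsense-mediated decay frame ratios
# ---------------------------------------------------------------------------

@dataclass
class NmdRecord:
    exon: GenomicInterval
    count_no_stop: int
    count_stop: int
    log2_ratio: float


def nmd_log_ratio(
    exons_with_counts: Sequence[Tuple[GenomicInterval, Mapping[str, int]]],
    frame_pair: Tuple[Tuple[str, int], Tuple[str, int]],
    genome: Genome,
) -> Tuple[List[NmdRecord], float, Dict[str, int]]:
    """Per-exon log2(no-stop vector count / stop vector count).

    ``frame_pair`` is ((vector_id, frame), (vector_id, frame)): the first
    vector must lack a stop codon in its reading frame, the second must
    carry one.  Eligible exons have length divisible by three and nonzero
    counts in both vectors.  Returns (records, median log2 ratio,
    exclusion tally).
    """
    (vec_ns, frame_ns), (vec_s, frame_s) = frame_pair
    records: List[NmdRecord] = []
    excluded: Counter = Counter()
    for iv, counts in exons_with_counts:
        if iv.length % 3 != 0:
            excluded["length_not_multiple_of_3"] += 1
            continue
        c_ns = counts.get(vec_ns, 0)
        c_s = counts.get(vec_s, 0)
        if c_ns <= 0 or c_s <= 0:
            excluded["zero_count"] += 1
            continue
        _, _, stops = exon_properties(iv, genome)
        if stops[frame_ns]:
            excluded["stop_in_no_stop_frame"] += 1
            continue
        if not stops[frame_s]:
            excluded["no_stop_in_stop_frame"] += 1
            continue
        records.append(NmdRecord(iv, c_ns, c_s, float(np.log2(c_ns / c_s))))
    median = float(np.median([r.log2_ratio for r in records])) if records else float("nan")
    return records, median, dict(excluded)


# ---------------------------------------------------------------------------
# capture-rate curves and category ratios
# ---------------------------------------------------------------------------

def capture_rate_curve(
    annotated: Sequence[GenomicInterval],
    values: Sequence[float],
    trapped: Sequence[GenomicInterval],
    bins: np.ndarray,
    smooth: int = 9,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Percent of annotated exons with a perfect-match trapped
    counterpart, per property bin; a centered moving average (default
    9 bins) smooths the curve.  Returns (bin_centers, percent, n_per_bin);
    empty bins are NaN."""
    if len(annotated) != len(values):
        raise ValueError("annotated and values must align")
    trapped_keys = {(t.chrom, t.start, t.end, t.strand) for t in trapped}
    hit = np.array(
        [(a.chrom, a.start, a.end, a.strand) in trapped_keys for a in annotated], dtype=float
    )
    values = np.asarray(values, dtype=float)
    bins = np.asarray(bins, dtype=float)
    idx = np.digitize(values, bins) - 1
    n_bins = len(bins) - 1
    pct = np.full(n_bins, np.nan)
    counts = np.zeros(n_bins)
    for b in range(n_bins):
        mask = idx == b
        counts[b] = mask.sum()
        if counts[b]:
            pct[b] = 100.0 * hit[mask].mean()
    centers = 0.5 * (bins[:-1] + bins[1:])
    if smooth > 1:
        pct = moving_average(pct, smooth)
    return centers, pct, counts


def category_count_ratio(
    classified: Sequence[ClassifiedExon], numerator_label: str, denominator_label: str
) -> float:
    """Count ratio between two exon categories (e.g. intronic vs
    antisense)."""
    num = sum(1 for c in classified if c.category == numerator_label)
    den = sum(1 for c in classified if c.category == denominator_label)
    if den == 0:
        raise ValueError(f"no exons in denominator category {denominator_label!r}")
    return num / den
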