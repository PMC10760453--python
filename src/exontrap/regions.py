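"""Stranded decomposition of the genome into annotation categories.

Every base of every (chromosome, strand) pair gets exactly one label:

    mRNA_exon_internal > mRNA_exon_terminal > lncRNA_exon >
    mRNA_intron > lncRNA_intron > antisense > intergenic

The precedence resolves overlapping annotation: exons beat introns,
sense transcripts beat the antisense shadow of an opposite-strand gene,
and protein-coding features beat lncRNA features at equal tier.
``antisense`` is the opposite-strand span of any transcript minus any
same-strand transcript.  Transcripts of gene_type ``other`` are treated
at the lncRNA tier.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np

from .core import GenomicInterval, TranscriptModel

LABELS = (
    "mRNA_exon_internal",
    "mRNA_exon_terminal",
    "mRNA_intron",
    "lncRNA_exon",
    "lncRNA_intron",
    "antisense",
    "intergenic",
)
_LABEL_INDEX = {name: i for i, name in enumerate(LABELS)}
BOUNDARY = "boundary_spanning"

# painting order: later paints override earlier ones
_PAINT_ORDER = (
    "antisense",
    "lncRNA_intron",
    "mRNA_intron",
    "lncRNA_exon",
    "mRNA_exon_terminal",
    "mRNA_exon_internal",
)


@dataclass
class RegionPartition:
    """Per-(chrom, strand) label array; index into :data:`LABELS`."""

    arrays: Dict[Tuple[str, str], np.ndarray]
    chrom_sizes: Dict[str, int]

    def label_at(self, chrom: str, strand: str, pos: int) -> str:
        return LABELS[self.arrays[(chrom, strand)][pos]]

    def labels_in(self, iv: GenomicInterval) -> np.ndarray:
        return self.arrays[(iv.chrom, iv.strand)][iv.start : iv.end]

    def base_counts(self) -> Dict[Tuple[str, str], Dict[str, int]]:
        out: Dict[Tuple[str, str], Dict[str, int]] = {}
        for key, arr in self.arrays.items():
            counts = np.bincount(arr, minlength=len(LABELS))
            out[key] = {name: int(counts[i]) for i, name in enumerate(LABELS)}
        return out

    def total_label_bases(self) -> Dict[str, int]:
        totals = {name: 0 for name in LABELS}
        for counts in self.base_counts().values():
            for name, n in counts.items():
                totals[name] += n
        return totals

    def validate(self) -> None:
        """Partition property: per-strand label counts sum to the
        chromosome length (exhaustive + exclusive is guaranteed by the
        single label array; this checks completeness)."""
        for (chrom, _strand), arr in self.arrays.items():
            if len(arr) != self.chrom_sizes[chrom]:
                raise AssertionError(f"partition array length mismatch on {chrom}")
            if arr.min() < 0 or arr.max() >= len(LABELS):
                raise AssertionError("unlabeled base in partition")


@dataclass
class ClassifiedExon:
    exon: object  # PrimaryExon or any object with .interval
    category: str

    @property
    def interval(self) -> GenomicInterval:
        return self.exon.interval if hasattr(self.exon, "interval") else self.exon


def _tier(gene_type: str) -> str:
    return "mRNA" if gene_type == "protein_coding" else "lncRNA"


def extract_internal_exons(
    transcripts: Sequence[TranscriptModel],
) -> Dict[str, Dict[str, Set[GenomicInterval]]]:
    """Per gene tier ('mRNA', 'lncRNA'), the deduplicated internal,
    first and last exon sets (first/last in transcription order)."""
    out: Dict[str, Dict[str, Set[GenomicInterval]]] = {
        tier: {"internal": set(), "first": set(), "last": set()}
        for tier in ("mRNA", "lncRNA")
    }
    for tx in transcripts:
        tier = _tier(tx.gene_type)
        exons = tx.exons_in_transcription_order()
        out[tier]["first"].add(exons[0])
        out[tier]["last"].add(exons[-1])
        for e in exons[1:-1]:
            out[tier]["internal"].add(e)
    return out


def build_region_partition(
    transcripts: Sequence[TranscriptModel],
    chrom_sizes: Mapping[str, int],
    attribute_filter=None,
) -> RegionPartition:
    """Paint the stranded genome by label precedence.

    ``attribute_filter`` optionally drops transcripts before painting
    (stands in for annotation-quality predicates such as transcript
    support level); default accepts all.
    """
    if attribute_filter is not None:
        transcripts = [tx for tx in transcripts if attribute_filter(tx)]
    arrays = {
        (chrom, strand): np.full(size, _LABEL_INDEX["intergenic"], dtype=np.int8)
        for chrom, size in chrom_sizes.items()
        for strand in "+-"
    }

    exon_sets = extract_internal_exons(transcripts)

    paint: Dict[str, List[Tuple[str, str, int, int]]] = {name: [] for name in _PAINT_ORDER}
    for tx in transcripts:
        span = tx.span
        tier = _tier(tx.gene_type)
        opposite = "-" if tx.strand == "+" else "+"
        paint["antisense"].append((span.chrom, opposite, span.start, span.end))
        intron_label = "mRNA_intron" if tier == "mRNA" else "lncRNA_intron"
        paint[intron_label].append((span.chrom, tx.strand, span.start, span.end))
    # exon labels override the intron paint of the whole span
    for e in exon_sets["lncRNA"]["internal"] | exon_sets["lncRNA"]["first"] | exon_sets["lncRNA"]["last"]:
        paint["lncRNA_exon"].append((e.chrom, e.strand, e.start, e.end))
    for e in exon_sets["mRNA"]["first"] | exon_sets["mRNA"]["last"]:
        paint["mRNA_exon_terminal"].append((e.chrom, e.strand, e.start, e.end))
    for e in exon_sets["mRNA"]["internal"]:
        paint["mRNA_exon_internal"].append((e.chrom, e.strand, e.start, e.end))

    for label in _PAINT_ORDER:
        idx = _LABEL_INDEX[label]
        for chrom, strand, start, end in paint[label]:
            arrays[(chrom, strand)][start:end] = idx

    partition = RegionPartition(arrays, dict(chrom_sizes))
    partition.validate()
    return partition


def classify_exons(exons: Sequence[object], partition: RegionPartition) -> List[ClassifiedExon]:
    """Category = the unique label covering every base of the exon on its
    strand, else ``boundary_spanning``."""
    out = []
    for exon in exons:
        iv = exon.interval if hasattr(exon, "interval") else exon
        labels = partition.labels_in(iv)
        uniq = np.unique(labels)
        category = LABELS[uniq[0]] if len(uniq) == 1 else BOUNDARY
        out.append(ClassifiedExon(exon, category))
    return out


def region_base_coverage(
    exons: Sequence[ClassifiedExon], partition: RegionPartition
) -> Dict[str, Tuple[int, int, float]]:
    """Per label: (exon-covered bases of that label, total label bases,
    percent covered).  Overlapping exons count once per base; labels with
    zero bases report NaN percent."""
    covered = {
        key: np.zeros(len(arr), dtype=bool) for key, arr in partition.arrays.items()
    }
    for ce in exons:
        iv = ce.interval
        covered[(iv.chrom, iv.strand)][iv.start : iv.end] = True
    out: Dict[str, Tuple[int, int, float]] = {}
    totals = partition.total_label_bases()
    for i, label in enumerate(LABELS):
        k = 0
        for key, arr in partition.arrays.items():
            k += int(np.count_nonzero(covered[key] & (arr == i)))
        total = totals[label]
        pct = 100.0 * k / total if total else float("nan")
        out[label] = (k, total, pct)
    return out


# ---------------------------------------------------------------------------
# interval-set joins and Venn tallies
# ---------------------------------------------------------------------------

def _key(iv: GenomicInterval) -> Tuple[str, int, int, str]:
    return (iv.chrom, iv.start, iv.end, iv.strand)


def join_by_overlap(
    query: Sequence[GenomicInterval],
    target: Sequence[GenomicInterval],
    mode: str = "perfect",
) -> List[bool]:
    """Per-query match flag against the target set: ``perfect`` requires
    identical stranded coordinates, ``partial`` at least one shared
    stranded base."""
    if mode == "perfect":
        keys = {_key(t) for t in target}
        return [_key(q) in keys for q in query]
    if mode == "partial":
        by_cs: Dict[Tuple[str, str], List[Tuple[int, int]]] = {}
        for t in target:
            by_cs.setdefault((t.chrom, t.strand), []).append((t.start, t.end))
        flags = []
        for q in query:
            lst = by_cs.get((q.chrom, q.strand), [])
            flags.append(any(s < q.end and q.start < e for s, e in lst))
        return flags
    raise ValueError(f"unknown join mode {mode!r}")


def venn_counts(
    sets: Mapping[str, Sequence[GenomicInterval]], mode: str = "perfect"
) -> Dict[Tuple[str, ...], int]:
    """Counts of distinct exons per membership cell over up to 4 labeled
    sets; cells sum to the number of distinct exons across all sets."""
    if not (2 <= len(sets) <= 4):
        raise ValueError("venn_counts requires 2-4 sets")
    labels = list(sets)
    universe: Dict[Tuple[str, int, int, str], GenomicInterval] = {}
    for ivs in sets.values():
        for iv in ivs:
            universe.setdefault(_key(iv), iv)
    members = list(universe.values())
    flags = {label: join_by_overlap(members, sets[label], mode) for label in labels}
    cells: Dict[Tuple[str, ...], int] = {}
    for i in range(len(members)):
        cell = tuple(label for label in labels if flags[label][i])
        cells[cell] = cells.get(cell, 0) + 1
    return cells
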