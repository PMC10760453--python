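"""Readers and writers for the external formats the pipeline touches.

GTF is 1-based inclusive on disk and converted to the internal 0-based
half-open convention here; BED-family formats are already 0-based
half-open.  SAM is read through :mod:`pysam`.  The ``paired_bed`` dialect
is this package's plain-text alignment exchange format (one trapped
product per line) so the simulator can emit alignments without a SAM
writer: tab-separated ``chrom, start, end, name, mapq, strand,
block_starts, block_sizes, library, vector`` with block starts relative
to ``start``.
"""

from __future__ import annotations

import logging
import re
from collections import defaultdict
from typing import Dict, Iterable, Iterator, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .core import ExonCluster, Genome, GenomicInterval, ReadAlignment, ScoreTrack, TranscriptModel

logger = logging.getLogger("exontrap")

_GTF_ATTR = re.compile(r'(\w+)\s+"([^"]*)"')


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

def read_annotation(path: str, dialect: str = "gtf") -> List[TranscriptModel]:
    """Read transcript models from a GTF exon subset or a BED12 file."""
    if dialect == "gtf":
        return _read_gtf(path)
    if dialect == "bed12":
        return _read_bed12(path)
    raise ValueError(f"unknown annotation dialect {dialect!r}")


def _read_gtf(path: str) -> List[TranscriptModel]:
    by_tx: Dict[str, dict] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise ValueError(f"{path}:{lineno}: malformed GTF line ({len(fields)} fields)")
            chrom, _src, feature, start, end, _score, strand, _frame, attrs = fields[:9]
            if feature != "exon":
                continue
            try:
                start_i, end_i = int(start), int(end)
            except ValueError:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from None
            attr = dict(_GTF_ATTR.findall(attrs))
            tx_id = attr.get("transcript_id")
            if tx_id is None:
                raise ValueError(f"{path}:{lineno}: exon line without transcript_id")
            rec = by_tx.setdefault(
                tx_id,
                {
                    "gene_id": attr.get("gene_id", tx_id),
                    "gene_type": attr.get("gene_type", "other"),
                    "strand": strand,
                    "exons": [],
                },
            )
            # GTF is 1-based inclusive
            rec["exons"].append(GenomicInterval(chrom, start_i - 1, end_i, strand))
    return [
        TranscriptModel(rec["gene_id"], tx_id, _norm_gene_type(rec["gene_type"]), rec["strand"], rec["exons"])
        for tx_id, rec in by_tx.items()
    ]


def _norm_gene_type(gt: str) -> str:
    return gt if gt in ("protein_coding", "lncRNA") else "other"


def write_gtf(transcripts: Sequence[TranscriptModel], path: str) -> None:
    with open(path, "w") as fh:
        for tx in transcripts:
            for i, e in enumerate(tx.exons, start=1):
                attrs = (
                    f'gene_id "{tx.gene_id}"; transcript_id "{tx.transcript_id}"; '
                    f'gene_type "{tx.gene_type}"; exon_number "{i}";'
                )
                fh.write(
                    f"{e.chrom}\texontrap\texon\t{e.start + 1}\t{e.end}\t.\t{tx.strand}\t.\t{attrs}\n"
                )


def _read_bed12(path: str) -> List[TranscriptModel]:
    transcripts = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 12:
                raise ValueError(f"{path}:{lineno}: BED12 requires 12 fields, got {len(f)}")
            chrom, start, _end, name, _score, strand = f[0], int(f[1]), int(f[2]), f[3], f[4], f[5]
            n_blocks = int(f[9])
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            starts = [int(x) for x in f[11].rstrip(",").split(",")]
            if len(sizes) != n_blocks or len(starts) != n_blocks:
                raise ValueError(f"{path}:{lineno}: block count mismatch")
            gene_id, _, rest = name.partition("|")
            gene_type = "other"
            tx_id = gene_id
            if rest:
                tx_id, _, gt = rest.partition("|")
                if gt:
                    gene_type = gt
            exons = [
                GenomicInterval(chrom, start + s, start + s + sz, strand)
                for s, sz in zip(starts, sizes)
            ]
            transcripts.append(TranscriptModel(gene_id, tx_id, _norm_gene_type(gene_type), strand, exons))
    return transcripts


def write_bed12(transcripts: Sequence[TranscriptModel], path: str) -> None:
    with open(path, "w") as fh:
        for tx in transcripts:
            span = tx.span
            starts = ",".join(str(e.start - span.start) for e in tx.exons)
            sizes = ",".join(str(e.length) for e in tx.exons)
            name = f"{tx.gene_id}|{tx.transcript_id}|{tx.gene_type}"
            fh.write(
                f"{span.chrom}\t{span.start}\t{span.end}\t{name}\t0\t{tx.strand}\t"
                f"{span.start}\t{span.end}\t0\t{len(tx.exons)}\t{sizes}\t{starts}\n"
            )


# ---------------------------------------------------------------------------
# alignments
# ---------------------------------------------------------------------------

def read_alignments(
    path: str,
    dialect: str = "paired_bed",
    chrom_sizes: Optional[Mapping[str, int]] = None,
) -> Iterator[ReadAlignment]:
    """Stream trapped-product alignments from SAM or paired_bed."""
    if dialect == "sam":
        yield from _read_sam(path)
    elif dialect == "paired_bed":
        yield from _read_paired_bed(path, chrom_sizes)
    else:
        raise ValueError(f"unknown alignment dialect {dialect!r}")


def _read_sam(path: str) -> Iterator[ReadAlignment]:
    import pysam

    pending: Dict[str, object] = {}
    n_orphan = 0
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for rec in sam:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            if not rec.is_paired:
                yield _sam_to_alignment([rec], sam)
                continue
            mate = pending.pop(rec.query_name, None)
            if mate is None:
                pending[rec.query_name] = rec
            else:
                yield _sam_to_alignment([mate, rec], sam)
    n_orphan = len(pending)
    if n_orphan:
        logger.info("read_alignments: skipped %d orphan mates", n_orphan)


def _sam_to_alignment(records, sam) -> ReadAlignment:
    chrom = sam.get_reference_name(records[0].reference_id)
    read1 = next((r for r in records if not r.is_paired or r.is_read1), records[0])
    strand = "-" if read1.is_reverse else "+"
    blocks: List[Tuple[int, int]] = []
    clipped = False
    for r in records:
        if sam.get_reference_name(r.reference_id) != chrom:
            raise ValueError(f"mates of {r.query_name} on different chromosomes")
        blocks.extend(r.get_blocks())
        if any(op in (4, 5) for op, _ in (r.cigartuples or [])):
            clipped = True
    merged = _merge_blocks(blocks)
    start, end = merged[0][0], merged[-1][1]
    rg = dict(records[0].tags or {}).get("RG", "lib1")
    return ReadAlignment(
        interval=GenomicInterval(chrom, start, end, strand),
        blocks=[GenomicInterval(chrom, s, e, strand) for s, e in merged],
        mapq=min(r.mapping_quality for r in records),
        clipped=clipped,
        library_id=str(rg),
    )


def _merge_blocks(blocks: List[Tuple[int, int]]) -> List[Tuple[int, int]]:
    blocks = sorted(blocks)
    merged = [list(blocks[0])]
    for s, e in blocks[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [tuple(b) for b in merged]


def _read_paired_bed(path: str, chrom_sizes: Optional[Mapping[str, int]]) -> Iterator[ReadAlignment]:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 10:
                raise ValueError(f"{path}:{lineno}: paired_bed requires 10 fields")
            chrom, start, end, _name, mapq, strand = f[0], int(f[1]), int(f[2]), f[3], int(f[4]), f[5]
            if chrom_sizes is not None and chrom not in chrom_sizes:
                raise ValueError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
            starts = [int(x) for x in f[6].rstrip(",").split(",")]
            sizes = [int(x) for x in f[7].rstrip(",").split(",")]
            blocks = [
                GenomicInterval(chrom, start + s, start + s + sz, strand)
                for s, sz in zip(starts, sizes)
            ]
            yield ReadAlignment(
                interval=GenomicInterval(chrom, start, end, strand),
                blocks=blocks,
                mapq=mapq,
                clipped=False,
                library_id=f[8],
                vector_id=f[9],
            )


def write_paired_bed(reads: Iterable[ReadAlignment], path: str) -> int:
    n = 0
    with open(path, "w") as fh:
        for i, r in enumerate(reads):
            iv = r.interval
            starts = ",".join(str(b.start - iv.start) for b in r.blocks)
            sizes = ",".join(str(b.length) for b in r.blocks)
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\tread{i}\t{r.mapq}\t{iv.strand}\t"
                f"{starts}\t{sizes}\t{r.library_id}\t{r.vector_id}\n"
            )
            n += 1
    return n


# ---------------------------------------------------------------------------
# exon tables
# ---------------------------------------------------------------------------

def _sorted_exons(exons: Sequence[ExonCluster]) -> List[ExonCluster]:
    return sorted(exons, key=lambda c: c.key())


def write_exons(exons: Sequence[ExonCluster], path: str, dialect: str = "tsv") -> None:
    """Write exon clusters as BED6 (capped score) or a full TSV counts table."""
    exons = _sorted_exons(exons)
    if dialect == "bed6":
        with open(path, "w") as fh:
            for c in exons:
                iv = c.interval
                score = min(c.total_reads, 1000)
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\texon\t{score}\t{iv.strand}\n")
    elif dialect == "tsv":
        libraries = sorted({lib for c in exons for lib in c.counts_by_library})
        with open(path, "w") as fh:
            header = ["chrom", "start", "end", "strand", "total"] + libraries
            fh.write("\t".join(header) + "\n")
            for c in exons:
                iv = c.interval
                row = [iv.chrom, str(iv.start), str(iv.end), iv.strand, str(c.total_reads)]
                row += [str(c.counts_by_library.get(lib, 0)) for lib in libraries]
                fh.write("\t".join(row) + "\n")
    else:
        raise ValueError(f"unknown exon dialect {dialect!r}")


def read_exons_tsv(path: str) -> List[ExonCluster]:
    out: List[ExonCluster] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        libraries = header[5:]
        for line in fh:
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            counts = {lib: int(v) for lib, v in zip(libraries, f[5:]) if int(v) > 0}
            out.append(
                ExonCluster(GenomicInterval(f[0], int(f[1]), int(f[2]), f[3]), counts)
            )
    return out


def read_bed6(path: str) -> List[GenomicInterval]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.rstrip("\n").split("\t")
            strand = f[5] if len(f) > 5 else "+"
            out.append(GenomicInterval(f[0], int(f[1]), int(f[2]), strand))
    return out


def write_bed6(intervals: Sequence[GenomicInterval], path: str, scores: Optional[Sequence[float]] = None) -> None:
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            score = 0 if scores is None else scores[i]
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\tiv{i}\t{score}\t{iv.strand}\n")


# ---------------------------------------------------------------------------
# genome FASTA
# ---------------------------------------------------------------------------

def write_fasta(sequences: Mapping[str, str], path: str, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# score tracks: bedGraph and fixed-step wig
# ---------------------------------------------------------------------------

def write_bedgraph(track: ScoreTrack, path: str) -> None:
    """Run-length encode a per-base track; NaN runs are omitted."""
    vals = track.values
    with open(path, "w") as fh:
        i, n = 0, len(vals)
        while i < n:
            v = vals[i]
            j = i + 1
            while j < n and (vals[j] == v or (np.isnan(vals[j]) and np.isnan(v))):
                j += 1
            if not np.isnan(v):
                fh.write(f"{track.chrom}\t{i}\t{j}\t{v:g}\n")
            i = j


def read_bedgraph(path: str, chrom: str, chrom_length: int, strand: str = "+") -> ScoreTrack:
    vals = np.full(chrom_length, np.nan)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.rstrip("\n").split("\t")
            if f[0] != chrom:
                continue
            start, end, value = int(f[1]), int(f[2]), float(f[3])
            if end > chrom_length:
                raise ValueError(f"{path}:{lineno}: interval past chromosome end")
            vals[start:end] = value
    return ScoreTrack(chrom, strand, vals)


def read_wig_fixedstep(path: str, chrom: str, chrom_length: int, strand: str = "+") -> ScoreTrack:
    vals = np.full(chrom_length, np.nan)
    cur_chrom, pos, step = None, 0, 1
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            if line.startswith("fixedStep"):
                kv = dict(p.split("=") for p in line.split()[1:])
                cur_chrom = kv["chrom"]
                pos = int(kv["start"]) - 1  # wig is 1-based
                step = int(kv.get("step", 1))
            else:
                if cur_chrom == chrom and 0 <= pos < chrom_length:
                    vals[pos] = float(line)
                pos += step
    return ScoreTrack(chrom, strand, vals)


# ---------------------------------------------------------------------------
# repeat hit tables
# ---------------------------------------------------------------------------

def write_repeats(instances: Sequence["RepeatInstance"], path: str) -> None:
    with open(path, "w") as fh:
        fh.write(
            "family\tchrom\tstart\tend\tstrand\tconsensus_start\tconsensus_end\tconsensus_length\n"
        )
        for r in instances:
            iv = r.interval
            fh.write(
                f"{r.family}\t{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.strand}\t"
                f"{r.consensus_start}\t{r.consensus_end}\t{r.consensus_length}\n"
            )


def read_repeats(path: str) -> List["RepeatInstance"]:
    from .core import RepeatInstance

    out = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("family\t"):
            raise ValueError(f"{path}: missing repeats header")
        for line in fh:
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            out.append(
                RepeatInstance(
                    family=f[0],
                    interval=GenomicInterval(f[1], int(f[2]), int(f[3]), f[4]),
                    consensus_start=int(f[5]),
                    consensus_end=int(f[6]),
                    consensus_length=int(f[7]),
                )
            )
    return out


# ---------------------------------------------------------------------------
# motif lists and score tables
# ---------------------------------------------------------------------------

def read_motif_list(path: str) -> List[str]:
    motifs = []
    with open(path) as fh:
        for line in fh:
            word = line.strip().upper()
            if word and not word.startswith("#"):
                motifs.append(word)
    return motifs


def write_motif_list(motifs: Iterable[str], path: str) -> None:
    with open(path, "w") as fh:
        for m in sorted(set(motifs)):
            fh.write(m + "\n")


def read_score_table(path: str) -> Dict[str, Dict[str, float]]:
    """TSV of (kind, window sequence, score) -> {kind: {window: score}}."""
    table: Dict[str, Dict[str, float]] = defaultdict(dict)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#") or line.startswith("kind\t"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 3:
                raise ValueError(f"{path}:{lineno}: expected kind/window/score")
            table[f[0]][f[1].upper()] = float(f[2])
    return dict(table)


def write_score_table(table: Mapping[str, Mapping[str, float]], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("kind\twindow\tscore\n")
        for kind in table:
            for window, score in table[kind].items():
                fh.write(f"{kind}\t{window}\t{score:g}\n")
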