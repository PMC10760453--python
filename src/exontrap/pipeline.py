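"""End-to-end orchestration: simulate -> call -> classify -> score ->
find -> enrich, with a provenance manifest.

One global seed is fanned out to per-stage seeds (seed + stage index) so
a single number reproduces every output byte-identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional

from . import io as etio
from .calling import CallingConfig, call_exons
from .core import Genome
from .discovery import FinderConfig, compare_exon_sets, find_exons_in_genome
from .regions import build_region_partition, classify_exons, region_base_coverage
from .signals import SpliceSiteModel, ese_density, exon_properties, site_windows
from .simulate import SimConfig, generate_genome, simulate_trapping, write_truth
from .stats import nmd_log_ratio, repeat_enrichment

logger = logging.getLogger("exontrap")


@dataclass
class RunConfig:
    out_dir: str
    sim: SimConfig = field(default_factory=SimConfig)
    calling: CallingConfig = field(default_factory=CallingConfig)
    finder: FinderConfig = field(default_factory=FinderConfig)
    seed: int = 0
    log_level: str = "INFO"
    # optional external inputs; when all three are set the simulator is
    # bypassed and the pipeline consumes them instead
    genome_path: Optional[str] = None
    annotation_path: Optional[str] = None
    alignments_path: Optional[str] = None

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(
            out_dir=raw.get("out_dir", "exontrap_run"),
            sim=SimConfig(**raw.get("sim", {})),
            calling=CallingConfig(**raw.get("calling", {})),
            finder=FinderConfig(**raw.get("finder", {})),
            seed=int(raw.get("seed", 0)),
            log_level=raw.get("log_level", "INFO"),
            genome_path=raw.get("genome_path"),
            annotation_path=raw.get("annotation_path"),
            alignments_path=raw.get("alignments_path"),
        )

    def validate_inputs(self) -> None:
        """All referenced files must exist before any stage runs."""
        for name in ("genome_path", "annotation_path", "alignments_path"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{name}: missing input file {p}")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> Dict:
    """Run every stage in dependency order; returns the manifest (also
    written to ``out_dir/manifest.json``)."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    config.validate_inputs()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: Dict = {"seed": config.seed, "stages": {}}

    def record(stage: str, params: Dict, files: List[Path]) -> None:
        manifest["stages"][stage] = {
            "params": params,
            "outputs": {f.name: _sha256(f) for f in files},
        }

    external = all(
        getattr(config, k) is not None
        for k in ("genome_path", "annotation_path", "alignments_path")
    )
    sim_cfg = replace(config.sim, seed=config.seed + 0)
    if external:
        genome = Genome.from_fasta(config.genome_path)
        annotation = etio.read_annotation(config.annotation_path, "gtf")
        by_lib: Dict[str, List] = {}
        for r in etio.read_alignments(config.alignments_path, "paired_bed", genome.chrom_sizes):
            by_lib.setdefault(r.library_id, []).append(r)
        alignments = by_lib
        sim = None
        record("inputs", {k: getattr(config, k) for k in
                          ("genome_path", "annotation_path", "alignments_path")}, [])
    else:
        # stage 0: simulate
        sim = generate_genome(sim_cfg)
        simulate_trapping(sim, sim_cfg)
        genome, annotation, alignments = sim.genome, sim.annotation, sim.alignments
        chrom = sim_cfg.chrom
        f_fasta = out / "genome.fa"
        f_gtf = out / "annotation.gtf"
        f_truth = out / "truth.tsv"
        f_reps = out / "repeats.tsv"
        f_reads = out / "reads.paired_bed"
        f_cons = out / "conservation.bedgraph"
        etio.write_fasta({chrom: sim.genome.sequence(chrom)}, f_fasta)
        etio.write_gtf(sim.annotation, f_gtf)
        write_truth(sim.truth, f_truth)
        etio.write_repeats(sim.repeats, f_reps)
        all_reads = [r for lib in sorted(sim.alignments) for r in sim.alignments[lib]]
        etio.write_paired_bed(all_reads, f_reads)
        etio.write_bedgraph(sim.tracks[chrom], f_cons)
        record("simulate", {"seed": sim_cfg.seed, "genome_length": sim_cfg.genome_length},
               [f_fasta, f_gtf, f_truth, f_reps, f_reads, f_cons])

    # stage 1: train the splice scorer on the annotated internal exons
    internal = [
        e for tx in annotation for e in tx.exons_in_transcription_order()[1:-1]
    ]
    donors, acceptors = site_windows(genome, internal)
    scorer = SpliceSiteModel.train(donors, acceptors)

    # stage 2: call exons
    calling = config.calling
    if not calling.dark_cycle_trim_by_library:
        calling = replace(
            calling,
            dark_cycle_trim_by_library={
                lib.library_id: lib.dark_cycle_trim for lib in sim_cfg.libraries
            },
        )
    clusters, primaries = call_exons(alignments, scorer, genome, calling)
    f_clusters = out / "clusters.tsv"
    f_primary = out / "primary.tsv"
    f_primary_bed = out / "primary.bed"
    etio.write_exons(clusters, f_clusters, "tsv")
    etio.write_exons([p.exon for p in primaries], f_primary, "tsv")
    etio.write_exons([p.exon for p in primaries], f_primary_bed, "bed6")
    record("call", {"min_group_reads": calling.min_group_reads},
           [f_clusters, f_primary, f_primary_bed])

    # stage 3: classify against the region partition
    partition = build_region_partition(annotation, genome.chrom_sizes)
    classified = classify_exons(primaries, partition)
    coverage = region_base_coverage(classified, partition)
    f_class = out / "classified.tsv"
    with open(f_class, "w") as fh:
        fh.write("chrom\tstart\tend\tstrand\ttotal_reads\tcategory\n")
        for ce in classified:
            iv = ce.interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.strand}\t"
                f"{ce.exon.exon.total_reads}\t{ce.category}\n"
            )
    f_cov = out / "region_coverage.tsv"
    with open(f_cov, "w") as fh:
        fh.write("label\texon_bases\tregion_bases\tpercent\n")
        for label, (k, total, pct) in coverage.items():
            fh.write(f"{label}\t{k}\t{total}\t{pct:.4f}\n")
    record("classify", {}, [f_class, f_cov])

    # stage 4: per-exon splice signals
    motifs = sim_cfg.motif_set
    f_sig = out / "exon_signals.tsv"
    with open(f_sig, "w") as fh:
        fh.write(
            "chrom\tstart\tend\tstrand\ttotal_reads\tacceptor_score\tdonor_score\t"
            "ese_count\tese_per_100bp\tlength\tgc\n"
        )
        for p in primaries:
            iv = p.interval
            a, d = scorer.score_exon(genome, iv)
            count, per100 = ese_density(genome.fetch_interval(iv), motifs)
            length, gc, _ = exon_properties(iv, genome)
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.strand}\t{p.exon.total_reads}\t"
                f"{a:.4f}\t{d:.4f}\t{count}\t{per100:.4f}\t{length}\t{gc:.4f}\n"
            )
    record("signals", {}, [f_sig])

    # stage 5: de novo exon finding + set comparison
    predicted = find_exons_in_genome(scorer, genome, config.finder)
    f_pred = out / "predicted.bed"
    etio.write_bed6([p.interval for p in predicted], f_pred)
    venn = compare_exon_sets(
        {
            "trapped": [p.interval for p in primaries],
            "predicted": [p.interval for p in predicted],
        },
        mode="partial",
    )
    f_venn = out / "venn.tsv"
    with open(f_venn, "w") as fh:
        fh.write("cell\tcount\n")
        for cell, count in sorted(venn.items()):
            fh.write(f"{'&'.join(cell) or 'none'}\t{count}\n")
    record("find", {"threshold": config.finder.score_threshold}, [f_pred, f_venn])

    # stage 6: enrichment + NMD
    files = []
    if sim is not None and sim.repeats:
        f_enrich = out / "enrichment.tsv"
        results = repeat_enrichment([p.interval for p in primaries], sim.repeats, genome.chrom_sizes)
        with open(f_enrich, "w") as fh:
            fh.write("family\tM\tn\tN\tk\tratio\tlog_p\tlog_p_upper\n")
            for r in results:
                fh.write(
                    f"{r.family}\t{r.M}\t{r.n}\t{r.N}\t{r.k}\t{r.ratio:.4f}\t"
                    f"{r.log_p:.4f}\t{r.log_p_upper:.4f}\n"
                )
        files.append(f_enrich)

    lib_to_vector = {lib.library_id: lib.vector_id for lib in sim_cfg.libraries}
    vector_frames: Dict[str, int] = {
        lib.vector_id: lib.frame_offset for lib in sim_cfg.libraries
    }
    frames_present = sorted(set(vector_frames.values()))
    if len(frames_present) >= 2:
        vec_by_frame = {f: v for v, f in vector_frames.items()}
        pair = ((vec_by_frame[frames_present[0]], frames_present[0]),
                (vec_by_frame[frames_present[1]], frames_present[1]))
        exons_with_counts = []
        for c in clusters:
            by_vec: Dict[str, int] = {}
            for lib, cnt in c.counts_by_library.items():
                vec = lib_to_vector.get(lib, lib)
                by_vec[vec] = by_vec.get(vec, 0) + cnt
            exons_with_counts.append((c.interval, by_vec))
        records, median, excluded = nmd_log_ratio(exons_with_counts, pair, genome)
        f_nmd = out / "nmd.tsv"
        with open(f_nmd, "w") as fh:
            fh.write(f"# median_log2_ratio\t{median:.4f}\n")
            fh.write(f"# excluded\t{json.dumps(excluded)}\n")
            fh.write("chrom\tstart\tend\tstrand\tcount_no_stop\tcount_stop\tlog2_ratio\n")
            for r in records:
                iv = r.exon
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.strand}\t"
                    f"{r.count_no_stop}\t{r.count_stop}\t{r.log2_ratio:.4f}\n"
                )
        files.append(f_nmd)
    record("enrich", {}, files)

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
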