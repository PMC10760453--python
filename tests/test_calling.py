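"""Exon calling: filtering, collapse, terminus adjustment, grouping."""

from collections import Counter

import numpy as np
import pytest

from exontrap.calling import (
    CallingConfig,
    adjust_and_merge,
    call_primary_exons,
    collapse_reads,
    detect_doublets,
    group_clusters,
    pool_clusters,
    preprocess_alignments,
    remove_reporter_exons,
)
from exontrap.core import ExonCluster, Genome, GenomicInterval, ReadAlignment
from exontrap.signals import SpliceSiteModel


def mkread(start, end, strand="+", mapq=60, clipped=False, lib="lib1", chrom="c"):
    iv = GenomicInterval(chrom, start, end, strand)
    return ReadAlignment(iv, [iv], mapq=mapq, clipped=clipped, library_id=lib)


CFG = CallingConfig(dark_cycle_trim_by_library={"lib1": 3, "lib2": 4})


class TestPreprocess:
    def test_mapq_below_20_dropped(self):
        kept = preprocess_alignments([mkread(100, 200, mapq=19), mkread(100, 200, mapq=20)], CFG)
        assert len(kept) == 1 and kept[0].mapq == 20

    def test_clipped_dropped(self):
        kept = preprocess_alignments([mkread(100, 200, clipped=True)], CFG)
        assert kept == []

    def test_plus_strand_trim_extends_start_outward(self):
        (r,) = preprocess_alignments([mkread(103, 200, "+", lib="lib1")], CFG)
        assert (r.interval.start, r.interval.end) == (100, 200)
        assert r.blocks[0].start == 100

    def test_minus_strand_trim_extends_end_outward(self):
        (r,) = preprocess_alignments([mkread(100, 200, "-", lib="lib2")], CFG)
        assert (r.interval.start, r.interval.end) == (100, 204)

    def test_unconfigured_library_is_an_error(self):
        with pytest.raises(ValueError, match="libX"):
            preprocess_alignments([mkread(100, 200, lib="libX")], CFG)

    def test_mixed_stream_matches_per_record_oracle(self, rng):
        reads = []
        for _ in range(50):
            s = int(rng.integers(100, 1000))
            reads.append(
                mkread(
                    s,
                    s + int(rng.integers(50, 150)),
                    "+" if rng.random() < 0.5 else "-",
                    mapq=int(rng.integers(0, 61)),
                    clipped=bool(rng.random() < 0.3),
                    lib="lib1" if rng.random() < 0.5 else "lib2",
                )
            )
        kept = preprocess_alignments(reads, CFG)
        # oracle: apply the filter rules record by record
        expected = [r for r in reads if r.mapq >= 20 and not r.clipped]
        assert len(kept) == len(expected)
        for k, e in zip(kept, expected):
            trim = {"lib1": 3, "lib2": 4}[e.library_id]
            if e.interval.strand == "+":
                assert k.interval.start == e.interval.start - trim
            else:
                assert k.interval.end == e.interval.end + trim


class TestCollapse:
    def test_distinct_ends_kept_separate(self):
        reads = [mkread(100, 250)] * 3 + [mkread(100, 251)] * 2
        clusters = collapse_reads(reads)
        assert [(c.interval.end, c.total_reads) for c in clusters] == [(250, 3), (251, 2)]

    def test_empty_stream(self):
        assert collapse_reads([]) == []

    def test_500_random_reads_match_grouping_oracle(self, rng):
        reads = []
        for _ in range(500):
            s = int(rng.integers(0, 200))
            reads.append(mkread(s, s + int(rng.integers(10, 30)), lib=f"lib{rng.integers(3)}"))
        clusters = collapse_reads(reads)
        oracle = Counter(
            (r.interval.chrom, r.interval.start, r.interval.end, r.interval.strand, r.library_id)
            for r in reads
        )
        assert sum(c.total_reads for c in clusters) == 500
        for c in clusters:
            for lib, n in c.counts_by_library.items():
                iv = c.interval
                assert oracle[(iv.chrom, iv.start, iv.end, iv.strand, lib)] == n
        keys = [c.key() for c in clusters]
        assert keys == sorted(keys)

    def test_collapse_is_idempotent(self, rng):
        reads = [mkread(int(rng.integers(0, 50)) * 10, 600 + int(rng.integers(0, 5))) for _ in range(100)]
        clusters = collapse_reads(reads)
        # expand back to reads and re-collapse
        expanded = []
        for c in clusters:
            for lib, n in c.counts_by_library.items():
                expanded.extend([mkread(c.interval.start, c.interval.end, lib=lib)] * n)
        again = collapse_reads(expanded)
        assert [(c.key(), sorted(c.counts_by_library.items())) for c in again] == [
            (c.key(), sorted(c.counts_by_library.items())) for c in clusters
        ]


def _table_scorer(donor_scores, acceptor_scores, genome):
    """Score-table model assigning the given scores to the windows found
    at specific boundary positions of the genome; everything else -99."""
    tables = {"donor": {}, "acceptor": {}}
    probe = SpliceSiteModel(donor_matrix=np.zeros((9, 4)), acceptor_matrix=np.zeros((23, 4)))
    for (chrom, pos, strand), score in donor_scores.items():
        lo, hi = probe.window_interval("donor", pos, strand)
        tables["donor"][genome.fetch(chrom, lo, hi, strand)] = score
    for (chrom, pos, strand), score in acceptor_scores.items():
        lo, hi = probe.window_interval("acceptor", pos, strand)
        tables["acceptor"][genome.fetch(chrom, lo, hi, strand)] = score
    model = SpliceSiteModel.from_score_table(tables)
    return model


@pytest.fixture
def toy_genome(rng):
    # random sequence long enough for windows; distinct everywhere
    return Genome({"c": "".join(rng.choice(list("ACGT"), size=2000))})


class TestAdjustAndMerge:
    def test_shift_to_strictly_higher_scoring_donor(self, toy_genome):
        e = 700
        scorer = _table_scorer({("c", e, "+"): 2.0, ("c", e + 2, "+"): 5.0}, {("c", 500, "+"): 8.0}, toy_genome)
        cluster = ExonCluster(GenomicInterval("c", 500, e, "+"), {"lib1": 10})
        (out,) = adjust_and_merge([[cluster]], scorer, toy_genome, CFG)
        assert out.interval.end == e + 2

    def test_tie_smaller_magnitude_then_negative_wins(self, toy_genome):
        e = 700
        # +1 and +2 improved equally -> +1; -1 and +1 equal -> -1
        s1 = _table_scorer({("c", e, "+"): 1.0, ("c", e + 1, "+"): 5.0, ("c", e + 2, "+"): 5.0},
                           {("c", 500, "+"): 8.0}, toy_genome)
        cluster = ExonCluster(GenomicInterval("c", 500, e, "+"), {"lib1": 10})
        (out,) = adjust_and_merge([[cluster]], s1, toy_genome, CFG)
        assert out.interval.end == e + 1
        s2 = _table_scorer({("c", e, "+"): 1.0, ("c", e - 1, "+"): 5.0, ("c", e + 1, "+"): 5.0},
                           {("c", 500, "+"): 8.0}, toy_genome)
        (out2,) = adjust_and_merge([[cluster]], s2, toy_genome, CFG)
        assert out2.interval.end == e - 1

    def test_no_improvement_no_shift(self, toy_genome):
        scorer = _table_scorer({("c", 700, "+"): 9.0}, {("c", 500, "+"): 9.0}, toy_genome)
        cluster = ExonCluster(GenomicInterval("c", 500, 700, "+"), {"lib1": 10})
        (out,) = adjust_and_merge([[cluster]], scorer, toy_genome, CFG)
        assert (out.interval.start, out.interval.end) == (500, 700)

    def test_libraries_pooled_additively(self, toy_genome):
        scorer = _table_scorer({("c", 700, "+"): 9.0}, {("c", 500, "+"): 9.0}, toy_genome)
        a = ExonCluster(GenomicInterval("c", 500, 700, "+"), {"lib1": 300})
        b = ExonCluster(GenomicInterval("c", 500, 700, "+"), {"lib2": 200})
        (out,) = adjust_and_merge([[a], [b]], scorer, toy_genome, CFG)
        assert out.total_reads == 500
        assert out.counts_by_library == {"lib1": 300, "lib2": 200}

    def test_adjusted_clusters_recollapse(self, toy_genome):
        e = 700
        scorer = _table_scorer(
            {("c", e, "+"): 9.0, ("c", e + 1, "+"): 1.0},
            {("c", 500, "+"): 9.0},
            toy_genome,
        )
        exact = ExonCluster(GenomicInterval("c", 500, e, "+"), {"lib1": 50})
        offby1 = ExonCluster(GenomicInterval("c", 500, e + 1, "+"), {"lib1": 5})
        (out,) = adjust_and_merge([[exact, offby1]], scorer, toy_genome, CFG)
        assert out.interval.end == e and out.total_reads == 55

    def test_never_shifts_beyond_max_and_never_decreases_score(self, big_sim, big_called):
        scorer, _, _ = big_called
        cfg = CallingConfig(dark_cycle_trim_by_library={l.library_id: l.dark_cycle_trim for l in big_sim.config.libraries})
        reads = preprocess_alignments(big_sim.alignments["lib1"][:2000], cfg)
        before = collapse_reads(reads)
        after = adjust_and_merge([before], scorer, big_sim.genome, cfg)
        pos_before = {c.key(): c for c in before}
        total_after = sum(c.total_reads for c in after)
        assert total_after == sum(c.total_reads for c in before)
        for c in after:
            # find any source cluster within max shift
            iv = c.interval
            sources = [
                s for s in before
                if s.interval.strand == iv.strand
                and abs(s.interval.start - iv.start) <= cfg.max_terminus_shift
                and abs(s.interval.end - iv.end) <= cfg.max_terminus_shift
            ]
            assert sources, f"adjusted cluster {iv} has no nearby source"


class TestReporterRemoval:
    REPORTER = GenomicInterval("c", 1000, 2000, "+")

    def mk(self, chrom, start, end, strand="+"):
        return ExonCluster(GenomicInterval(chrom, start, end, strand), {"l": 1})

    def test_fully_contained_removed_any_strand(self):
        inside = [self.mk("c", 1100, 1200), self.mk("c", 1100, 1200, "-")]
        assert remove_reporter_exons(inside, self.REPORTER) == []

    def test_one_base_outside_retained(self):
        edge = self.mk("c", 999, 1500)
        assert remove_reporter_exons([edge], self.REPORTER) == [edge]

    def test_other_chromosome_retained(self):
        other = self.mk("d", 1100, 1200)
        assert remove_reporter_exons([other], self.REPORTER) == [other]

    def test_none_reporter_is_noop(self):
        x = [self.mk("c", 1100, 1200)]
        assert remove_reporter_exons(x, None) == x


class TestPrimarySelection:
    def mk(self, start, end, reads, strand="+"):
        return ExonCluster(GenomicInterval("c", start, end, strand), {"l": reads})

    def test_group_total_meets_threshold_and_max_count_is_primary(self):
        clusters = [self.mk(100, 250, 60), self.mk(100, 260, 50)]
        (p,) = call_primary_exons(clusters, CFG)
        assert p.group_total == 110 and p.members == 2
        assert p.exon.total_reads == 60

    def test_group_below_threshold_not_emitted(self):
        assert call_primary_exons([self.mk(100, 250, 60), self.mk(100, 260, 39)], CFG) == []

    def test_different_acceptors_not_grouped(self):
        clusters = [self.mk(100, 250, 120), self.mk(101, 250, 130)]
        assert len(call_primary_exons(clusters, CFG)) == 2

    def test_tie_longer_then_leftmost(self):
        a, b = self.mk(100, 250, 60), self.mk(100, 260, 60)
        (p,) = call_primary_exons([a, b], CFG)
        assert p.exon.interval.end == 260  # longer wins the tie

    def test_minus_strand_groups_share_end(self):
        clusters = [self.mk(100, 250, 60, "-"), self.mk(90, 250, 50, "-")]
        (p,) = call_primary_exons(clusters, CFG)
        assert p.group_total == 110

    def test_grouping_matches_union_find_oracle(self, rng):
        clusters = []
        for _ in range(200):
            acc = int(rng.integers(0, 40)) * 25
            length = int(rng.integers(20, 100))
            strand = "+" if rng.random() < 0.5 else "-"
            if strand == "+":
                iv = GenomicInterval("c", acc, acc + length, "+")
            else:
                iv = GenomicInterval("c", max(0, acc - length) , acc if acc > 0 else length, "-")
            clusters.append(ExonCluster(iv, {"l": int(rng.integers(1, 200))}))
        groups = group_clusters(clusters)
        # brute-force union-find over the stated pairwise relation
        n = len(clusters)
        parent = list(range(n))

        def find(i):
            while parent[i] != i:
                i = parent[i]
            return i

        for i in range(n):
            for j in range(i + 1, n):
                a, b = clusters[i].interval, clusters[j].interval
                if (
                    a.strand == b.strand
                    and a.chrom == b.chrom
                    and a.acceptor_pos == b.acceptor_pos
                    and a.start < b.end
                    and b.start < a.end
                ):
                    ri, rj = find(i), find(j)
                    if ri != rj:
                        parent[rj] = ri
        from collections import defaultdict

        oracle = defaultdict(set)
        for i in range(n):
            oracle[find(i)].add(clusters[i].key())
        got = {frozenset(c.key() for c in g) for g in groups}
        assert got == {frozenset(v) for v in oracle.values()}


class TestDoublets:
    def test_two_blocks_within_span_detected(self):
        iv = GenomicInterval("c", 100, 670, "+")
        blocks = [GenomicInterval("c", 100, 180, "+"), GenomicInterval("c", 580, 670, "+")]
        read = ReadAlignment(iv, blocks, mapq=60)
        (d,) = detect_doublets([read])
        assert (d[0].start, d[0].end, d[1].start, d[1].end, d[2]) == (100, 180, 580, 670, 1)

    def test_single_block_not_a_doublet(self):
        assert detect_doublets([mkread(100, 200)]) == []

    def test_span_beyond_fragment_excluded(self):
        iv = GenomicInterval("c", 100, 5100, "+")
        blocks = [GenomicInterval("c", 100, 180, "+"), GenomicInterval("c", 5000, 5100, "+")]
        assert detect_doublets([ReadAlignment(iv, blocks, mapq=60)]) == []
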