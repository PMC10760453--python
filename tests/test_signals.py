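"""Splice-site scoring, motif densities and positional profiles."""

import math
import re

import numpy as np
import pytest

from exontrap.core import Genome, GenomicInterval, ScoreTrack, reverse_complement
from exontrap.signals import (
    ACCEPTOR_WIDTH,
    DONOR_WIDTH,
    MotifSet,
    SpliceSiteModel,
    ese_density,
    exon_properties,
    moving_average,
    motif_frequency_profile,
    offset_control_interval,
    site_windows,
    track_profile,
)


def random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


class TestTrainSpliceModel:
    def test_identical_examples_attain_max_score(self, rng):
        donor = random_seq(rng, 9)
        acceptor = random_seq(rng, 23)
        model = SpliceSiteModel.train([donor] * 50, [acceptor] * 50)
        assert model.score_window("donor", donor) == pytest.approx(model.max_score("donor"))
        assert model.score_window("acceptor", acceptor) == pytest.approx(model.max_score("acceptor"))

    def test_single_example_matches_hand_computed_log_odds(self):
        # one donor example, uniform background, pseudocount 1:
        # observed base: log2((1 + 1*0.25)/(1 + 1)/0.25) = log2(2.5)
        # unobserved:    log2((0 + 0.25)/2/0.25)          = log2(0.5)
        model = SpliceSiteModel.train(["CAGGTAAGT"], ["T" * 20 + "AGG"])
        hit = math.log2(2.5)
        miss = math.log2(0.5)
        assert model.score_window("donor", "CAGGTAAGT") == pytest.approx(9 * hit)
        # one mismatch swaps a hit for a miss
        assert model.score_window("donor", "AAGGTAAGT") == pytest.approx(8 * hit + miss)

    def test_wrong_length_example_names_index(self):
        with pytest.raises(ValueError, match="example 1"):
            SpliceSiteModel.train(["CAGGTAAGT", "SHORT"], ["T" * 20 + "AGG"])

    def test_score_table_passthrough_is_exact(self, rng):
        windows = {random_seq(rng, 9): float(rng.normal()) for _ in range(20)}
        model = SpliceSiteModel.from_score_table({"donor": windows})
        for w, s in windows.items():
            assert model.score_window("donor", w) == s
        assert np.isnan(model.score_window("donor", "A" * 9))  # absent window


class TestScoreSite:
    @pytest.fixture
    def model(self, rng):
        donors = [random_seq(rng, 9) for _ in range(40)]
        acceptors = [random_seq(rng, 23) for _ in range(40)]
        return SpliceSiteModel.train(donors, acceptors)

    def test_window_score_is_column_sum(self, model, rng):
        # oracle: brute-force sum of per-position matrix entries
        for _ in range(20):
            w = random_seq(rng, 9)
            expected = sum(
                model.donor_matrix[i, "ACGT".index(b)] for i, b in enumerate(w)
            )
            assert model.score_window("donor", w) == pytest.approx(expected)

    def test_plus_strand_window_coordinates(self, model, rng):
        seq = random_seq(rng, 200)
        g = Genome({"c": seq})
        e = 100
        assert model.score_site(g, "c", e, "+", "donor") == pytest.approx(
            model.score_window("donor", seq[e - 3 : e + 6])
        )
        assert model.score_site(g, "c", e, "+", "acceptor") == pytest.approx(
            model.score_window("acceptor", seq[e - 20 : e + 3])
        )

    def test_reverse_complement_symmetry(self, model, rng):
        seq = random_seq(rng, 300)
        g = Genome({"c": seq})
        grc = Genome({"c": reverse_complement(seq)})
        for kind in ("donor", "acceptor"):
            for pos in (50, 120, 250):
                minus = model.score_site(g, "c", pos, "-", kind)
                plus = model.score_site(grc, "c", len(seq) - pos, "+", kind)
                assert minus == pytest.approx(plus, nan_ok=True)

    def test_window_with_n_scores_missing(self, model):
        g = Genome({"c": "A" * 50 + "N" + "A" * 50})
        assert np.isnan(model.score_site(g, "c", 52, "+", "donor"))

    def test_out_of_range_window_missing(self, model, rng):
        g = Genome({"c": random_seq(rng, 30)})
        assert np.isnan(model.score_site(g, "c", 1, "+", "donor"))
        assert np.isnan(model.score_site(g, "c", 29, "+", "acceptor"))


class TestScoreTracks:
    @pytest.fixture
    def model(self, rng):
        return SpliceSiteModel.train(
            [random_seq(rng, 9) for _ in range(30)],
            [random_seq(rng, 23) for _ in range(30)],
        )

    def test_track_matches_pointwise_scoring(self, model, rng):
        g = Genome({"c": random_seq(rng, 10_000)})
        for strand in "+-":
            donor, acceptor = model.score_tracks(g, "c", strand)
            assert len(donor) == len(acceptor) == 10_000
            for pos in rng.integers(25, 9_975, size=100):
                pos = int(pos)
                assert donor.values[pos] == pytest.approx(
                    model.score_site(g, "c", pos, strand, "donor"), nan_ok=True
                )
                assert acceptor.values[pos] == pytest.approx(
                    model.score_site(g, "c", pos, strand, "acceptor"), nan_ok=True
                )

    def test_all_n_sequence_all_missing(self, model):
        g = Genome({"c": "N" * 500})
        donor, acceptor = model.score_tracks(g, "c", "+")
        assert np.isnan(donor.values).all() and np.isnan(acceptor.values).all()


class TestEseDensity:
    MOTIFS = MotifSet("ese", frozenset({"GAAGAA"}))

    def test_per_100bp_normalization(self):
        seq = "GAAGAA" + "C" * 44 + "GAAGAA" + "C" * 44 + "GAAGAA" + "C" * 44 + "GAAGAA" + "C" * 44
        count, per100 = ese_density(seq, self.MOTIFS)
        assert count == 4 and len(seq) == 200
        assert per100 == pytest.approx(2.0)

    def test_overlapping_occurrences_counted(self):
        count, _ = ese_density("GAAGAAGAA", self.MOTIFS)
        assert count == 2  # starts 0 and 3

    def test_short_sequence_zero(self):
        assert ese_density("GAAGA", self.MOTIFS) == (0, 0.0)

    def test_matches_regex_scan_oracle(self, rng):
        motifs = MotifSet("m", frozenset({"GAAGAA", "TTTCCA", "ACGTAC"}))
        seq = random_seq(rng, 1000)
        count, _ = ese_density(seq, motifs)
        oracle = sum(
            len(re.findall(f"(?={m})", seq)) for m in motifs.hexamers
        )
        assert count == oracle

    def test_additive_over_concatenation_up_to_boundary(self, rng):
        motifs = MotifSet("m", frozenset({"GAAGAA", "ACGTAC"}))
        a, b = random_seq(rng, 400), random_seq(rng, 400)
        ca, _ = ese_density(a, motifs)
        cb, _ = ese_density(b, motifs)
        cab, _ = ese_density(a + b, motifs)
        assert ca + cb <= cab <= ca + cb + 5


class TestOffsetControl:
    def test_plus_strand_shifts_downstream(self):
        exon = GenomicInterval("c", 1000, 1150, "+")
        ctrl = offset_control_interval(exon, 250)
        assert (ctrl.start, ctrl.end) == (1250, 1400)

    def test_minus_strand_shifts_upstream_in_genome_coordinates(self):
        exon = GenomicInterval("c", 1000, 1150, "-")
        ctrl = offset_control_interval(exon, 250)
        assert (ctrl.start, ctrl.end) == (750, 900)

    def test_zero_offset_identity(self):
        exon = GenomicInterval("c", 1000, 1150, "+")
        assert offset_control_interval(exon, 0) == exon

    def test_out_of_range_returns_missing(self):
        exon = GenomicInterval("c", 100, 200, "-")
        assert offset_control_interval(exon, 250) is None
        plus = GenomicInterval("c", 100, 200, "+")
        assert offset_control_interval(plus, 250, {"c": 300}) is None


class TestMotifFrequencyProfile:
    def test_indicator_spike_at_planted_offset(self, rng):
        motifs = MotifSet("m", frozenset({"GAAGAA"}))
        chrom_parts = []
        exons = []
        pos = 0
        for _ in range(10):
            pad = random_seq(rng, 200).replace("GAAGAA", "GTAGAA")
            chrom_parts.append(pad)
            s = pos + 60
            exons.append(GenomicInterval("c", s, s + 80, "+"))
            pos += 200
        seq = list("".join(chrom_parts))
        for e in exons:
            seq[e.start + 10 : e.start + 16] = "GAAGAA"
        g = Genome({"c": "".join(seq)})
        prof = motif_frequency_profile(exons, g, motifs, "acceptor", halfwidth=30, smooth=1)
        idx = {o: i for i, o in enumerate(prof.offsets)}
        assert prof.values[idx[10]] == pytest.approx(1.0)
        assert np.nansum(prof.values) == pytest.approx(1.0)

    def test_smoothing_preserves_constant(self):
        vals = np.full(41, 0.3)
        assert np.allclose(moving_average(vals, 19), 0.3)

    def test_matches_per_offset_tally_oracle(self, rng):
        motifs = MotifSet("m", frozenset({"GAAGAA", "AAGAAG"}))
        seq = random_seq(rng, 6000)
        g = Genome({"c": seq})
        exons = []
        for _ in range(25):
            s = int(rng.integers(100, 5800))
            exons.append(GenomicInterval("c", s, s + 90, "+" if rng.random() < 0.5 else "-"))
        prof = motif_frequency_profile(exons, g, motifs, "acceptor", halfwidth=20, smooth=1)
        for i, o in enumerate(prof.offsets):
            hits = 0
            for e in exons:
                if e.strand == "+":
                    w = seq[e.start + o : e.start + o + 6]
                else:
                    w = reverse_complement(seq[e.end - o - 6 : e.end - o])
                if w in motifs:
                    hits += 1
            assert prof.values[i] == pytest.approx(hits / len(exons))

    def test_exclude_drops_overlapping_exons(self, rng):
        motifs = MotifSet("m", frozenset({"GAAGAA"}))
        g = Genome({"c": random_seq(rng, 2000)})
        exons = [GenomicInterval("c", 500, 580, "+"), GenomicInterval("c", 1000, 1080, "+")]
        mask = [GenomicInterval("c", 490, 600, "+")]
        prof = motif_frequency_profile(exons, g, motifs, halfwidth=10, smooth=1, exclude=mask)
        assert prof.n == 1


class TestTrackProfile:
    def test_constant_track_flat_profile(self):
        track = {"c": ScoreTrack("c", "+", np.ones(1000))}
        exons = [GenomicInterval("c", 400, 500, s) for s in "+-"]
        prof = track_profile(exons, track, "acceptor", halfwidth=20)
        assert np.allclose(prof.values, 1.0)

    def test_single_exon_equals_raw_slice(self, rng):
        vals = rng.normal(size=1000)
        track = {"c": ScoreTrack("c", "+", vals)}
        exon = GenomicInterval("c", 400, 500, "-")
        prof = track_profile([exon], track, "acceptor", halfwidth=10)
        # '-' acceptor at end=500; exon-ward offset o -> genome 499-o
        expected = [vals[499 - o] for o in prof.offsets]
        assert np.allclose(prof.values, expected)

    def test_mean_matches_direct_oracle(self, rng):
        vals = rng.normal(size=5000)
        vals[rng.integers(0, 5000, 200)] = np.nan
        track = {"c": ScoreTrack("c", "+", vals)}
        exons = [
            GenomicInterval("c", int(s), int(s) + 80, "+" if rng.random() < 0.5 else "-")
            for s in rng.integers(100, 4800, 50)
        ]
        prof = track_profile(exons, track, "donor", halfwidth=25)
        for i, o in enumerate(prof.offsets):
            samples = []
            for e in exons:
                g = (e.end - 1 - o) if e.strand == "+" else (e.start + o)
                v = vals[g]
                if np.isfinite(v):
                    samples.append(v)
            assert prof.values[i] == pytest.approx(np.mean(samples), abs=1e-12)

    def test_no_exons_is_error(self):
        with pytest.raises(ValueError):
            track_profile([], {"c": ScoreTrack("c", "+", np.ones(10))}, "acceptor")


class TestExonProperties:
    def test_stop_codon_in_frame_zero(self):
        g = Genome({"c": "ATGTAAGGG"})
        _, _, stops = exon_properties(GenomicInterval("c", 0, 9, "+"), g)
        assert stops[0] and not stops[1] and not stops[2]

    def test_all_gc_exon(self):
        g = Genome({"c": "GCGCGCGC"})
        length, gc, _ = exon_properties(GenomicInterval("c", 0, 8, "+"), g)
        assert (length, gc) == (8, 1.0)

    def test_matches_codon_walk_oracle(self, rng):
        seq = random_seq(rng, 3000)
        g = Genome({"c": seq})
        for _ in range(100):
            s = int(rng.integers(0, 2800))
            exon = GenomicInterval("c", s, s + int(rng.integers(30, 150)), "+" if rng.random() < 0.5 else "-")
            _, _, stops = exon_properties(exon, g)
            body = g.fetch_interval(exon)
            for f in (0, 1, 2):
                codons = [body[p : p + 3] for p in range(f, len(body) - 2, 3)]
                assert stops[f] == any(c in ("TAA", "TAG", "TGA") for c in codons)


def test_trained_model_separates_true_sites_from_background(big_sim, big_called):
    """Monotone discrimination: planted sites outscore the 99th percentile
    of random non-site positions."""
    scorer, _, _ = big_called
    g = big_sim.genome
    rng = np.random.default_rng(5)
    chrom = big_sim.config.chrom
    bg_scores = {"donor": [], "acceptor": []}
    for pos in rng.integers(100, g.length(chrom) - 100, 2000):
        for kind in ("donor", "acceptor"):
            s = scorer.score_site(g, chrom, int(pos), "+", kind)
            if np.isfinite(s):
                bg_scores[kind].append(s)
    thr = {k: np.percentile(v, 99) for k, v in bg_scores.items()}
    true_d = [scorer.score_site(g, t.interval.chrom, t.interval.donor_pos, t.interval.strand, "donor") for t in big_sim.truth]
    true_a = [scorer.score_site(g, t.interval.chrom, t.interval.acceptor_pos, t.interval.strand, "acceptor") for t in big_sim.truth]
    assert np.mean(true_d) > thr["donor"]
    assert np.mean(true_a) > thr["acceptor"]
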