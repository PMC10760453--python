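"""Synthetic exon-trapping data with planted ground truth.

The generator builds a toy genome hosting multi-exon genes and standalone
exons (intronic, antisense, intergenic, and exons carried inside repeat
instances), each with sampled donor/acceptor windows and enhancer
hexamers, then simulates trapping libraries whose read counts follow a
logistic inclusion-rate model of the planted signal strengths.  Every
planted exon is recorded as a :class:`TruthExon` so downstream modules
can be tested by parameter recovery.

Library features emulated: fragments of 500-1000 bp sampled with
all-or-nothing per-library coverage, read counts increasing with
splice-signal strength, ~2-fold depletion of stop-containing exons in a
frame-matched vector (nonsense-mediated decay), +/-2 bp terminus jitter,
and per-library 3-4 base dark-cycle truncation of the exon 5' terminus.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .core import (
    Genome,
    GenomicInterval,
    ReadAlignment,
    RepeatInstance,
    ScoreTrack,
    TranscriptModel,
    reverse_complement,
)
from .signals import (
    ACCEPTOR_INTRONIC,
    ACCEPTOR_WIDTH,
    DONOR_EXONIC,
    DONOR_WIDTH,
    MotifSet,
    SpliceSiteModel,
    STOP_CODONS,
)

logger = logging.getLogger("exontrap")

BASES = "ACGT"
_BASE_ARR = np.frombuffer(b"ACGT", dtype=np.uint8)

# Generating position probability models (A, C, G, T).  Donor: 3 exonic +
# GT + 4 intronic consensus-like positions; acceptor: 18 pyrimidine-rich
# positions + AG + 3 exonic.
DONOR_PROBS = np.array(
    [
        [0.33, 0.37, 0.18, 0.12],
        [0.60, 0.13, 0.14, 0.13],
        [0.10, 0.04, 0.80, 0.06],
        [0.0, 0.0, 1.0, 0.0],  # G, invariant
        [0.0, 0.0, 0.0, 1.0],  # T, invariant
        [0.55, 0.02, 0.35, 0.08],
        [0.70, 0.08, 0.10, 0.12],
        [0.08, 0.05, 0.80, 0.07],
        [0.15, 0.15, 0.20, 0.50],
    ]
)

ACCEPTOR_PROBS = np.array(
    [[0.10, 0.30, 0.10, 0.50]] * 18
    + [
        [1.0, 0.0, 0.0, 0.0],  # A, invariant
        [0.0, 0.0, 1.0, 0.0],  # G, invariant
        [0.25, 0.15, 0.50, 0.10],
        [0.30, 0.25, 0.20, 0.25],
        [0.25, 0.25, 0.25, 0.25],
    ]
)

# background dinucleotide (Markov) model with CpG depletion
BACKGROUND_INITIAL = np.array([0.28, 0.22, 0.22, 0.28])
BACKGROUND_TRANSITION = np.array(
    [
        [0.30, 0.20, 0.28, 0.22],
        [0.32, 0.28, 0.06, 0.34],
        [0.26, 0.24, 0.26, 0.24],
        [0.18, 0.26, 0.30, 0.26],
    ]
)

EXON_BODY_PROBS = np.array([0.22, 0.28, 0.28, 0.22])

DEFAULT_ESE_MOTIFS = (
    "GAAGAA",
    "AAGAAG",
    "GAAGGA",
    "AGAAGA",
    "TGAAGA",
    "GGAAGA",
    "AAGGAA",
    "CAAGAA",
)

PLAIN_REPEAT_FAMILY = "SIM_ALU"
EXONIC_REPEAT_FAMILY = "SIM_L1EX"

# inclusion-rate length band (the typical internal-exon length range)
LENGTH_BAND = (63, 222)


def generating_model() -> SpliceSiteModel:
    """Log-odds scorer derived from the generating probabilities."""
    return SpliceSiteModel.from_probabilities(DONOR_PROBS, ACCEPTOR_PROBS)


@dataclass
class LibraryConfig:
    library_id: str
    vector_id: str
    frame_offset: int
    coverage: float = 0.85
    dark_cycle_trim: int = 3
    scale: float = 1.0

    def __post_init__(self) -> None:
        if self.frame_offset not in (0, 1, 2):
            raise ValueError("frame_offset must be 0, 1 or 2")
        if not (0 < self.coverage <= 1):
            raise ValueError("coverage must be in (0, 1]")
        if self.dark_cycle_trim not in (3, 4):
            raise ValueError("dark_cycle_trim must be 3 or 4")


def default_libraries() -> List[LibraryConfig]:
    return [
        LibraryConfig("lib1", "vecF0", 0, dark_cycle_trim=3),
        LibraryConfig("lib2", "vecF1", 1, dark_cycle_trim=4),
        LibraryConfig("lib3", "vecF2", 2, dark_cycle_trim=3),
        LibraryConfig("lib4", "vecF0", 0, dark_cycle_trim=4),
        LibraryConfig("lib5", "vecF1", 1, dark_cycle_trim=3),
    ]


@dataclass
class SimConfig:
    genome_length: int = 200_000
    chrom: str = "sim1"
    n_genes: int = 4
    n_lnc_genes: int = 1
    exons_per_gene: int = 4  # internal exons per gene
    n_intergenic_exons: int = 10
    n_antisense_exons: int = 5
    n_intronic_exons: int = 5
    exon_length_range: Tuple[int, int] = (66, 180)
    exon_length_multiple: int = 1  # set 3 to force frame-compatible lengths
    intron_length_range: Tuple[int, int] = (700, 1500)
    fragment_length_range: Tuple[int, int] = (500, 1000)
    libraries: List[LibraryConfig] = field(default_factory=default_libraries)
    nmd_factor: float = 0.5
    jitter_prob: float = 0.1
    base_inclusion: float = 150.0
    inclusion_weights: Tuple[float, float, float, float] = (-7.0, 0.4, 0.15, -1.5)
    ese_motifs: Tuple[str, ...] = DEFAULT_ESE_MOTIFS
    ese_rate_per_100bp: float = 2.0
    stop_free_frame_prob: float = 0.0  # chance an exon body avoids frame-0 stops
    n_repeats_plain: int = 8
    n_repeats_exonic: int = 6
    repeat_mutation_rate: float = 0.03
    min_gap: int = 1200
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "n_genes",
            "n_lnc_genes",
            "n_intergenic_exons",
            "n_antisense_exons",
            "n_intronic_exons",
            "n_repeats_plain",
            "n_repeats_exonic",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (0 <= self.jitter_prob < 0.5):
            raise ValueError("jitter_prob must be in [0, 0.5)")
        if not (0 < self.nmd_factor <= 1):
            raise ValueError("nmd_factor must be in (0, 1]")
        if self.exon_length_range[0] > self.exon_length_range[1]:
            raise ValueError("bad exon_length_range")
        self.libraries = [
            lib if isinstance(lib, LibraryConfig) else LibraryConfig(**lib)
            for lib in self.libraries
        ]

    @property
    def motif_set(self) -> MotifSet:
        return MotifSet("sim_ese", frozenset(self.ese_motifs))


@dataclass
class TruthExon:
    """A planted exon with its generating signal strengths."""

    interval: GenomicInterval
    category: str  # mRNA_internal, lncRNA_internal, intronic, antisense, intergenic
    donor_score: float
    acceptor_score: float
    ese_count: int
    has_stop_in_frame: Dict[int, bool]
    expected_rate: float = 0.0


TRUTH_TO_REGION = {
    "mRNA_internal": "mRNA_exon_internal",
    "lncRNA_internal": "lncRNA_exon",
    "intronic": "mRNA_intron",
    "antisense": "antisense",
    "intergenic": "intergenic",
}


@dataclass
class SimOutput:
    genome: Genome
    annotation: List[TranscriptModel]
    truth: List[TruthExon]
    repeats: List[RepeatInstance]
    tracks: Dict[str, ScoreTrack]
    config: SimConfig
    alignments: Dict[str, List[ReadAlignment]] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# inclusion-rate model
# ---------------------------------------------------------------------------

def logistic(x: float) -> float:
    return 1.0 / (1.0 + np.exp(-x))


def inclusion_rate(
    donor_score: float,
    acceptor_score: float,
    ese_count: int,
    length: int,
    config: SimConfig,
) -> float:
    """Expected reads per trapping event: bounded, monotone in signal."""
    w0, w1, w2, w3 = config.inclusion_weights
    penalty = 0.0 if LENGTH_BAND[0] <= length <= LENGTH_BAND[1] else 1.0
    eta = w0 + w1 * (donor_score + acceptor_score) + w2 * ese_count + w3 * penalty
    return config.base_inclusion * logistic(eta)


def library_rate(truth: TruthExon, lib: LibraryConfig, config: SimConfig) -> float:
    rate = truth.expected_rate * lib.scale
    if truth.has_stop_in_frame.get(lib.frame_offset, False):
        rate *= config.nmd_factor
    return rate


def expected_pooled_count(truth: TruthExon, config: SimConfig) -> float:
    """Expectation of the pooled read count over presence and sampling."""
    return sum(lib.coverage * library_rate(truth, lib, config) for lib in config.libraries)


# ---------------------------------------------------------------------------
# sequence generation helpers
# ---------------------------------------------------------------------------

def markov_sequence(length: int, rng: np.random.Generator) -> str:
    """Background sequence from the stated dinucleotide (Markov) model."""
    u = rng.random(length)
    cum = np.cumsum(BACKGROUND_TRANSITION, axis=1)
    init_cum = np.cumsum(BACKGROUND_INITIAL)
    out = np.empty(length, dtype=np.int8)
    state = int(np.searchsorted(init_cum, u[0], side="right"))
    out[0] = state
    for i in range(1, length):
        state = int(np.searchsorted(cum[state], u[i], side="right"))
        out[i] = state
    return _BASE_ARR[out].tobytes().decode("ascii")


def _sample_pwm(probs: np.ndarray, rng: np.random.Generator) -> str:
    cum = np.cumsum(probs, axis=1)
    u = rng.random(len(probs))
    idx = (u[:, None] > cum).sum(axis=1)
    return "".join(BASES[i] for i in idx)


def _sample_iid(probs: np.ndarray, length: int, rng: np.random.Generator) -> str:
    idx = rng.choice(4, size=length, p=probs)
    return "".join(BASES[i] for i in idx)


def dinucleotide_counts(seq: str) -> Dict[str, int]:
    counts: Dict[str, int] = {}
    for i in range(len(seq) - 1):
        d = seq[i : i + 2]
        counts[d] = counts.get(d, 0) + 1
    return counts


def _exon_body(length: int, stop_free_frame0: bool, rng: np.random.Generator) -> str:
    """Exon body sequence; optionally resampled codon-wise so frame 0
    carries no stop codon."""
    if not stop_free_frame0:
        return _sample_iid(EXON_BODY_PROBS, length, rng)
    codons: List[str] = []
    for _ in range(length // 3):
        codon = _sample_iid(EXON_BODY_PROBS, 3, rng)
        while codon in STOP_CODONS:
            codon = _sample_iid(EXON_BODY_PROBS, 3, rng)
        codons.append(codon)
    tail = length - 3 * (length // 3)
    if tail:
        codons.append(_sample_iid(EXON_BODY_PROBS, tail, rng))
    return "".join(codons)


def _insert_eses(body: str, config: SimConfig, rng: np.random.Generator) -> str:
    n = rng.poisson(config.ese_rate_per_100bp * len(body) / 100.0)
    if n == 0 or len(body) < 14:
        return body
    body_list = list(body)
    taken: List[Tuple[int, int]] = []
    motifs = config.ese_motifs
    for _ in range(n):
        for _try in range(20):
            start = int(rng.integers(4, len(body) - 10))
            if all(start + 6 <= s or start >= e for s, e in taken):
                motif = motifs[int(rng.integers(len(motifs)))]
                body_list[start : start + 6] = motif
                taken.append((start, start + 6))
                break
    return "".join(body_list)


# ---------------------------------------------------------------------------
# genome layout
# ---------------------------------------------------------------------------

@dataclass
class _PlantedExon:
    offset: int  # start within element
    length: int
    strand: str
    category: str
    stop_free: bool = False


@dataclass
class _Element:
    kind: str  # gene, lnc_gene, intergenic_exon, repeat
    length: int
    payload: dict


def _draw_exon_length(config: SimConfig, rng: np.random.Generator) -> int:
    lo, hi = config.exon_length_range
    n = int(rng.integers(lo, hi + 1))
    m = config.exon_length_multiple
    if m > 1:
        n = max(lo + (-lo) % m, (n // m) * m)
    return n


def _plan_elements(config: SimConfig, rng: np.random.Generator) -> List[_Element]:
    elements: List[_Element] = []
    margin = 90  # keeps planted windows clear of neighbouring features

    intron_hosts: List[dict] = []
    for g in range(config.n_genes + config.n_lnc_genes):
        is_lnc = g >= config.n_genes
        strand = "+" if rng.random() < 0.5 else "-"
        n_internal = config.exons_per_gene if not is_lnc else max(config.exons_per_gene - 2, 1)
        first_len = int(rng.integers(100, 200))
        last_len = int(rng.integers(150, 250))
        internal_lens = [_draw_exon_length(config, rng) for _ in range(n_internal)]
        intron_lens = [
            int(rng.integers(*config.intron_length_range)) for _ in range(n_internal + 1)
        ]
        payload = {
            "strand": strand,
            "gene_type": "lncRNA" if is_lnc else "protein_coding",
            "first_len": first_len,
            "last_len": last_len,
            "internal_lens": internal_lens,
            "intron_lens": intron_lens,
            "hosted": {},  # intron index -> _PlantedExon
            "index": g,
        }
        length = first_len + last_len + sum(internal_lens) + sum(intron_lens)
        elements.append(_Element("gene", length, payload))
        if not is_lnc:
            for i in range(n_internal + 1):
                intron_hosts.append({"payload": payload, "intron": i})

    # distribute intronic and antisense exons over protein-coding introns
    wanted = [("intronic", config.n_intronic_exons), ("antisense", config.n_antisense_exons)]
    total_wanted = sum(n for _, n in wanted)
    if total_wanted > len(intron_hosts):
        raise ValueError(
            f"cannot host {total_wanted} intronic/antisense exons in "
            f"{len(intron_hosts)} introns; add genes or internal exons"
        )
    host_order = list(rng.permutation(len(intron_hosts)))
    cursor = 0
    for category, n in wanted:
        for _ in range(n):
            host = intron_hosts[host_order[cursor]]
            cursor += 1
            payload, intron_i = host["payload"], host["intron"]
            exon_len = _draw_exon_length(config, rng)
            intron_len = payload["intron_lens"][intron_i]
            if intron_len < exon_len + 2 * margin:
                payload["intron_lens"][intron_i] = exon_len + 2 * margin
                intron_len = exon_len + 2 * margin
            gene_strand = payload["strand"]
            strand = gene_strand if category == "intronic" else ("-" if gene_strand == "+" else "+")
            offset = int(rng.integers(margin, intron_len - exon_len - margin + 1))
            payload["hosted"][intron_i] = _PlantedExon(
                offset, exon_len, strand, category,
                stop_free=rng.random() < config.stop_free_frame_prob,
            )

    # recompute gene lengths (introns may have grown)
    for el in elements:
        if el.kind == "gene":
            p = el.payload
            el.length = (
                p["first_len"] + p["last_len"] + sum(p["internal_lens"]) + sum(p["intron_lens"])
            )

    for _ in range(config.n_intergenic_exons):
        exon_len = _draw_exon_length(config, rng)
        strand = "+" if rng.random() < 0.5 else "-"
        elements.append(
            _Element(
                "intergenic_exon",
                exon_len,
                {
                    "strand": strand,
                    "stop_free": rng.random() < config.stop_free_frame_prob,
                },
            )
        )

    for _ in range(config.n_repeats_plain):
        cs = int(rng.integers(0, 80))
        ce = int(rng.integers(220, 300))
        elements.append(
            _Element(
                "repeat",
                ce - cs,
                {
                    "family": PLAIN_REPEAT_FAMILY,
                    "cons_start": cs,
                    "cons_end": ce,
                    "orientation": "+" if rng.random() < 0.5 else "-",
                    "with_exon": False,
                },
            )
        )
    for _ in range(config.n_repeats_exonic):
        elements.append(
            _Element(
                "repeat",
                400,
                {
                    "family": EXONIC_REPEAT_FAMILY,
                    "cons_start": 0,
                    "cons_end": 400,
                    "orientation": "+" if rng.random() < 0.5 else "-",
                    "with_exon": True,
                },
            )
        )

    order = rng.permutation(len(elements))
    return [elements[i] for i in order]


# consensus exon coordinates inside the exonic repeat family
_REPEAT_EXON_CONS = (150, 240)


def generate_genome(config: SimConfig) -> SimOutput:
    """Build the toy genome, annotation, truth table, repeats and a
    synthetic conservation track (no alignments yet)."""
    rng = np.random.default_rng(config.seed)
    elements = _plan_elements(config, rng)

    needed = sum(e.length for e in elements) + (len(elements) + 1) * config.min_gap
    if needed > config.genome_length:
        raise ValueError(
            f"infeasible packing: features need {needed} bases but "
            f"genome_length is {config.genome_length}"
        )

    # place elements with randomly distributed slack
    slack = config.genome_length - needed
    extra = rng.multinomial(slack, np.full(len(elements) + 1, 1.0 / (len(elements) + 1)))
    gaps = [config.min_gap + int(x) for x in extra]

    seq = bytearray(markov_sequence(config.genome_length, rng), "ascii")
    chrom = config.chrom
    gen_model = generating_model()
    motifs = config.motif_set

    annotation: List[TranscriptModel] = []
    truth: List[TruthExon] = []
    repeats: List[RepeatInstance] = []

    # repeat consensus sequences (deterministic from the seed)
    cons_rng = np.random.default_rng(config.seed + 7919)
    consensus = {
        PLAIN_REPEAT_FAMILY: markov_sequence(300, cons_rng),
        EXONIC_REPEAT_FAMILY: markov_sequence(400, cons_rng),
    }

    def write(pos: int, segment: str) -> None:
        seq[pos : pos + len(segment)] = segment.encode("ascii")

    def plant_exon(start: int, length: int, strand: str, category: str, stop_free: bool) -> TruthExon:
        body = _insert_eses(_exon_body(length, stop_free, rng), config, rng)
        w_a = _sample_pwm(ACCEPTOR_PROBS, rng)
        w_d = _sample_pwm(DONOR_PROBS, rng)
        body = w_a[ACCEPTOR_INTRONIC:] + body[3:-3] + w_d[:DONOR_EXONIC]
        segment = w_a[:ACCEPTOR_INTRONIC] + body + w_d[DONOR_EXONIC:]
        if strand == "+":
            write(start - ACCEPTOR_INTRONIC, segment)
        else:
            write(start - (DONOR_WIDTH - DONOR_EXONIC), reverse_complement(segment))
        iv = GenomicInterval(chrom, start, start + length, strand)
        n_ese, _ = _ese_density_count(body, motifs)
        stops = _stops_by_frame(body)
        t = TruthExon(
            interval=iv,
            category=category,
            donor_score=gen_model.score_window("donor", w_d),
            acceptor_score=gen_model.score_window("acceptor", w_a),
            ese_count=n_ese,
            has_stop_in_frame=stops,
        )
        t.expected_rate = inclusion_rate(t.donor_score, t.acceptor_score, t.ese_count, length, config)
        truth.append(t)
        return t

    def plant_boundary(pos: int, strand: str, kind: str) -> None:
        """Donor or acceptor window for a terminal exon boundary."""
        w = _sample_pwm(DONOR_PROBS if kind == "donor" else ACCEPTOR_PROBS, rng)
        m = SpliceSiteModel(donor_matrix=np.zeros((DONOR_WIDTH, 4)), acceptor_matrix=np.zeros((ACCEPTOR_WIDTH, 4)))
        lo, hi = m.window_interval(kind, pos, strand)
        write(lo, w if strand == "+" else reverse_complement(w))

    pos = gaps[0]
    for el, gap_after in zip(elements, gaps[1:]):
        start = pos
        if el.kind == "gene":
            p = el.payload
            strand, gtype = p["strand"], p["gene_type"]
            category = "mRNA_internal" if gtype == "protein_coding" else "lncRNA_internal"
            # genomic layout left->right: exon0, intron0, exon1, ...
            lens_exons = [p["first_len"]] + p["internal_lens"] + [p["last_len"]]
            n_introns = len(p["intron_lens"])
            if strand == "-":
                # transcription runs right-to-left; flip both lists so the
                # hosted-exon offsets line up with the intron they were
                # drawn for
                lens_exons = list(reversed(lens_exons))
                intron_lens_g = list(reversed(p["intron_lens"]))
            else:
                intron_lens_g = p["intron_lens"]
            exon_ivs: List[GenomicInterval] = []
            cur = start
            for i, el_len in enumerate(lens_exons):
                exon_ivs.append(GenomicInterval(chrom, cur, cur + el_len, strand))
                cur += el_len
                if i < n_introns:
                    intron_start = cur
                    intron_len = intron_lens_g[i]
                    hosted = p["hosted"].get(i if strand == "+" else n_introns - 1 - i)
                    if hosted is not None:
                        hstart = intron_start + hosted.offset
                        plant_exon(hstart, hosted.length, hosted.strand, hosted.category, hosted.stop_free)
                    cur += intron_len
            # transcription-order exon list for window planting
            tx_order = exon_ivs if strand == "+" else list(reversed(exon_ivs))
            for j, e in enumerate(tx_order):
                if j > 0:
                    plant_boundary(e.acceptor_pos, strand, "acceptor")
                if j < len(tx_order) - 1:
                    plant_boundary(e.donor_pos, strand, "donor")
            # internal exon bodies get full planted signal (overwrite windows)
            for e in tx_order[1:-1]:
                stop_free = rng.random() < config.stop_free_frame_prob
                plant_exon(e.start, e.length, strand, category, stop_free)
            gid = f"{'LNC' if gtype == 'lncRNA' else 'GENE'}{p['index']}"
            annotation.append(TranscriptModel(gid, gid + ".1", gtype, strand, exon_ivs))
        elif el.kind == "intergenic_exon":
            plant_exon(start, el.length, el.payload["strand"], "intergenic", el.payload["stop_free"])
        elif el.kind == "repeat":
            p = el.payload
            fam, cs, ce = p["family"], p["cons_start"], p["cons_end"]
            piece = consensus[fam][cs:ce]
            piece_arr = np.frombuffer(piece.encode(), dtype=np.uint8).copy()
            mut = rng.random(len(piece_arr)) < config.repeat_mutation_rate
            piece_arr[mut] = _BASE_ARR[rng.integers(0, 4, mut.sum())]
            piece = piece_arr.tobytes().decode("ascii")
            orientation = p["orientation"]
            write(start, piece if orientation == "+" else reverse_complement(piece))
            repeats.append(
                RepeatInstance(
                    family=fam,
                    interval=GenomicInterval(chrom, start, start + len(piece), orientation),
                    consensus_start=cs,
                    consensus_end=ce,
                    consensus_length=len(consensus[fam]),
                )
            )
            if p["with_exon"]:
                ex_cs, ex_ce = _REPEAT_EXON_CONS
                if orientation == "+":
                    ex_start = start + ex_cs
                else:
                    ex_start = start + (ce - cs) - ex_ce
                plant_exon(ex_start, ex_ce - ex_cs, orientation, "intergenic", False)
        pos = start + el.length + gap_after

    genome = Genome({chrom: seq.decode("ascii")})

    # synthetic conservation: elevated over annotated protein-coding exons
    cons_vals = rng.normal(0.0, 0.3, config.genome_length)
    for tx in annotation:
        if tx.gene_type == "protein_coding":
            for e in tx.exons:
                cons_vals[e.start : e.end] += 2.0
    tracks = {chrom: ScoreTrack(chrom, "+", cons_vals)}

    return SimOutput(genome, annotation, truth, repeats, tracks, config)


def _ese_density_count(body: str, motifs: MotifSet) -> Tuple[int, float]:
    from .signals import ese_density

    return ese_density(body, motifs)


def _stops_by_frame(body: str) -> Dict[int, bool]:
    stops = {0: False, 1: False, 2: False}
    for p in range(len(body) - 2):
        if body[p : p + 3] in STOP_CODONS:
            stops[p % 3] = True
    return stops


# ---------------------------------------------------------------------------
# trapping simulation
# ---------------------------------------------------------------------------

def simulate_trapping(sim: SimOutput, config: Optional[SimConfig] = None) -> Dict[str, List[ReadAlignment]]:
    """Per-library trapped-read streams for the planted exons.

    For each library, a fragment fully containing a planted exon is
    present with probability = the library's coverage (all-or-nothing
    plasmid sampling); a present fragment emits Poisson(rate) reads where
    the rate follows the logistic inclusion model, halved (by
    ``nmd_factor``) when the exon carries a stop codon in the vector's
    reading frame.  Read termini are jittered by 1-2 bases with
    ``jitter_prob`` and the acceptor-side terminus loses
    ``dark_cycle_trim`` bases to dark cycling.
    """
    config = config or sim.config
    rng = np.random.default_rng(config.seed + 104729)
    genome_len = sim.genome.length(config.chrom)
    frag_lo, frag_hi = config.fragment_length_range
    out: Dict[str, List[ReadAlignment]] = {lib.library_id: [] for lib in config.libraries}

    for lib in config.libraries:
        reads = out[lib.library_id]
        for t in sim.truth:
            iv = t.interval
            if iv.length > frag_hi:
                continue  # fragment cannot contain the exon
            if rng.random() >= lib.coverage:
                continue
            # the fragment this trapping event derives from
            frag_len = int(rng.integers(frag_lo, frag_hi + 1))
            lo = max(0, iv.end - frag_len)
            hi = min(iv.start, genome_len - frag_len)
            if hi < lo:
                continue
            _frag_start = int(rng.integers(lo, hi + 1))
            count = rng.poisson(library_rate(t, lib, config))
            if count == 0:
                continue
            starts = np.full(count, iv.start)
            ends = np.full(count, iv.end)
            if config.jitter_prob > 0:
                for arr in (starts, ends):
                    hit = rng.random(count) < config.jitter_prob
                    n_hit = int(hit.sum())
                    if n_hit:
                        delta = rng.choice([-2, -1, 1, 2], size=n_hit)
                        arr[hit] += delta
            # dark-cycle truncation of the exon 5' (acceptor-side) terminus
            if iv.strand == "+":
                starts = starts + lib.dark_cycle_trim
            else:
                ends = ends - lib.dark_cycle_trim
            for s, e in zip(starts, ends):
                riv = GenomicInterval(iv.chrom, int(s), int(e), iv.strand)
                reads.append(
                    ReadAlignment(
                        interval=riv,
                        blocks=[riv],
                        mapq=60,
                        clipped=False,
                        library_id=lib.library_id,
                        vector_id=lib.vector_id,
                    )
                )
    sim.alignments = out
    return out


# ---------------------------------------------------------------------------
# truth-table serialization
# ---------------------------------------------------------------------------

def write_truth(truth: Sequence[TruthExon], path: str) -> None:
    with open(path, "w") as fh:
        fh.write(
            "chrom\tstart\tend\tstrand\tcategory\tacceptor_score\tdonor_score\t"
            "ese_count\tstop_f0\tstop_f1\tstop_f2\texpected_rate\n"
        )
        for t in truth:
            iv = t.interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.strand}\t{t.category}\t"
                f"{t.acceptor_score:.4f}\t{t.donor_score:.4f}\t{t.ese_count}\t"
                f"{int(t.has_stop_in_frame[0])}\t{int(t.has_stop_in_frame[1])}\t"
                f"{int(t.has_stop_in_frame[2])}\t{t.expected_rate:.4f}\n"
            )


def read_truth(path: str) -> List[TruthExon]:
    out: List[TruthExon] = []
    with open(path) as fh:
        fh.readline()
        for line in fh:
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            out.append(
                TruthExon(
                    interval=GenomicInterval(f[0], int(f[1]), int(f[2]), f[3]),
                    category=f[4],
                    acceptor_score=float(f[5]),
                    donor_score=float(f[6]),
                    ese_count=int(f[7]),
                    has_stop_in_frame={0: f[8] == "1", 1: f[9] == "1", 2: f[10] == "1"},
                    expected_rate=float(f[11]),
                )
            )
    return out


# ---------------------------------------------------------------------------
# dinucleotide-preserving shuffle
# ---------------------------------------------------------------------------

def shuffle_dinucleotide(seq: str, seed: int) -> str:
    """Shuffle preserving the exact dinucleotide count multiset
    (Eulerian-path construction); first and last characters are fixed.
    Maximal ACGT runs are shuffled independently so N gaps stay put."""
    if len(seq) < 2:
        raise ValueError("sequence must have length >= 2")
    rng = np.random.default_rng(seed)
    seq = seq.upper()
    out: List[str] = []
    i, n = 0, len(seq)
    while i < n:
        if seq[i] == "N":
            j = i
            while j < n and seq[j] == "N":
                j += 1
            out.append("N" * (j - i))
            i = j
        else:
            j = i
            while j < n and seq[j] != "N":
                j += 1
            run = seq[i:j]
            out.append(_shuffle_run(run, rng) if len(run) >= 2 else run)
            i = j
    return "".join(out)


def _shuffle_run(s: str, rng: np.random.Generator) -> str:
    first, last = s[0], s[-1]
    # adjacency multisets
    succ: Dict[str, List[str]] = {}
    for a, b in zip(s, s[1:]):
        succ.setdefault(a, []).append(b)
    vertices = [v for v in succ if succ[v]]

    # choose last-exit edges forming an in-tree toward `last`
    while True:
        last_edge: Dict[str, str] = {}
        for v in vertices:
            if v == last:
                continue
            last_edge[v] = succ[v][int(rng.integers(len(succ[v])))]
        ok = True
        for v in vertices:
            if v == last:
                continue
            seen = {v}
            cur = v
            while cur != last:
                cur = last_edge.get(cur)
                if cur is None or cur in seen:
                    ok = False
                    break
                seen.add(cur)
            if not ok:
                break
        if ok:
            break

    # arrange each adjacency list: random order, designated last edge final
    queues: Dict[str, List[str]] = {}
    for v in vertices:
        edges = list(succ[v])
        if v in last_edge:
            edges.remove(last_edge[v])
        order = rng.permutation(len(edges))
        arranged = [edges[k] for k in order]
        if v in last_edge:
            arranged.append(last_edge[v])
        queues[v] = arranged

    chars = [first]
    cur = first
    pops = {v: 0 for v in queues}
    for _ in range(len(s) - 1):
        nxt = queues[cur][pops[cur]]
        pops[cur] += 1
        chars.append(nxt)
        cur = nxt
    return "".join(chars)
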