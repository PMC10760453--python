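import numpy as np
import pytest

from exontrap.calling import CallingConfig, call_exons
from exontrap.signals import SpliceSiteModel, site_windows
from exontrap.simulate import SimConfig, generate_genome, simulate_trapping


def acceptance_sim_config(seed: int = 1, jitter: float = 0.0, **kw) -> SimConfig:
    """The 2 Mb / ~300 planted exon / 5 library study configuration."""
    base = dict(
        genome_length=2_000_000,
        n_genes=30,
        n_lnc_genes=5,
        exons_per_gene=5,
        n_intergenic_exons=60,
        n_antisense_exons=40,
        n_intronic_exons=40,
        jitter_prob=jitter,
        seed=seed,
    )
    base.update(kw)
    return SimConfig(**base)


def run_calling_chain(sim, cfg):
    """Train the scorer on the annotated internal exons and run the full
    exon-calling chain; returns (scorer, clusters, primaries)."""
    internal = [e for tx in sim.annotation for e in tx.exons_in_transcription_order()[1:-1]]
    donors, acceptors = site_windows(sim.genome, internal)
    scorer = SpliceSiteModel.train(donors, acceptors)
    calling = CallingConfig(
        dark_cycle_trim_by_library={l.library_id: l.dark_cycle_trim for l in cfg.libraries}
    )
    clusters, primaries = call_exons(sim.alignments, scorer, sim.genome, calling)
    return scorer, clusters, primaries


@pytest.fixture(scope="session")
def small_sim():
    """200 kb simulation with trapping reads (no jitter), shared across tests."""
    cfg = SimConfig(seed=11, jitter_prob=0.0)
    sim = generate_genome(cfg)
    simulate_trapping(sim, cfg)
    return sim


@pytest.fixture(scope="session")
def big_sim():
    """Acceptance-scale simulation (2 Mb, ~300 exons, jitter 0, seed 1)."""
    cfg = acceptance_sim_config(seed=1)
    sim = generate_genome(cfg)
    simulate_trapping(sim, cfg)
    return sim


@pytest.fixture(scope="session")
def big_called(big_sim):
    return run_calling_chain(big_sim, big_sim.config)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
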