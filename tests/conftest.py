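import pytest

from ccseq import (
    ReadSimConfig,
    make_genome,
    random_cleavage_model,
    simulate_break_map,
    simulate_read_pairs,
)
from ccseq import fileio


@pytest.fixture(scope="session")
def small_genome():
    return make_genome(60_000, gc=0.40, seed=101)


@pytest.fixture(scope="session")
def top2_model(small_genome):
    """DSB-only Top2-like model (4-nt overhang)."""
    return random_cleavage_model(small_genome, n_sites=80, overhang=4, seed=102)


@pytest.fixture(scope="session")
def truth_map(top2_model):
    return simulate_break_map(top2_model, depth=1.0, seed=103)


@pytest.fixture(scope="session")
def clean_sam(tmp_path_factory, truth_map, small_genome):
    """Error-free simulated SAM for the truth map."""
    path = tmp_path_factory.mktemp("sam") / "clean.sam"
    records = simulate_read_pairs(truth_map, small_genome, ReadSimConfig(seed=104))
    fileio.write_sam(records, small_genome.contig_lengths(), path)
    return path
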