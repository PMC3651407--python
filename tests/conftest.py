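import pytest
from hypothesis import settings

from contiggraph import ace_io, simgen

settings.register_profile("repeatable", derandomize=True, deadline=None)
settings.load_profile("repeatable")

FIG3_SEED = 7


@pytest.fixture(scope="session")
def fig3_genome():
    """Four unique sections + a two-copy repeat on one linear chromosome."""
    return simgen.build_genome(simgen.fig3_style_spec(seed=FIG3_SEED))


@pytest.fixture(scope="session")
def fig3_ace(fig3_genome):
    return simgen.emit_ace(fig3_genome)


@pytest.fixture(scope="session")
def fig3_result(fig3_ace):
    """(graph, extraction, anomalies) from the simulated ACE assembly."""
    return ace_io.from_ace(fig3_ace)


@pytest.fixture(scope="session")
def panel_graph():
    """Graph of the chromosome + plasmid-menagerie genome."""
    genome = simgen.build_genome(simgen.replicon_panel_spec(seed=FIG3_SEED))
    graph, _, _ = ace_io.from_ace(simgen.emit_ace(genome))
    return genome, graph


@pytest.fixture(scope="session")
def matepair_fixture(tmp_path_factory):
    """(genome, sam_path) for the two-contig known-gap mate-pair genome."""
    genome = simgen.build_genome(simgen.matepair_gap_spec(seed=FIG3_SEED))
    sam = simgen.emit_matepairs(genome, n_pairs=3000)
    path = tmp_path_factory.mktemp("mp") / "matepairs.sam"
    path.write_text(sam)
    return genome, path
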