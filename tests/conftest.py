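import numpy as np
import pyfaidx
import pytest

from fusionviz import fixtures, fusion_builder, gene_models, io_formats


@pytest.fixture(scope="session")
def scenario(tmp_path_factory):
    """Default toy scenario: reverse-strand single-chromosome geometry."""
    return fixtures.make_scenario(7, tmp_path_factory.mktemp("scenario"))


@pytest.fixture(scope="session")
def truth(scenario):
    return fixtures.truth_report(scenario)


@pytest.fixture(scope="session")
def store(scenario):
    return gene_models.parse_gtf(str(scenario.paths["gtf"]))


@pytest.fixture(scope="session")
def genome(scenario):
    return pyfaidx.Fasta(str(scenario.paths["fasta"]))


@pytest.fixture(scope="session")
def built(scenario, store, genome):
    """The fusion transcript assembled from the scenario's default pair."""
    rec = io_formats.read_bedpe(scenario.paths["bedpe"])[0]
    candidate = fusion_builder.candidate_from_bedpe(rec, store)
    return fusion_builder.build_fusion_transcript(
        candidate,
        store.transcripts["TXA001"],
        store.transcripts["TXB001"],
        genome,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
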