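import pathlib

import numpy as np
import pytest

import rifconv as rc

REPO = pathlib.Path(__file__).resolve().parent.parent
GENOME_TABLE = REPO / "examples" / "data" / "genome_features.tsv"


@pytest.fixture(scope="session")
def jtt_model():
    """JTT model with its published default frequencies."""
    return rc.build_model(rc.JTT_FREQUENCIES)


@pytest.fixture(scope="session")
def bench_tree():
    """The 9-leaf benchmark tree with its three foreground branches."""
    return rc.default_tree()


@pytest.fixture()
def four_taxon_tree():
    return rc.read_tree("((A:0.12,B:0.07):0.05,(C:0.20,D:0.09):0.11);")


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


def make_alignment(gene_id, taxa, seqs):
    return rc.Alignment(
        gene_id=gene_id, taxa=list(taxa),
        codes=np.vstack([rc.io.encode_sequence(s) for s in seqs]),
    )


@pytest.fixture()
def genome_table():
    return rc.read_genome_table(GENOME_TABLE)
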