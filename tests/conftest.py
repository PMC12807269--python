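import numpy as np
import pytest
from hypothesis import settings

from otuspace import embedder, hetnet, otu_io, synthdata, walker

settings.register_profile("suite", deadline=None, derandomize=True)
settings.load_profile("suite")

#: scale of the fixture pipeline used across the suite (kept small so the
#: whole chain runs in seconds; the statistics are scale-invariant)
WALKS_PER_OTU = 20
N_CYCLES = 20
EMBED_DIM = 64
PIPELINE_SEED = 1


@pytest.fixture(scope="session")
def fixture_data():
    return synthdata.fixture_small()


@pytest.fixture(scope="session")
def fixture_pipeline(fixture_data):
    """Full chain on the canned cohort: filter -> network -> walks -> vectors."""
    table, meta, truth = fixture_data
    filtered = otu_io.filter_dataset(table)
    rel = otu_io.to_relative_abundance(filtered)
    net = hetnet.build_network(rel)
    corpus = walker.generate_corpus(
        net, walks_per_otu=WALKS_PER_OTU, n_cycles=N_CYCLES, seed=PIPELINE_SEED
    )
    space = embedder.train_embeddings(corpus, d=EMBED_DIM, seed=PIPELINE_SEED)
    X = embedder.aligned_matrix(space, rel.sample_ids, "SAMPLE")
    return {
        "table": table, "meta": meta, "truth": truth, "filtered": filtered,
        "rel": rel, "net": net, "corpus": corpus, "space": space,
        "sample_space": X,
    }


@pytest.fixture
def toy_table(tmp_path):
    """3-OTU x 2-sample classic TSV with known depths {7, 5}."""
    path = tmp_path / "toy.tsv"
    path.write_text(
        "#OTU ID\tsampleA\tsampleB\n"
        "otu1\t5\t0\n"
        "otu2\t0\t3\n"
        "otu3\t2\t2\n"
    )
    return path


def make_table(counts, sample_ids=None, otu_ids=None):
    counts = np.asarray(counts)
    n_s, n_o = counts.shape
    return otu_io.OtuTable(
        sample_ids or [f"s{i}" for i in range(n_s)],
        otu_ids or [f"o{j}" for j in range(n_o)],
        counts,
    )
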