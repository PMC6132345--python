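import pytest
from hypothesis import settings

from fusioncall import (
    GeneModelIndex,
    RegionGenome,
    generate_fixture,
    g292_pcr_templates,
    read_chimeric_junctions,
    read_gtf,
    read_primers_tsv,
)

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")

FIXTURE_SEED = 17


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    out = tmp_path_factory.mktemp("g292")
    generate_fixture("g292", FIXTURE_SEED, out)
    return out


@pytest.fixture(scope="session")
def truth(fixture_dir):
    from fusioncall import TruthSet

    return TruthSet.from_json(fixture_dir / "truth.json")


@pytest.fixture(scope="session")
def models(fixture_dir):
    return read_gtf(fixture_dir / "models.gtf")


@pytest.fixture(scope="session")
def index(models):
    return GeneModelIndex(models)


@pytest.fixture(scope="session")
def genome(fixture_dir):
    return RegionGenome.from_fasta(fixture_dir / "genome.fa")


@pytest.fixture(scope="session")
def replicates(fixture_dir, truth):
    return [
        read_chimeric_junctions(fixture_dir / name, replicate_id=f"R{i + 1}")
        for i, name in enumerate(truth.files["junctions"])
    ]


@pytest.fixture(scope="session")
def templates(fixture_dir):
    return g292_pcr_templates(fixture_dir)


@pytest.fixture(scope="session")
def primers(fixture_dir):
    return read_primers_tsv(fixture_dir / "primers.tsv")


@pytest.fixture(scope="session")
def random_fixture(tmp_path_factory):
    out = tmp_path_factory.mktemp("randomfix")
    truth = generate_fixture("random", 123, out, n_events=50)
    return out, truth
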