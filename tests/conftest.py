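import pytest

from extscan.classify import classify_proteome
from extscan.motifs import profile_motifs
from extscan.synthetic import GeneratorSpec, generate_proteome


@pytest.fixture(scope="session")
def default_synthetic():
    """Seed-1 default proteome (10 per class, 20 backgrounds, ambiguity 0)."""
    return generate_proteome(GeneratorSpec(seed=1))


@pytest.fixture(scope="session")
def default_records(default_synthetic):
    return default_synthetic[0]


@pytest.fixture(scope="session")
def default_truths(default_synthetic):
    return default_synthetic[1]


@pytest.fixture(scope="session")
def default_classifications(default_records):
    return classify_proteome(default_records)


@pytest.fixture(scope="session")
def default_profiles(default_records):
    return [profile_motifs(r.sequence, r.id) for r in default_records]


@pytest.fixture
def tiny_fasta(tmp_path):
    path = tmp_path / "tiny.fasta"
    path.write_text(">a first\nSPPP\n>b second\nMKV\n")
    return path
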