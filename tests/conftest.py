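import pytest

from profilegrid import build_profile, make_alignment, normalize

TOY4_RECORDS = (
    ("s1", "ACD"),
    ("s2", "ACD"),
    ("s3", "A-E"),
    ("s4", "GCD"),
)

TOY4_FASTA = "".join(f">{rid}\n{seq}\n" for rid, seq in TOY4_RECORDS)

TOY4_CLUSTAL = (
    "CLUSTAL W (1.82) multiple sequence alignment\n"
    "\n"
    "s1    ACD\n"
    "s2    ACD\n"
    "s3    A-E\n"
    "s4    GCD\n"
)


@pytest.fixture
def toy4():
    return make_alignment(TOY4_RECORDS)


@pytest.fixture
def toy4_profile(toy4):
    return build_profile(toy4)


@pytest.fixture
def toy4_freqs(toy4_profile):
    return normalize(toy4_profile)


@pytest.fixture
def toy4_fasta(tmp_path):
    path = tmp_path / "toy4.fasta"
    path.write_text(TOY4_FASTA)
    return path


@pytest.fixture
def toy4_clustal(tmp_path):
    path = tmp_path / "toy4.aln"
    path.write_text(TOY4_CLUSTAL)
    return path
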