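import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20230613)


def random_dna(rng, length):
    return "".join(rng.choice(list("ACGT"), size=length))


def random_rna(rng, length):
    return "".join(rng.choice(list("ACGU"), size=length))


@pytest.fixture
def tiny_fasta(tmp_path):
    path = tmp_path / "tiny.fasta"
    path.write_text(">a\nACGU\n>b\nGGGU\n")
    return path
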