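import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def fasta_factory(tmp_path):
    """Write a FASTA file from (label, sequence) pairs, return its path."""

    counter = {"n": 0}

    def write(records):
        counter["n"] += 1
        path = tmp_path / f"aln{counter['n']}.fasta"
        with open(path, "w") as fh:
            for label, seq in records:
                fh.write(f">{label}\n{seq}\n")
        return path

    return write


@pytest.fixture
def toy_codon_alignment():
    from lipidshift.alignment import CodonAlignment

    return CodonAlignment(
        ["t1", "t2", "t3", "t4"],
        [
            "ATGGCTAAAGTT",
            "ATGGCTAAAGTC",
            "ATGGCAAAAGTT",
            "ATGGCTAGAGTT",
        ],
    )


@pytest.fixture
def toy_tree():
    from lipidshift.likelihood import read_tree

    return read_tree("((t1:0.1,t2:0.2):0.05,(t3:0.15,t4:0.1):0.08);")
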