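import numpy as np
import pytest

from ssnmine.profile_search import build_profile, calibrate_evalue
from ssnmine.sequence_io import AMINO_ACIDS, SequenceRecord
from ssnmine.synthetic_data import BenchmarkConfig, generate_benchmark


def random_protein(rng: np.random.Generator, length: int, start_met: bool = True) -> str:
    body = "".join(AMINO_ACIDS[i] for i in rng.integers(0, 20, size=length))
    return ("M" + body[1:]) if start_met and length > 0 else body


@pytest.fixture(scope="session")
def small_benchmark():
    """A scaled-down benchmark shared by unit tests (fast to generate)."""
    config = BenchmarkConfig(
        n_families=2,
        family_size=14,
        novel_cluster_size=6,
        decoy_count=8,
        root_length=120,
        truncation_fraction=0.15,
        seed=11,
    )
    records, truth, seed_alignments = generate_benchmark(config)
    return config, records, truth, seed_alignments


@pytest.fixture(scope="session")
def small_profile(small_benchmark):
    """Calibrated profile for family 0 of the small benchmark."""
    _, _, _, seed_alignments = small_benchmark
    profile = build_profile(seed_alignments[0], name="family0")
    return calibrate_evalue(profile, decoy_count=250, decoy_length=200, seed=5)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def make_record(rec_id: str, residues: str, source: str = "metagenome", **kwargs) -> SequenceRecord:
    return SequenceRecord(id=rec_id, source=source, residues=residues, **kwargs)
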