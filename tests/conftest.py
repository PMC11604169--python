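import logging

import numpy as np
import pytest

from damid_kit import fixtures

logging.getLogger("damid_kit").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def small_spec():
    return fixtures.SimulationSpec(
        seed=42, n_chrom=2, chrom_length=30_000, motif_rate=3.0,
        library_sizes=[4000, 4000, 4000, 4000],
    )


@pytest.fixture(scope="session")
def small_genome(small_spec):
    return fixtures.make_genome(small_spec)


@pytest.fixture(scope="session")
def small_regions(small_genome):
    return fixtures.make_regions(small_genome)


@pytest.fixture(scope="session")
def small_matrix(small_spec, small_regions):
    samples = fixtures.make_samples(small_spec)
    matrix, enriched = fixtures.simulate_counts(small_regions, small_spec, samples)
    return matrix, enriched


def write_fasta(path, sequences: dict[str, str]):
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n{seq}\n")
    return path


@pytest.fixture()
def toy_fasta(tmp_path):
    # chrT carries GATC at 2 and 10
    return write_fasta(tmp_path / "toy.fa", {"chrT": "TTGATCAAAAGATCCC"})
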