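import random

import pytest

from adtcount import (
    BarcodeWhitelist,
    SimulationConfig,
    TagReference,
    generate_dataset,
)


@pytest.fixture
def rng():
    return random.Random(20240520)


@pytest.fixture
def small_whitelist():
    return BarcodeWhitelist(
        (
            "AAAACCCCGGGGTTTT",
            "CCCCGGGGTTTTAAAA",
            "GGGGTTTTAAAACCCC",
            "TTTTAAAACCCCGGGG",
        )
    )


@pytest.fixture
def small_tags():
    return TagReference(
        ("CD4", "CD8"),
        ("ACACACACACACACAC", "GTGTGTGTGTGTGTGT"),
    )


@pytest.fixture
def clean_dataset(tmp_path):
    """Error-free, duplication-free synthetic dataset."""
    config = SimulationConfig(
        n_cells=30,
        n_tags=6,
        mean_molecules=3.0,
        duplication_rate=0.0,
        substitution_error_rate=0.0,
        seed=11,
    )
    return generate_dataset(config, tmp_path / "clean")


def write_fastq(path, records):
    """records: iterable of (read_id, sequence)."""
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")
    return path
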