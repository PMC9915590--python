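from __future__ import annotations

import numpy as np
import pytest

from deltasketch.io_fasta import GenomeInput, SequenceRecord, genome_from_records


def make_genome(*seqs: str, label: str = "") -> GenomeInput:
    records = [
        SequenceRecord(id=f"r{i}", seq=s.upper()) for i, s in enumerate(seqs)
    ]
    return genome_from_records(records, label=label)


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_pangenome():
    """Six 10-kb genomes at 1% divergence; shared across tests."""
    from deltasketch.simdata import PangenomeSimSpec, simulate_pangenome

    spec = PangenomeSimSpec(
        base_length=10_000, n_genomes=6, snp_rate=0.01,
        indel_rate=0.0005, novel_insert_bp=100, seed=11,
    )
    return simulate_pangenome(spec)
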