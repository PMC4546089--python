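"""Shared fixtures: small synthetic data built programmatically."""

from __future__ import annotations

import numpy as np
import pytest

from repeatscape import synthetic
from repeatscape.seqio import SequenceRecord

BASES = np.array(list("ACGT"))


def random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[rng.integers(0, 4, n)])


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def small_genome():
    """50 kb genome with two planted families (20% Gypsy, 10% Copia)."""
    spec = synthetic.GenomeSpec(
        genome_length=50_000,
        families=(
            synthetic.FamilySpec("RLG_a", "Gypsy", 500, 20, divergence=0.01),
            synthetic.FamilySpec("RLC_b", "Copia", 500, 10, divergence=0.01),
        ),
        seed=11,
    )
    return synthetic.make_genome(spec)


@pytest.fixture(scope="session")
def small_reads(small_genome):
    genome, _, _ = small_genome
    pairs, origins = synthetic.simulate_reads(genome, coverage=2.0, seed=11)
    return pairs, origins


def make_fastq(path, records):
    with open(path, "w") as fh:
        for rec in records:
            qual = "".join(chr(q + 33) for q in (rec.quality or [35] * len(rec)))
            fh.write(f"@{rec.identifier}\n{rec.sequence}\n+\n{qual}\n")
    return path


def record(ident: str, seq: str, qual: int = 35) -> SequenceRecord:
    return SequenceRecord(ident, seq, [qual] * len(seq))
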