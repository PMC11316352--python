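import numpy as np
import pytest

import picocult as pc


@pytest.fixture(scope="session")
def genome_100kb():
    return pc.generate_genome(100_000, 0.60, seed=7, genome_id="base")


@pytest.fixture(scope="session")
def genome_50kb():
    return pc.generate_genome(50_000, 0.50, seed=11, genome_id="ref50")


@pytest.fixture(scope="session")
def single_member_culture(genome_50kb):
    return pc.CultureTruth(
        culture_id="CU1",
        member_genome_ids=(genome_50kb.genome_id,),
        relative_abundances=(1.0,),
        n_reads=2000,
        read_length=150,
        substitution_rate=0.0,
        seed=42,
    )


def brute_force_exact_placements(read_seq: str, genome_seq: str):
    """All exact placements of a read on a genome, either strand.

    Independent oracle for the seeded mapper: plain substring scanning via
    str.find, no k-mers involved.  Returns sorted (start, strand) tuples.
    """
    from picocult._seq import revcomp

    hits = []
    for strand, seq in (("+", read_seq), ("-", revcomp(read_seq))):
        start = genome_seq.find(seq)
        while start != -1:
            hits.append((start, strand))
            start = genome_seq.find(seq, start + 1)
    return sorted(hits)
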