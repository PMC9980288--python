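import numpy as np
import pytest

from sigscan import GenomeSequence, MutationRecord
from sigscan.simulate import GenomeIndex, SyntheticCohortConfig, generate_genome


def mk_sbs(
    contig="c1",
    pos=10,
    ref="C",
    alt="T",
    sample="S1",
    alt_depth=20,
    total_depth=50,
):
    return MutationRecord(
        sample_id=sample,
        contig=contig,
        position=pos,
        ref_allele=ref,
        alt_allele=alt,
        alt_depth=alt_depth,
        total_depth=total_depth,
        vaf=alt_depth / total_depth,
    )


@pytest.fixture
def tiny_genome():
    #        123456789012345678901234
    return GenomeSequence({"c1": "AATCATGACCGGTTCATCTGGCAA", "c2": "TTTTCCCCGGGG"})


@pytest.fixture(scope="session")
def sim_genome():
    """A 2 x 100 kb uniform-composition genome shared across tests."""
    config = SyntheticCohortConfig(seed=11, n_contigs=2, contig_length=100_000)
    return generate_genome(config)


@pytest.fixture(scope="session")
def sim_index(sim_genome):
    return GenomeIndex(sim_genome)


def random_records_on(genome, n, rng, sample="S1"):
    """Uniform random SBS records consistent with the genome's bases."""
    records = []
    names = list(genome.contigs)
    lengths = np.array([genome.length(c) for c in names], dtype=float)
    for _ in range(n):
        ci = rng.choice(len(names), p=lengths / lengths.sum())
        contig = names[ci]
        pos = int(rng.integers(1, genome.length(contig) + 1))
        ref = genome.base(contig, pos)
        if ref == "N":
            continue
        alt = rng.choice([b for b in "ACGT" if b != ref])
        records.append(mk_sbs(contig, pos, ref, alt, sample=sample))
    return records
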