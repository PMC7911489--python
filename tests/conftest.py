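import pytest

from trimtail import (
    MatureRef,
    MirnaLocus,
    SeqCountTable,
    SimConfig,
    mask_genome,
    simulate_library,
    simulate_reference,
)

M1 = "ACGTACGTACGTACGTACGTA"  # 21 nt toy mature sequence


@pytest.fixture
def m1_ref() -> MatureRef:
    return MatureRef(ref_id="M1", sequence=M1, kind="guide")


@pytest.fixture
def toy_genome() -> dict[str, str]:
    # M1 planted at position 101 (1-based) between unrelated flanks
    left = "TTGCACCAATGGTTCAAGTCC" * 5
    right = "GGATCCTTAAGGCCTTAAGGA" * 5
    return {"chr1": left[:100] + M1 + right[:100]}


@pytest.fixture
def toy_locus() -> MirnaLocus:
    return MirnaLocus(
        locus_id="M1", chrom="chr1", start=101, end=121, strand="+", kind="guide"
    )


@pytest.fixture(scope="session")
def small_sim():
    """A small simulated reference plus one wild-type replicate, reused widely."""
    config = SimConfig(
        seed=42,
        n_mirnas=6,
        genome_len=8_000,
        n_background_reads=100,
        reads_per_mirna=400.0,
        n_replicates=3,
    )
    reference = simulate_reference(config)
    table, truth = simulate_library(config, reference, "wt", "rep1")
    return config, reference, table, truth


def write_fasta(path, sequences: dict[str, str]) -> None:
    with open(path, "w") as out:
        for name, seq in sequences.items():
            out.write(f">{name}\n{seq}\n")


def write_fastq_plain(path, reads: list[str]) -> None:
    with open(path, "w") as out:
        for i, seq in enumerate(reads):
            out.write(f"@r{i}\n{seq}\n+\n{'I' * len(seq)}\n")
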