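"""Read intake: collapse adapter-trimmed FASTQ to unique-sequence counts and
drop everything that still matches the masked genome.

Reads that map perfectly (either strand, zero mismatches) to the masked
genome are ordinary genomic small RNAs; reads that fail to map can only come
from the masked miRNA loci and are therefore unaltered, 3'-trimmed and/or
3'-tailed miRNA molecules, which the classifier sorts out downstream.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from ._seq import canonicalize, is_dna
from .refs import MaskedGenome

logger = logging.getLogger(__name__)


@dataclass
class SeqCountTable:
    """Unique read sequence -> count for one sequencing library."""

    sample_id: str
    replicate_id: str
    counts: dict[str, int] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"sequence": list(self.counts), "count": list(self.counts.values())}
        )
        return df.sort_values(["count", "sequence"], ascending=[False, True]).reset_index(
            drop=True
        )

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_frame(
        cls, df: pd.DataFrame, sample_id: str = "", replicate_id: str = ""
    ) -> "SeqCountTable":
        counts = {
            canonicalize(str(s)): int(c) for s, c in zip(df["sequence"], df["count"])
        }
        return cls(sample_id=sample_id, replicate_id=replicate_id, counts=counts)


def _open_text(path: str | Path):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def dedupe_reads(
    fastq: str | Path,
    sample_id: str = "",
    replicate_id: str = "",
    min_len: int = 18,
    max_len: int = 32,
) -> SeqCountTable:
    """Collapse a FASTQ into unique-sequence counts within a length window.

    Reads outside [min_len, max_len] and reads containing non-ACGT
    characters (ambiguity codes cannot be classified) are counted, logged
    and discarded.  Gzip input is handled transparently.  A malformed FASTQ
    record raises with the record number.
    """
    counts: dict[str, int] = {}
    n_len_filtered = 0
    n_bad_alpha = 0
    record_no = 0
    with _open_text(fastq) as fh:
        iterator = FastqGeneralIterator(fh)
        while True:
            try:
                _title, seq, _qual = next(iterator)
            except StopIteration:
                break
            except ValueError as exc:
                raise ValueError(
                    f"{fastq}: malformed FASTQ near record {record_no + 1}: {exc}"
                ) from exc
            record_no += 1
            seq = canonicalize(seq)
            if not min_len <= len(seq) <= max_len:
                n_len_filtered += 1
                continue
            if not is_dna(seq):
                n_bad_alpha += 1
                continue
            counts[seq] = counts.get(seq, 0) + 1
    if n_len_filtered or n_bad_alpha:
        logger.info(
            "%s: dropped %d reads outside %d-%d nt and %d with non-ACGT bases",
            fastq,
            n_len_filtered,
            min_len,
            max_len,
            n_bad_alpha,
        )
    table = SeqCountTable(sample_id=sample_id, replicate_id=replicate_id, counts=counts)
    logger.info(
        "%s: %d reads -> %d unique sequences (total kept %d)",
        fastq,
        record_no,
        len(counts),
        table.total,
    )
    return table


def filter_genome_matching(
    table: SeqCountTable, masked: MaskedGenome
) -> tuple[SeqCountTable, SeqCountTable]:
    """Split a count table into (retained, removed) by masked-genome matching.

    A sequence is removed iff it occurs exactly (forward or
    reverse-complement) anywhere in the masked genome.  The two outputs
    partition the input, so retained.total + removed.total == table.total.
    """
    from ._seq import find_in_genome

    retained = SeqCountTable(table.sample_id, table.replicate_id)
    removed = SeqCountTable(table.sample_id, table.replicate_id)
    for seq, count in table.counts.items():
        if find_in_genome(seq, masked.sequences) is None:
            retained.counts[seq] = count
        else:
            removed.counts[seq] = count
    logger.info(
        "%s/%s: genome filter removed %d unique sequences (%d reads), kept %d (%d reads)",
        table.sample_id,
        table.replicate_id,
        len(removed.counts),
        removed.total,
        len(retained.counts),
        retained.total,
    )
    return retained, removed
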