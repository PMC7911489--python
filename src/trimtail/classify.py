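"""5'-anchored classification of small RNA reads as 3' trimmed/tailed isomiRs.

A read is compared against each mature reference with its 5' end fixed: the
read must reproduce the reference prefix exactly, may stop short of the
reference 3' end by up to ``max_trim`` bases (trimming), and may carry up to
``max_tail`` extra 3' bases that do not match the reference (tailing).
Tailing is operationally "any nucleotide not matching the miRNA", so the
decomposition is canonical: the matched prefix is maximal, which makes the
(trim, tail) pair the minimal-modification explanation for that reference.
A tail base that coincidentally continues the reference is absorbed into
the match.

Across references the minimal total modification wins; an exact tie between
distinct references is reported as ``ambiguous`` and excluded from index
statistics rather than double-counted.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from ._seq import is_dna
from .intake import SeqCountTable
from .refs import MatureRef

logger = logging.getLogger(__name__)

UNALTERED = "unaltered"
TRIMMED = "trimmed"
TAILED = "tailed"
TRIMMED_TAILED = "trimmed_tailed"
AMBIGUOUS = "ambiguous"
UNCLASSIFIED = "unclassified"

CATEGORIES = (UNALTERED, TRIMMED, TAILED, TRIMMED_TAILED, AMBIGUOUS, UNCLASSIFIED)


@dataclass(frozen=True)
class ModRecord:
    """Classification of one unique read sequence."""

    sequence: str
    count: int
    ref_id: str | None
    trim_len: int
    tail_seq: str
    category: str


def _category(trim_len: int, tail_len: int) -> str:
    if trim_len == 0 and tail_len == 0:
        return UNALTERED
    if trim_len > 0 and tail_len == 0:
        return TRIMMED
    if trim_len == 0:
        return TAILED
    return TRIMMED_TAILED


def _lcp(a: str, b: str) -> int:
    n = min(len(a), len(b))
    for i in range(n):
        if a[i] != b[i]:
            return i
    return n


def classify_read(
    seq: str,
    refs: list[MatureRef],
    max_trim: int = 7,
    max_tail: int = 7,
    count: int = 1,
) -> ModRecord:
    """Classify one sequence against the mature references.

    For each reference the canonical decomposition takes the maximal
    matching prefix p, giving trim = len(ref) - p and tail = seq[p:]; it is
    compatible iff trim <= max_trim and len(tail) <= max_tail.  The
    compatible reference with the smallest trim + tail is assigned; an exact
    tie between distinct references yields ``ambiguous`` and no compatible
    reference yields ``unclassified``.
    """
    if not is_dna(seq):
        raise ValueError(f"read contains non-ACGT characters: {seq!r}")
    best: tuple[int, MatureRef, int, str] | None = None
    tie = False
    for ref in refs:
        p = _lcp(seq, ref.sequence)
        trim = len(ref.sequence) - p
        tail = seq[p:]
        if trim > max_trim or len(tail) > max_tail:
            continue
        score = trim + len(tail)
        if best is None or score < best[0]:
            best = (score, ref, trim, tail)
            tie = False
        elif score == best[0]:
            tie = True
    if best is None:
        return ModRecord(seq, count, None, 0, "", UNCLASSIFIED)
    if tie:
        return ModRecord(seq, count, None, 0, "", AMBIGUOUS)
    _score, ref, trim, tail = best
    return ModRecord(seq, count, ref.ref_id, trim, tail, _category(trim, len(tail)))


def classify_table(
    table: SeqCountTable,
    refs: list[MatureRef],
    max_trim: int = 7,
    max_tail: int = 7,
) -> list[ModRecord]:
    """Classify every unique sequence in a count table, carrying counts through."""
    if not refs:
        raise ValueError("refs must be non-empty")
    records = [
        classify_read(seq, refs, max_trim=max_trim, max_tail=max_tail, count=count)
        for seq, count in table.counts.items()
    ]
    totals = Counter()
    for rec in records:
        totals[rec.category] += rec.count
    logger.info(
        "%s/%s: classified %d unique sequences: %s",
        table.sample_id,
        table.replicate_id,
        len(records),
        dict(totals),
    )
    return records


def records_to_frame(records: list[ModRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sequence": [r.sequence for r in records],
            "count": [r.count for r in records],
            "ref_id": [r.ref_id if r.ref_id is not None else "" for r in records],
            "trim_len": [r.trim_len for r in records],
            "tail_seq": [r.tail_seq for r in records],
            "category": [r.category for r in records],
        }
    )


def write_records_tsv(records: list[ModRecord], path: str | Path) -> None:
    records_to_frame(records).to_csv(path, sep="\t", index=False)
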