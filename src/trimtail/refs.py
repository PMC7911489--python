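"""Reference preparation for miRNA trimming/tailing analysis.

Loads a genome and a GFF3 annotation of mature miRNA coordinates (feature
type ``miRNA``, guide and star strands annotated separately, as in
Araport11), extracts the mature sequences strand-aware, collapses family
members with byte-identical mature sequences into one reference, masks the
mature loci in the genome with N, and flags references whose exact sequence
still occurs elsewhere in the masked genome (on either strand).  Reads from
such cross-mapping miRNAs are lost to the masked-genome filter, so these
references are excluded from downstream index statistics.

Coordinates are GFF3 1-based inclusive at the API boundary and in all
reports; slicing is 0-based half-open internally.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from pyfaidx import Fasta

from ._seq import canonicalize, find_in_genome, is_dna, revcomp

logger = logging.getLogger(__name__)

GUIDE = "guide"
STAR = "star"


@dataclass(frozen=True)
class MirnaLocus:
    """One annotated mature miRNA (guide or star) on the genome."""

    locus_id: str
    chrom: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    strand: str
    kind: str

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.locus_id}: start {self.start} > end {self.end}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.locus_id}: bad strand {self.strand!r}")
        if self.kind not in (GUIDE, STAR):
            raise ValueError(f"{self.locus_id}: kind must be guide or star")
        length = self.end - self.start + 1
        if not 18 <= length <= 26:
            raise ValueError(
                f"{self.locus_id}: mature length {length} outside 18-26 nt"
            )


@dataclass(frozen=True)
class MatureRef:
    """One collapsed mature reference: all loci sharing an identical sequence.

    ``ref_id`` joins the member identifiers with "/" so a family collapsed
    to one sequence reads e.g. ``miR165a/miR165b``.
    """

    ref_id: str
    sequence: str
    kind: str
    member_loci: tuple[MirnaLocus, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not is_dna(self.sequence):
            raise ValueError(f"{self.ref_id}: sequence is not plain A/C/G/T DNA")


@dataclass
class MaskedGenome:
    """Genome with mature miRNA footprints replaced by N."""

    sequences: dict[str, str]
    masked_intervals: list[tuple[str, int, int]]  # 1-based inclusive

    def n_masked(self) -> int:
        return sum(seq.count("N") for seq in self.sequences.values())


def read_genome(path: str | Path) -> dict[str, str]:
    """Read a genome FASTA into a chrom -> uppercase-DNA map."""
    fa = Fasta(str(path), as_raw=True, sequence_always_upper=True, rebuild=False)
    return {name: canonicalize(str(fa[name][:])) for name in fa.keys()}


def _parse_gff_attributes(text: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for part in text.strip().split(";"):
        if not part:
            continue
        key, _, value = part.partition("=")
        out[key.strip()] = value.strip()
    return out


def _kind_from_name(name: str) -> str:
    low = name.lower()
    if name.endswith("*") or low.endswith("-star") or low.endswith("_star"):
        return STAR
    return GUIDE


def read_mirna_loci(annotation: str | Path) -> list[MirnaLocus]:
    """Read GFF3 records of feature type ``miRNA`` into loci.

    Guide/star labels come from a ``kind=`` attribute when present,
    otherwise from the identifier suffix ("*" / "-star" marks the star
    strand).  Records with other feature types are skipped, with a count
    logged.
    """
    loci: list[MirnaLocus] = []
    skipped = 0
    with open(annotation) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(f"{annotation}: malformed GFF3 line {lineno}")
            chrom, _, ftype, start, end, _, strand, _, attrs = fields
            if ftype != "miRNA":
                skipped += 1
                continue
            att = _parse_gff_attributes(attrs)
            locus_id = att.get("Name") or att.get("ID") or f"miRNA_{lineno}"
            kind = att.get("kind", "").lower() or _kind_from_name(locus_id)
            loci.append(
                MirnaLocus(
                    locus_id=locus_id,
                    chrom=chrom,
                    start=int(start),
                    end=int(end),
                    strand=strand,
                    kind=kind,
                )
            )
    if skipped:
        logger.info("ignored %d non-miRNA feature records", skipped)
    return loci


def extract_sequence(genome: dict[str, str], locus: MirnaLocus) -> str:
    """Strand-aware extraction of a locus sequence (reverse-complemented on -)."""
    if locus.chrom not in genome:
        raise ValueError(f"{locus.locus_id}: chromosome {locus.chrom!r} not in genome")
    chrom_seq = genome[locus.chrom]
    if locus.end > len(chrom_seq) or locus.start < 1:
        raise ValueError(
            f"{locus.locus_id}: coordinates {locus.start}-{locus.end} outside "
            f"{locus.chrom} (length {len(chrom_seq)})"
        )
    seq = chrom_seq[locus.start - 1 : locus.end]
    return revcomp(seq) if locus.strand == "-" else seq


def load_mature_refs(
    genome: str | Path | dict[str, str],
    annotation: str | Path,
    mature_fasta: str | Path | None = None,
) -> list[MatureRef]:
    """Extract mature sequences and collapse identical ones into references.

    Every locus whose extracted sequence is byte-identical to another's is
    collapsed into a single :class:`MatureRef`; the collapsed reference keeps
    all member loci and a joined identifier.  If ``mature_fasta`` (a
    miRBase-style file, RNA alphabet allowed) is supplied, its sequences are
    cross-checked against the genome extraction per identifier and every
    disagreement is logged — the annotation-derived sequence is kept, the
    conflict is never resolved silently.
    """
    if not isinstance(genome, dict):
        genome = read_genome(genome)
    loci = read_mirna_loci(annotation)

    by_seq: dict[str, list[MirnaLocus]] = {}
    extracted: dict[str, str] = {}
    for locus in loci:
        seq = extract_sequence(genome, locus)
        by_seq.setdefault(seq, []).append(locus)
        extracted[locus.locus_id] = seq

    if mature_fasta is not None:
        from Bio import SeqIO

        mismatches = 0
        for record in SeqIO.parse(str(mature_fasta), "fasta"):
            name = record.id
            seq = canonicalize(str(record.seq))
            if name in extracted and extracted[name] != seq:
                mismatches += 1
                logger.warning(
                    "mature sequence conflict for %s: annotation-derived %s "
                    "vs supplied %s",
                    name,
                    extracted[name],
                    seq,
                )
        if mismatches:
            logger.warning(
                "%d mature sequences disagree with the genome extraction", mismatches
            )

    refs: list[MatureRef] = []
    for seq, members in by_seq.items():
        kinds = {m.kind for m in members}
        if len(kinds) > 1:
            names = ", ".join(m.locus_id for m in members)
            raise ValueError(
                f"identical mature sequence labeled both guide and star: {names}"
            )
        ref_id = "/".join(sorted(m.locus_id for m in members))
        refs.append(
            MatureRef(
                ref_id=ref_id,
                sequence=seq,
                kind=members[0].kind,
                member_loci=tuple(members),
            )
        )
    refs.sort(key=lambda r: r.ref_id)
    logger.info("collapsed %d loci into %d mature references", len(loci), len(refs))
    return refs


def mask_genome(
    genome: str | Path | dict[str, str],
    loci: list[MirnaLocus] | list[tuple[str, int, int]],
) -> MaskedGenome:
    """Replace the union of the loci footprints with N; nothing else changes.

    ``loci`` may be :class:`MirnaLocus` objects or bare 1-based inclusive
    ``(chrom, start, end)`` tuples.  Overlapping loci are allowed (the union
    is masked once).  A locus extending past its chromosome end is a hard
    error.
    """
    if not isinstance(genome, dict):
        genome = read_genome(genome)
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for locus in loci:
        if isinstance(locus, tuple):
            chrom, start, end = locus
            name = f"{chrom}:{start}-{end}"
        else:
            chrom, start, end, name = locus.chrom, locus.start, locus.end, locus.locus_id
        if chrom not in genome:
            raise ValueError(f"{name}: chromosome {chrom!r} not in genome")
        if end > len(genome[chrom]) or start < 1:
            raise ValueError(
                f"{name}: interval {start}-{end} beyond chromosome "
                f"{chrom} (length {len(genome[chrom])})"
            )
        by_chrom.setdefault(chrom, []).append((start, end))

    sequences = dict(genome)
    intervals: list[tuple[str, int, int]] = []
    for chrom, spans in by_chrom.items():
        spans.sort()
        merged: list[list[int]] = []
        for start, end in spans:
            if merged and start <= merged[-1][1] + 1:
                merged[-1][1] = max(merged[-1][1], end)
            else:
                merged.append([start, end])
        text = sequences[chrom]
        for start, end in merged:
            text = text[: start - 1] + "N" * (end - start + 1) + text[end:]
            intervals.append((chrom, start, end))
        sequences[chrom] = text
    return MaskedGenome(sequences=sequences, masked_intervals=intervals)


def find_cross_mapping(
    refs: list[MatureRef], masked: MaskedGenome
) -> tuple[list[MatureRef], list[MatureRef], pd.DataFrame]:
    """Partition references into cross-mapping (excluded) and clean (retained).

    A reference is excluded iff its exact sequence, forward or
    reverse-complement, still occurs anywhere in the masked genome — i.e. a
    perfect copy exists outside the masked miRNA loci, so its reads would be
    absorbed by the genome filter.  Returns (excluded, retained, report)
    where the report has one row per excluded reference with one match
    coordinate (1-based).
    """
    if not refs:
        raise ValueError("refs must be non-empty")
    excluded: list[MatureRef] = []
    retained: list[MatureRef] = []
    rows = []
    for ref in refs:
        hit = find_in_genome(ref.sequence, masked.sequences)
        if hit is None:
            retained.append(ref)
        else:
            excluded.append(ref)
            chrom, pos, strand = hit
            rows.append(
                {
                    "ref_id": ref.ref_id,
                    "kind": ref.kind,
                    "sequence": ref.sequence,
                    "match_chrom": chrom,
                    "match_pos": pos,
                    "match_strand": strand,
                }
            )
    report = pd.DataFrame(
        rows,
        columns=["ref_id", "kind", "sequence", "match_chrom", "match_pos", "match_strand"],
    )
    if excluded:
        logger.info(
            "excluding %d cross-mapping references (%d guide, %d star)",
            len(excluded),
            sum(r.kind == GUIDE for r in excluded),
            sum(r.kind == STAR for r in excluded),
        )
    return excluded, retained, report


def write_masked_fasta(masked: MaskedGenome, path: str | Path, width: int = 70) -> None:
    with open(path, "w") as out:
        for chrom in sorted(masked.sequences):
            out.write(f">{chrom}\n")
            seq = masked.sequences[chrom]
            for i in range(0, len(seq), width):
                out.write(seq[i : i + width] + "\n")
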