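"""Low-level sequence helpers shared across modules.

All sequences are canonicalized to uppercase DNA (U -> T) as soon as they
enter the package; downstream code may assume the A/C/G/T alphabet (plus N
inside masked genomes).
"""

from __future__ import annotations

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_DNA_OK = frozenset("ACGT")


def canonicalize(seq: str) -> str:
    """Uppercase and convert RNA U to DNA T."""
    return seq.upper().replace("U", "T")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def is_dna(seq: str) -> bool:
    return bool(seq) and set(seq) <= _DNA_OK


def find_in_genome(seq: str, sequences: dict[str, str]) -> tuple[str, int, str] | None:
    """Exact-match search of ``seq`` (both strands) over a chrom -> sequence map.

    Returns (chrom, 1-based position of the match start on the forward
    strand, strand) for the first hit found, or None. An N anywhere in the
    genome window defeats the match, so masked loci never fire.
    """
    rc = revcomp(seq)
    for chrom in sorted(sequences):
        text = sequences[chrom]
        pos = text.find(seq)
        if pos != -1:
            return chrom, pos + 1, "+"
        pos = text.find(rc)
        if pos != -1:
            return chrom, pos + 1, "-"
    return None
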