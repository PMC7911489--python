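"""Synthetic sRNA-seq data with known 3' trimming/tailing parameters.

The generator emulates the statistical structure the trimming/tailing
analysis assumes: replicated short-read libraries whose miRNA-derived reads
are exact, 3'-truncated and/or 3'-tailed copies of mature references, at
per-line modification rates (pi_t, pi_u) that the indexes estimate, mixed
with genomic background reads that the masked-genome filter must remove.

Guarantees engineered into the reference (by rejection sampling):

* no two mature sequences share their first ``len - 7`` bases, so no read
  derived from one reference can be compatible with another (classification
  is never ambiguous for simulated reads);
* every mature's ``len - 7`` 5' prefix is absent (both strands) from the
  masked genome, so every miRNA-derived read with trim <= 7 fails the
  genome filter and is retained, and no reference cross-maps.

Everything is deterministic under the configured seed.
"""

from __future__ import annotations

import gzip
import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from ._seq import find_in_genome, revcomp
from .intake import SeqCountTable
from .refs import GUIDE, STAR, MaskedGenome, MatureRef, MirnaLocus, mask_genome

_BASES = np.array(list("ACGT"))
_MAX_MOD = 7  # positions of trimming/tailing evaluated downstream


def _normalized_composition(comp: dict[str, float]) -> tuple[np.ndarray, list[str]]:
    bases = ["A", "C", "G", "T"]
    probs = np.array([comp.get(b, 0.0) for b in bases], dtype=float)
    if probs.sum() <= 0:
        raise ValueError("tail composition must have positive mass")
    return probs / probs.sum(), bases


@dataclass(frozen=True)
class LineParams:
    """Modification parameters of one genetic line.

    ``trim_prob``/``tail_prob`` are the per-read probabilities of any 3'
    truncation / nontemplated addition; lengths follow a geometric
    distribution (success probability ``trim_len_p``/``tail_len_p``)
    truncated at 7 positions.  The default tail composition is U-rich
    (T after DNA canonicalization), reflecting uridylation by HESO1/URT1.
    With ``collision_free`` the first tail base of a trimmed-and-tailed read
    is forced to differ from the reference base it replaces, so the
    generated (trim, tail) decomposition is exactly recoverable.
    ``replicate_jitter`` > 0 adds beta-distributed per-replicate wobble to
    the probabilities (concentration parameter; 0 disables).
    """

    trim_prob: float = 0.10
    tail_prob: float = 0.10
    trim_len_p: float = 0.5
    tail_len_p: float = 0.5
    tail_composition: tuple[tuple[str, float], ...] = (
        ("T", 0.8),
        ("A", 0.0667),
        ("C", 0.0667),
        ("G", 0.0667),
    )
    collision_free: bool = True
    replicate_jitter: float = 0.0

    def __post_init__(self) -> None:
        for p in (self.trim_prob, self.tail_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("modification probabilities must be in [0, 1]")


@dataclass(frozen=True)
class SimConfig:
    """Study design: reference layout, depth, replication and line parameters.

    ``reads_per_mirna`` is the expected depth of each mature reference
    (guide and star alike); per-reference abundance varies around it with a
    log-normal weight (mean 1, sigma ``abundance_sigma``) that is a fixed
    property of each line.
    """

    seed: int = 0
    n_mirnas: int = 20
    mirna_len_range: tuple[int, int] = (20, 22)
    genome_len: int = 50_000
    n_background_reads: int = 1_000
    n_replicates: int = 3
    reads_per_mirna: float = 2_000.0
    abundance_sigma: float = 1.0
    params: LineParams = field(default_factory=LineParams)

    def __post_init__(self) -> None:
        if self.genome_len < self.n_mirnas * 60:
            raise ValueError("genome_len must be at least n_mirnas * 60")
        lo, hi = self.mirna_len_range
        if not 18 <= lo <= hi <= 26:
            raise ValueError("mirna_len_range must lie within 18-26 nt")


@dataclass
class SimReference:
    """A simulated genome with planted MIR loci (one guide + one star each)."""

    config: SimConfig
    genome: dict[str, str]
    loci: list[MirnaLocus]
    refs: list[MatureRef]
    masked: MaskedGenome

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        genome_fa = outdir / "genome.fa"
        with open(genome_fa, "w") as out:
            for chrom in sorted(self.genome):
                out.write(f">{chrom}\n")
                seq = self.genome[chrom]
                for i in range(0, len(seq), 70):
                    out.write(seq[i : i + 70] + "\n")
        gff = outdir / "annotation.gff3"
        with open(gff, "w") as out:
            out.write("##gff-version 3\n")
            for locus in self.loci:
                attrs = f"ID={locus.locus_id};Name={locus.locus_id};kind={locus.kind}"
                out.write(
                    f"{locus.chrom}\ttrimtail_sim\tmiRNA\t{locus.start}\t{locus.end}"
                    f"\t.\t{locus.strand}\t.\t{attrs}\n"
                )
        mature_fa = outdir / "mature.fa"
        with open(mature_fa, "w") as out:
            for ref in self.refs:
                out.write(f">{ref.ref_id}\n{ref.sequence}\n")
        return {"genome": genome_fa, "annotation": gff, "mature": mature_fa}


@dataclass
class SimTruth:
    """Ground truth of one simulated library."""

    line_id: str
    replicate_id: str
    params: pd.DataFrame  # ref_id, pi_t, pi_u (configured, pre-jitter)
    reads: pd.DataFrame  # ref_id, trim_len, tail_seq, count
    realized: pd.DataFrame  # ref_id, total, n_trimmed, n_tailed
    n_background: int

    def write(self, path: str | Path) -> None:
        df = self.reads.copy()
        df.insert(0, "replicate_id", self.replicate_id)
        df.insert(0, "line_id", self.line_id)
        df.to_csv(path, sep="\t", index=False)


def _rng(*entropy: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([e & 0x7FFFFFFF for e in entropy]))


def _tag(text: str) -> int:
    return zlib.crc32(text.encode())


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=length)])


def _truncated_geometric(
    rng: np.random.Generator, p: float, size: int, kmax: int = _MAX_MOD
) -> np.ndarray:
    """Geometric(p) lengths (support 1..kmax), truncated by inverse CDF."""
    if size == 0:
        return np.zeros(0, dtype=int)
    u = rng.random(size)
    tail_mass = 1.0 - (1.0 - p) ** kmax
    k = np.ceil(np.log1p(-u * tail_mass) / np.log(1.0 - p)).astype(int)
    return np.clip(k, 1, kmax)


def simulate_reference(config: SimConfig, max_attempts: int = 50) -> SimReference:
    """Build a random genome with ``n_mirnas`` planted MIR loci.

    Each locus contributes a guide and a star mature on a random strand.
    Rejection sampling enforces the uniqueness guarantees described in the
    module docstring; if they cannot be met in ``max_attempts`` fresh draws
    the genome is too small and an error says so.
    """
    lo, hi = config.mirna_len_range
    for attempt in range(max_attempts):
        rng = _rng(config.seed, 910_001, attempt)
        genome_arr = _BASES[rng.integers(0, 4, size=config.genome_len)]
        matures: list[str] = []
        prefixes: set[str] = set()
        ok = True
        for _ in range(config.n_mirnas * 2):
            for _draw in range(200):
                seq = _random_seq(rng, int(rng.integers(lo, hi + 1)))
                prefix = seq[: len(seq) - _MAX_MOD]
                if any(prefix.startswith(q[: len(prefix)]) or q.startswith(prefix)
                       for q in prefixes):
                    continue
                if any(
                    len(seq) == len(m)
                    and sum(a != b for a, b in zip(seq, m)) <= 2
                    for m in matures
                ):
                    continue
                matures.append(seq)
                prefixes.add(prefix)
                break
            else:
                ok = False
                break
        if not ok:
            continue

        if config.n_mirnas == 0:
            genome = {"chr1": "".join(genome_arr)}
            return SimReference(config, genome, [], [], mask_genome(genome, []))

        spacing = config.genome_len // config.n_mirnas
        loci: list[MirnaLocus] = []
        refs: list[MatureRef] = []
        genome_list = genome_arr.tolist()
        for i in range(config.n_mirnas):
            guide_seq = matures[2 * i]
            star_seq = matures[2 * i + 1]
            strand = "+" if rng.random() < 0.5 else "-"
            base = i * spacing + int(rng.integers(0, max(1, spacing - 60)))
            cursor = base
            for seq, kind, name in (
                (guide_seq, GUIDE, f"miR{i + 1:03d}"),
                (star_seq, STAR, f"miR{i + 1:03d}-star"),
            ):
                planted = seq if strand == "+" else revcomp(seq)
                genome_list[cursor : cursor + len(seq)] = list(planted)
                locus = MirnaLocus(
                    locus_id=name,
                    chrom="chr1",
                    start=cursor + 1,
                    end=cursor + len(seq),
                    strand=strand,
                    kind=kind,
                )
                loci.append(locus)
                refs.append(
                    MatureRef(ref_id=name, sequence=seq, kind=kind, member_loci=(locus,))
                )
                cursor += len(seq) + 3
        genome = {"chr1": "".join(genome_list)}
        masked = mask_genome(genome, loci)

        clean = all(
            find_in_genome(ref.sequence[: len(ref.sequence) - _MAX_MOD], masked.sequences)
            is None
            for ref in refs
        )
        if clean:
            return SimReference(config, genome, loci, refs, masked)
    raise RuntimeError(
        "could not place cross-mapping-free miRNA loci; increase genome_len"
    )


def _effective_probs(
    rng: np.random.Generator, params: LineParams, n_refs: int
) -> tuple[np.ndarray, np.ndarray]:
    pi_t = np.full(n_refs, params.trim_prob)
    pi_u = np.full(n_refs, params.tail_prob)
    if params.replicate_jitter > 0:
        kappa = params.replicate_jitter
        pi_t = np.array(
            [rng.beta(max(p * kappa, 1e-9), max((1 - p) * kappa, 1e-9)) if 0 < p < 1 else p
             for p in pi_t]
        )
        pi_u = np.array(
            [rng.beta(max(p * kappa, 1e-9), max((1 - p) * kappa, 1e-9)) if 0 < p < 1 else p
             for p in pi_u]
        )
    return pi_t, pi_u


def simulate_library(
    config: SimConfig,
    reference: SimReference,
    line_id: str,
    replicate_id: str,
    params: LineParams | None = None,
) -> tuple[SeqCountTable, SimTruth]:
    """One replicate library: miRNA-derived reads plus genomic background.

    Per-reference abundance weights are drawn once per line (deterministic
    in seed and line_id), so replicates of a line share expected depths;
    read counts are Poisson around them.  Returns the deduplicated count
    table and the ground truth.
    """
    params = params or config.params
    refs = reference.refs
    comp, comp_bases = _normalized_composition(dict(params.tail_composition))

    ab_rng = _rng(config.seed, _tag(line_id), 1)
    sigma = config.abundance_sigma
    weights = ab_rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=len(refs))

    rng = _rng(config.seed, _tag(line_id), _tag(replicate_id), 2)
    pi_t_eff, pi_u_eff = _effective_probs(rng, params, len(refs))

    counts: dict[str, int] = {}
    truth_rows: list[tuple[str, int, str, int]] = []
    realized_rows = []
    base_index = {b: i for i, b in enumerate(comp_bases)}

    for j, ref in enumerate(refs):
        n = int(rng.poisson(config.reads_per_mirna * weights[j]))
        if n == 0:
            continue
        ref_seq = ref.sequence
        L = len(ref_seq)
        trim_flag = rng.random(n) < pi_t_eff[j]
        tail_flag = rng.random(n) < pi_u_eff[j]
        trims = np.zeros(n, dtype=int)
        trims[trim_flag] = _truncated_geometric(rng, params.trim_len_p, int(trim_flag.sum()))
        tail_lens = np.zeros(n, dtype=int)
        tail_lens[tail_flag] = _truncated_geometric(
            rng, params.tail_len_p, int(tail_flag.sum())
        )
        flat = rng.choice(len(comp_bases), size=int(tail_lens.sum()), p=comp)
        per_read: dict[tuple[int, str], int] = {}
        pos = 0
        for t, u in zip(trims, tail_lens):
            tail = ""
            if u:
                picks = flat[pos : pos + u]
                pos += u
                tail = "".join(comp_bases[k] for k in picks)
                if params.collision_free and t >= 1:
                    forbidden = ref_seq[L - t]
                    while tail[0] == forbidden:
                        # conditional redraw of the first tail base
                        alt = comp.copy()
                        alt[base_index[forbidden]] = 0.0
                        alt /= alt.sum()
                        tail = comp_bases[rng.choice(len(comp_bases), p=alt)] + tail[1:]
            key = (int(t), tail)
            per_read[key] = per_read.get(key, 0) + 1
        n_trimmed = 0
        n_tailed = 0
        for (t, tail), c in sorted(per_read.items()):
            seq = ref_seq[: L - t] + tail
            counts[seq] = counts.get(seq, 0) + c
            truth_rows.append((ref.ref_id, t, tail, c))
            if t >= 1:
                n_trimmed += c
            if tail:
                n_tailed += c
        realized_rows.append(
            {
                "ref_id": ref.ref_id,
                "total": n,
                "n_trimmed": n_trimmed,
                "n_tailed": n_tailed,
            }
        )

    chrom = next(iter(reference.masked.sequences))
    text = reference.masked.sequences[chrom]
    n_bg = 0
    guard = 0
    while n_bg < config.n_background_reads:
        guard += 1
        if guard > config.n_background_reads * 100 + 1000:
            raise RuntimeError("cannot sample background reads clear of masked loci")
        length = int(rng.integers(20, 25))
        start = int(rng.integers(0, len(text) - length))
        window = text[start : start + length]
        if "N" in window:
            continue
        seq = window if rng.random() < 0.5 else revcomp(window)
        counts[seq] = counts.get(seq, 0) + 1
        n_bg += 1

    table = SeqCountTable(sample_id=line_id, replicate_id=replicate_id, counts=counts)
    truth = SimTruth(
        line_id=line_id,
        replicate_id=replicate_id,
        params=pd.DataFrame(
            {
                "ref_id": [r.ref_id for r in refs],
                "pi_t": params.trim_prob,
                "pi_u": params.tail_prob,
            }
        ),
        reads=pd.DataFrame(
            truth_rows, columns=["ref_id", "trim_len", "tail_seq", "count"]
        ),
        realized=pd.DataFrame(
            realized_rows, columns=["ref_id", "total", "n_trimmed", "n_tailed"]
        ),
        n_background=n_bg,
    )
    return table, truth


def write_fastq(table: SeqCountTable, path: str | Path) -> None:
    """Expand a count table into FASTQ (dummy quality 'I'; gzip by extension)."""
    path = str(path)
    opener = gzip.open if path.endswith(".gz") else open
    i = 0
    with opener(path, "wt") as out:
        for seq, count in table.counts.items():
            for _ in range(count):
                i += 1
                out.write(f"@read_{i}\n{seq}\n+\n{'I' * len(seq)}\n")


def simulate_line(
    config: SimConfig,
    reference: SimReference,
    line_id: str,
    params: LineParams | None = None,
) -> list[tuple[SeqCountTable, SimTruth]]:
    """All replicates of one line, in memory."""
    return [
        simulate_library(config, reference, line_id, f"rep{r + 1}", params=params)
        for r in range(config.n_replicates)
    ]


def elevated(params: LineParams, d_trim: float = 0.0, d_tail: float = 0.0) -> LineParams:
    """A copy of ``params`` with shifted modification probabilities."""
    return replace(
        params,
        trim_prob=min(1.0, max(0.0, params.trim_prob + d_trim)),
        tail_prob=min(1.0, max(0.0, params.tail_prob + d_tail)),
    )
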