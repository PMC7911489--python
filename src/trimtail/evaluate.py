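"""Validation experiments: oracle equivalence, recovery, type-I error, power.

These functions run the package against independent checks: a brute-force
enumeration re-deriving the classifier's answer, and simulations with known
modification rates whose indexes, false-positive rate and detection power
can be measured.  They back both the test suite and the reproduction script.
"""

from __future__ import annotations

import math

import numpy as np

from .classify import AMBIGUOUS, UNCLASSIFIED, classify_read, classify_table
from .intake import filter_genome_matching
from .refs import MatureRef
from .simulate import LineParams, SimConfig, elevated, simulate_library, simulate_reference
from .stats import (
    TAILING,
    TRIMMING,
    compute_indexes,
    index_differences,
    mean_indexes,
    paired_test,
)

_BASES = "ACGT"


def brute_force_classify(
    seq: str, refs: list[MatureRef], max_trim: int = 7, max_tail: int = 7
) -> tuple[str | None, int, str, str]:
    """Exhaustive enumeration of every (ref, trim, tail) decomposition.

    Independent re-derivation of the classifier contract: try every trim
    t <= max_trim against every reference, accept decompositions whose
    5' part matches the reference prefix exactly and whose implied tail is
    within max_tail, and keep the globally minimal t + u.  A minimum shared
    by two distinct references is ambiguous.  Returns
    (ref_id, trim, tail, category).
    """
    candidates: list[tuple[int, str, int, str]] = []
    for ref in refs:
        m = ref.sequence
        for t in range(0, max_trim + 1):
            if t > len(m):
                break
            u = len(seq) - (len(m) - t)
            if not 0 <= u <= max_tail:
                continue
            keep = len(m) - t
            if seq[:keep] != m[:keep]:
                continue
            candidates.append((t + u, ref.ref_id, t, seq[keep:]))
    if not candidates:
        return None, 0, "", UNCLASSIFIED
    best_score = min(c[0] for c in candidates)
    winners = {c[1] for c in candidates if c[0] == best_score}
    if len(winners) > 1:
        return None, 0, "", AMBIGUOUS
    score, ref_id, t, tail = min(c for c in candidates if c[0] == best_score)
    if t == 0 and not tail:
        category = "unaltered"
    elif t > 0 and not tail:
        category = "trimmed"
    elif t == 0:
        category = "tailed"
    else:
        category = "trimmed_tailed"
    return ref_id, t, tail, category


def _random_refs(rng: np.random.Generator, n_refs: int = 20) -> list[MatureRef]:
    """Random mature references, pairwise Hamming-separated (> 2 over the overlap)."""
    refs: list[MatureRef] = []
    while len(refs) < n_refs:
        length = int(rng.integers(20, 23))
        seq = "".join(_BASES[i] for i in rng.integers(0, 4, size=length))
        if all(
            sum(a != b for a, b in zip(seq, r.sequence)) > 2 for r in refs
        ):
            refs.append(MatureRef(ref_id=f"r{len(refs)}", sequence=seq, kind="guide"))
    return refs


def oracle_agreement(
    seed: int, n_reads: int = 1_000, n_refs: int = 20
) -> dict[str, float]:
    """Fraction of random reads on which classify_read matches brute force.

    Reads mix modified copies of the references (trims and tails drawn up to
    9, deliberately crossing the 7-position boundary) with fully random
    sequences, so both classifiable and unclassifiable inputs are probed.
    """
    rng = np.random.default_rng(seed)
    refs = _random_refs(rng, n_refs)
    n_agree = 0
    for _ in range(n_reads):
        if rng.random() < 0.8:
            ref = refs[rng.integers(0, len(refs))]
            t = int(rng.integers(0, 10))
            u = int(rng.integers(0, 10))
            tail = "".join(_BASES[i] for i in rng.integers(0, 4, size=u))
            seq = ref.sequence[: len(ref.sequence) - t] + tail
            if len(seq) < 1:
                seq = ref.sequence
        else:
            seq = "".join(_BASES[i] for i in rng.integers(0, 4, size=int(rng.integers(15, 30))))
        got = classify_read(seq, refs)
        want = brute_force_classify(seq, refs)
        if (got.ref_id, got.trim_len, got.tail_seq, got.category) == want:
            n_agree += 1
    return {"agreement": n_agree / n_reads, "n": n_reads}


def _line_mean_indexes(config: SimConfig, reference, line_id: str, params=None):
    """Simulate all replicates of a line and push them through the pipeline core."""
    tables = []
    totals = {}
    for r in range(config.n_replicates):
        replicate_id = f"rep{r + 1}"
        table, _truth = simulate_library(
            config, reference, line_id, replicate_id, params=params
        )
        retained, _removed = filter_genome_matching(table, reference.masked)
        records = classify_table(retained, reference.refs)
        idx = compute_indexes(records, line_id, replicate_id, refs=reference.refs)
        for row in idx.itertuples(index=False):
            totals.setdefault(row.ref_id, []).append(row.total)
        tables.append(idx)
    return mean_indexes(tables), totals


def parameter_recovery(
    seed: int,
    n_mirnas: int = 20,
    reads_per_mirna: float = 2_000.0,
    pi_t: float = 0.30,
    pi_u: float = 0.10,
) -> dict[str, float]:
    """Recover (pi_t, pi_u) from a simulated line; report errors and z-scores.

    The estimated index of each mature reference is compared with the
    simulated truth on the scale of its binomial standard error at the
    realized per-replicate depths: z = (estimate - pi) / se where
    se^2 = sum_r pi(1-pi)/n_r / R^2 for the unweighted mean over R replicates.
    """
    params = LineParams(trim_prob=pi_t, tail_prob=pi_u, collision_free=True)
    config = SimConfig(
        seed=seed,
        n_mirnas=n_mirnas,
        reads_per_mirna=reads_per_mirna,
        params=params,
    )
    reference = simulate_reference(config)
    means, totals = _line_mean_indexes(config, reference, "sim")
    abs_errors = {TRIMMING: [], TAILING: []}
    max_abs_z = 0.0
    n_within = 0
    n_checked = 0
    for row in means.itertuples(index=False):
        truth = pi_t if row.modification == TRIMMING else pi_u
        depths = totals[row.ref_id]
        se = math.sqrt(sum(truth * (1 - truth) / n for n in depths)) / len(depths)
        z = (row.mean_index - truth) / se
        max_abs_z = max(max_abs_z, abs(z))
        n_checked += 1
        n_within += abs(z) <= 3.0
        abs_errors[row.modification].append(abs(row.mean_index - truth))
    return {
        "mae_trimming": float(np.mean(abs_errors[TRIMMING])),
        "mae_tailing": float(np.mean(abs_errors[TAILING])),
        "max_abs_z": max_abs_z,
        "frac_within_3se": n_within / n_checked,
        "n": n_checked,
    }


def _small_config(seed: int, reads_per_mirna: float) -> SimConfig:
    return SimConfig(
        seed=seed,
        n_mirnas=8,
        genome_len=6_000,
        n_background_reads=0,
        reads_per_mirna=reads_per_mirna,
        n_replicates=3,
    )


def type_i_error(
    seed: int, n_sims: int = 200, reads_per_mirna: float = 150.0, alpha: float = 0.05
) -> dict[str, float]:
    """Paired-t rejection rate over simulated null line pairs.

    Both lines of every pair share the generator parameters exactly; only
    sampling noise differs, so every rejection at level ``alpha`` is a false
    positive.  Trimming and tailing tests are both counted.
    """
    config = _small_config(seed, reads_per_mirna)
    reference = simulate_reference(config)
    n_tests = 0
    n_reject = 0
    for s in range(n_sims):
        means_a, _ = _line_mean_indexes(config, reference, f"null{s}a")
        means_b, _ = _line_mean_indexes(config, reference, f"null{s}b")
        for modification in (TRIMMING, TAILING):
            res = paired_test(means_a, means_b, modification)
            if res.p_value is not None:
                n_tests += 1
                n_reject += res.p_value < alpha
    return {"rejection_rate": n_reject / n_tests, "n": n_tests}


def power_sign(
    seed: int,
    n_sims: int = 50,
    reads_per_mirna: float = 300.0,
    delta_trim: float = 0.15,
    p_threshold: float = 0.01,
    id_threshold: float = 0.10,
) -> dict[str, float]:
    """Detection rate for a mutant with elevated trimming.

    The mutant's per-read trimming probability sits ``delta_trim`` above the
    reference line's; a simulation counts as detected when the trimming
    paired-t p-value is below ``p_threshold`` AND the median trimming index
    difference exceeds ``id_threshold`` (right direction, sizeable effect).
    """
    config = _small_config(seed, reads_per_mirna)
    reference = simulate_reference(config)
    mutant_params = elevated(config.params, d_trim=delta_trim)
    n_detected = 0
    median_ids = []
    for s in range(n_sims):
        means_ref, _ = _line_mean_indexes(config, reference, f"ctl{s}")
        means_mut, _ = _line_mean_indexes(
            config, reference, f"mut{s}", params=mutant_params
        )
        res = paired_test(means_mut, means_ref, TRIMMING)
        ids = index_differences(means_mut, means_ref)
        median_id = float(ids[ids["modification"] == TRIMMING]["id_value"].median())
        median_ids.append(median_id)
        if res.p_value is not None and res.p_value < p_threshold and median_id > id_threshold:
            n_detected += 1
    return {
        "detection_rate": n_detected / n_sims,
        "median_trimming_id": float(np.median(median_ids)),
        "n": n_sims,
    }
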