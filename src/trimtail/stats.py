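"""Per-miRNA trimming/tailing indexes and differential statistics.

The trimming (tailing) index of a miRNA in one replicate is the fraction of
its classified reads that are trimmed (tailed) to any degree — each read
counts once regardless of how many bases were removed or added, and a read
that is both trimmed and tailed contributes to both indexes.  Per-line means
are taken over the replicates in which the index is defined (a miRNA with
zero classified reads in a replicate has no index there: 0/0 is not evidence
of zero modification).

A line is compared to its reference line with a paired t-test over the
per-miRNA mean-index pairs, one test per modification, and p-values are
Benjamini-Hochberg corrected within each modification across every test in
the run.
"""

from __future__ import annotations

import logging
import math
import sys
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .classify import ModRecord
from .refs import MatureRef

logger = logging.getLogger(__name__)

TRIMMING = "trimming"
TAILING = "tailing"
MODIFICATIONS = (TRIMMING, TAILING)

INDEX_COLUMNS = [
    "ref_id",
    "kind",
    "sample_id",
    "replicate_id",
    "total",
    "trimming_index",
    "tailing_index",
]


@dataclass
class TestResult:
    """Paired-t comparison of one line against its reference line."""

    __test__ = False  # not a pytest collectable despite the name

    line_id: str
    reference_line_id: str
    modification: str
    n_pairs: int
    t_stat: float | None
    p_value: float | None
    q_value: float | None = None
    note: str = ""


def compute_indexes(
    records: list[ModRecord],
    sample_id: str,
    replicate_id: str,
    refs: list[MatureRef] | None = None,
) -> pd.DataFrame:
    """Per-miRNA totals and trimming/tailing indexes for one replicate.

    Ambiguous and unclassified records are excluded.  One row per reference
    with at least one classified read; a reference absent from the table has
    undefined indexes in this replicate.
    """
    kind_of = {r.ref_id: r.kind for r in refs} if refs else {}
    acc: dict[str, list[int]] = {}  # ref_id -> [total, trimmed, tailed]
    for rec in records:
        if rec.ref_id is None:
            continue
        row = acc.setdefault(rec.ref_id, [0, 0, 0])
        row[0] += rec.count
        if rec.trim_len >= 1:
            row[1] += rec.count
        if rec.tail_seq:
            row[2] += rec.count
    rows = [
        {
            "ref_id": ref_id,
            "kind": kind_of.get(ref_id, ""),
            "sample_id": sample_id,
            "replicate_id": replicate_id,
            "total": total,
            "trimming_index": trimmed / total,
            "tailing_index": tailed / total,
        }
        for ref_id, (total, trimmed, tailed) in sorted(acc.items())
    ]
    return pd.DataFrame(rows, columns=INDEX_COLUMNS)


def mean_indexes(tables: list[pd.DataFrame] | pd.DataFrame) -> pd.DataFrame:
    """Mean index per (ref_id, modification) across the replicates of one line.

    Input is the replicate index tables of a single line (list or already
    concatenated).  The mean is over replicates where the index is defined;
    ``n_used`` records how many that was.
    """
    if isinstance(tables, list):
        if not tables:
            raise ValueError("at least one replicate index table required")
        df = pd.concat(tables, ignore_index=True)
    else:
        df = tables
    if df.empty:
        return pd.DataFrame(columns=["ref_id", "modification", "mean_index", "n_used"])
    long = df.melt(
        id_vars=["ref_id"],
        value_vars=["trimming_index", "tailing_index"],
        var_name="modification",
        value_name="index",
    )
    long["modification"] = long["modification"].str.replace("_index", "", regex=False)
    out = (
        long.groupby(["ref_id", "modification"], as_index=False)["index"]
        .agg(mean_index="mean", n_used="count")
        .sort_values(["modification", "ref_id"])
        .reset_index(drop=True)
    )
    return out


def index_differences(
    line_means: pd.DataFrame, ref_means: pd.DataFrame
) -> pd.DataFrame:
    """ID = line mean index − reference-line mean index, per (miRNA, modification).

    Only pairs defined in both lines are emitted.  Positive values mean more
    modification than the reference line.
    """
    if line_means.empty or ref_means.empty:
        raise ValueError("both mean-index tables must be nonempty")
    merged = line_means.merge(
        ref_means,
        on=["ref_id", "modification"],
        suffixes=("_line", "_ref"),
        how="inner",
    )
    out = merged[["ref_id", "modification"]].copy()
    out["line_mean"] = merged["mean_index_line"]
    out["ref_mean"] = merged["mean_index_ref"]
    out["id_value"] = out["line_mean"] - out["ref_mean"]
    return out


def paired_test(
    line_means: pd.DataFrame,
    ref_means: pd.DataFrame,
    modification: str,
    line_id: str = "line",
    reference_line_id: str = "reference",
    min_pairs: int = 3,
) -> TestResult:
    """Two-sided paired t-test on per-miRNA mean-index pairs for one modification.

    Degenerate inputs are flagged rather than guessed at: fewer than
    ``min_pairs`` shared miRNAs, or zero-variance differences with zero mean,
    give no p-value; zero-variance differences with a nonzero mean are
    reported at the smallest positive float and flagged.
    """
    if modification not in MODIFICATIONS:
        raise ValueError(f"modification must be one of {MODIFICATIONS}")
    a = line_means[line_means["modification"] == modification]
    b = ref_means[ref_means["modification"] == modification]
    merged = a.merge(b, on="ref_id", suffixes=("_line", "_ref"), how="inner")
    n = len(merged)
    if n < min_pairs:
        logger.warning(
            "%s vs %s (%s): only %d paired miRNAs (< %d), no p-value emitted",
            line_id,
            reference_line_id,
            modification,
            n,
            min_pairs,
        )
        return TestResult(
            line_id, reference_line_id, modification, n, None, None,
            note=f"fewer than {min_pairs} pairs",
        )
    diffs = (merged["mean_index_line"] - merged["mean_index_ref"]).to_numpy()
    mean_diff = float(np.mean(diffs))
    # constant differences up to float rounding count as zero variance
    if np.std(diffs, ddof=1) <= 1e-9 * max(abs(mean_diff), np.abs(diffs).max(), 1e-300):
        if mean_diff == 0.0:
            return TestResult(
                line_id, reference_line_id, modification, n, None, None,
                note="degenerate: zero variance, zero mean difference",
            )
        return TestResult(
            line_id,
            reference_line_id,
            modification,
            n,
            math.copysign(math.inf, mean_diff),
            sys.float_info.min,
            note="zero variance, nonzero mean: p below machine floor",
        )
    res = sps.ttest_rel(
        merged["mean_index_line"], merged["mean_index_ref"], alternative="two-sided"
    )
    return TestResult(
        line_id,
        reference_line_id,
        modification,
        n,
        float(res.statistic),
        float(res.pvalue),
    )


def fdr_correct(results: list[TestResult]) -> list[TestResult]:
    """Benjamini-Hochberg correction, pooled within each modification.

    All trimming tests in the run are corrected together and likewise all
    tailing tests, irrespective of any study grouping.  Results without a
    p-value pass through with no q-value.
    """
    out = list(results)
    for modification in MODIFICATIONS:
        idx = [
            i
            for i, r in enumerate(out)
            if r.modification == modification and r.p_value is not None
        ]
        if not idx:
            continue
        pvals = [out[i].p_value for i in idx]
        _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
        for i, q in zip(idx, qvals):
            out[i] = replace(out[i], q_value=float(q))
    return out


def significance_stars(q_value: float | None) -> str:
    """Figure-style annotation: * / ** / *** at 0.05 / 0.01 / 0.001."""
    if q_value is None:
        return ""
    if q_value < 0.001:
        return "***"
    if q_value < 0.01:
        return "**"
    if q_value < 0.05:
        return "*"
    return ""


def results_to_frame(results: list[TestResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "line_id": [r.line_id for r in results],
            "reference_line_id": [r.reference_line_id for r in results],
            "modification": [r.modification for r in results],
            "n_pairs": [r.n_pairs for r in results],
            "t_stat": [r.t_stat for r in results],
            "p_value": [r.p_value for r in results],
            "q_value": [r.q_value for r in results],
            "stars": [significance_stars(r.q_value) for r in results],
            "note": [r.note for r in results],
        }
    )
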