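import math

import numpy as np
import pandas as pd
import pytest

from trimtail import (
    compute_indexes,
    fdr_correct,
    index_differences,
    mean_indexes,
    paired_test,
    significance_stars,
)
from trimtail.classify import ModRecord
from trimtail.stats import TAILING, TRIMMING, TestResult


def make_records(ref_id, unaltered=0, trimmed=0, tailed=0, trimmed_tailed=0):
    recs = []
    if unaltered:
        recs.append(ModRecord("A" * 21, unaltered, ref_id, 0, "", "unaltered"))
    if trimmed:
        recs.append(ModRecord("A" * 19, trimmed, ref_id, 2, "", "trimmed"))
    if tailed:
        recs.append(ModRecord("A" * 21 + "TT", tailed, ref_id, 0, "TT", "tailed"))
    if trimmed_tailed:
        recs.append(
            ModRecord("A" * 18 + "TTT", trimmed_tailed, ref_id, 3, "TTT", "trimmed_tailed")
        )
    return recs


def means_frame(values: dict[str, float], modification=TRIMMING):
    return pd.DataFrame(
        {
            "ref_id": list(values),
            "modification": modification,
            "mean_index": list(values.values()),
            "n_used": 1,
        }
    )


class TestComputeIndexes:
    def test_basic_fractions(self):
        idx = compute_indexes(make_records("M1", unaltered=8, trimmed=1, tailed=1), "s", "r")
        row = idx.iloc[0]
        assert row.total == 10
        assert row.trimming_index == pytest.approx(0.1)
        assert row.tailing_index == pytest.approx(0.1)

    def test_trimmed_tailed_counts_in_both_numerators(self):
        idx = compute_indexes(make_records("M1", unaltered=6, trimmed_tailed=4), "s", "r")
        row = idx.iloc[0]
        assert row.trimming_index == pytest.approx(0.4)
        assert row.tailing_index == pytest.approx(0.4)

    def test_degree_blindness(self):
        # a read trimmed by 5 weighs the same as a read trimmed by 1
        deep = [ModRecord("A" * 16, 3, "M1", 5, "", "trimmed"),
                ModRecord("A" * 21, 7, "M1", 0, "", "unaltered")]
        shallow = [ModRecord("A" * 20, 3, "M1", 1, "", "trimmed"),
                   ModRecord("A" * 21, 7, "M1", 0, "", "unaltered")]
        a = compute_indexes(deep, "s", "r").iloc[0].trimming_index
        b = compute_indexes(shallow, "s", "r").iloc[0].trimming_index
        assert a == b == pytest.approx(0.3)

    def test_ambiguous_and_unclassified_excluded(self):
        recs = make_records("M1", unaltered=5) + [
            ModRecord("C" * 21, 9, None, 0, "", "ambiguous"),
            ModRecord("G" * 21, 4, None, 0, "", "unclassified"),
        ]
        idx = compute_indexes(recs, "s", "r")
        assert idx["total"].sum() == 5

    def test_index_times_total_is_integral(self, small_sim):
        _, reference, table, _ = small_sim
        from trimtail import classify_table, filter_genome_matching

        retained, _ = filter_genome_matching(table, reference.masked)
        idx = compute_indexes(
            classify_table(retained, reference.refs), "wt", "rep1", refs=reference.refs
        )
        for row in idx.itertuples(index=False):
            assert (row.trimming_index * row.total) == pytest.approx(
                round(row.trimming_index * row.total)
            )
            assert 0.0 <= row.trimming_index <= 1.0
            assert 0.0 <= row.tailing_index <= 1.0


class TestMeanIndexes:
    def table(self, replicate_id, values):
        return pd.DataFrame(
            {
                "ref_id": list(values),
                "kind": "guide",
                "sample_id": "s",
                "replicate_id": replicate_id,
                "total": 100,
                "trimming_index": list(values.values()),
                "tailing_index": 0.0,
            }
        )

    def test_mean_over_replicates(self):
        means = mean_indexes([self.table("r1", {"M1": 0.1}), self.table("r2", {"M1": 0.3})])
        row = means[means["modification"] == TRIMMING].iloc[0]
        assert row.mean_index == pytest.approx(0.2)
        assert row.n_used == 2

    def test_na_policy_mean_over_defined_replicates_only(self):
        means = mean_indexes([self.table("r1", {"M1": 0.4}), self.table("r2", {})])
        row = means[means["modification"] == TRIMMING].iloc[0]
        assert row.mean_index == pytest.approx(0.4)
        assert row.n_used == 1

    def test_single_replicate_is_identity(self):
        means = mean_indexes([self.table("r1", {"M1": 0.25})])
        assert means[means["modification"] == TRIMMING].iloc[0].mean_index == 0.25


class TestIndexDifferences:
    def test_difference(self):
        ids = index_differences(means_frame({"M1": 0.3}), means_frame({"M1": 0.1}))
        assert ids.iloc[0].id_value == pytest.approx(0.2)

    def test_self_comparison_is_zero(self):
        means = means_frame({"M1": 0.3, "M2": 0.05})
        ids = index_differences(means, means)
        assert (ids["id_value"] == 0).all()

    def test_antisymmetry(self):
        a = means_frame({"M1": 0.3, "M2": 0.1})
        b = means_frame({"M1": 0.05, "M2": 0.4})
        ab = index_differences(a, b).set_index("ref_id")["id_value"]
        ba = index_differences(b, a).set_index("ref_id")["id_value"]
        assert np.allclose(ab, -ba)

    def test_only_shared_mirnas_emitted(self):
        ids = index_differences(
            means_frame({"M1": 0.3, "M2": 0.1}), means_frame({"M1": 0.05})
        )
        assert list(ids["ref_id"]) == ["M1"]


class TestPairedTest:
    def test_against_df2_closed_form(self):
        # independent oracle: for df=2, P(T<=t) = 1/2 + t/(2*sqrt(t^2+2))
        line = means_frame({"a": 0.10, "b": 0.30, "c": 0.50})
        ref = means_frame({"a": 0.05, "b": 0.20, "c": 0.35})
        res = paired_test(line, ref, TRIMMING)
        assert res.n_pairs == 3
        assert res.t_stat == pytest.approx(3.4641, abs=1e-4)
        t = res.t_stat
        p_closed = 2 * (1 - (0.5 + t / (2 * math.sqrt(t * t + 2))))
        assert res.p_value == pytest.approx(p_closed, rel=1e-6)
        assert res.p_value == pytest.approx(0.0742, abs=5e-4)

    def test_identical_vectors_degenerate(self):
        means = means_frame({"a": 0.1, "b": 0.2, "c": 0.3})
        res = paired_test(means, means.copy(), TRIMMING)
        assert res.p_value is None
        assert "degenerate" in res.note

    def test_constant_nonzero_differences_flagged_floor(self):
        line = means_frame({"a": 0.2, "b": 0.3, "c": 0.4})
        ref = means_frame({"a": 0.1, "b": 0.2, "c": 0.3})
        res = paired_test(line, ref, TRIMMING)
        assert res.p_value is not None and res.p_value <= 1e-300
        assert "floor" in res.note

    def test_too_few_pairs_gives_no_p(self):
        res = paired_test(means_frame({"a": 0.1, "b": 0.2}), means_frame({"a": 0.0, "b": 0.1}), TRIMMING)
        assert res.n_pairs == 2
        assert res.p_value is None


class TestFdr:
    def make(self, pvals, modification=TRIMMING):
        return [
            TestResult(f"l{i}", "ref", modification, 5, 1.0, p)
            for i, p in enumerate(pvals)
        ]

    def test_hand_computed_bh(self):
        out = fdr_correct(self.make([0.01, 0.02, 0.03, 0.04]))
        assert [r.q_value for r in out] == pytest.approx([0.04, 0.04, 0.04, 0.04])

    def test_single_test_unchanged(self):
        out = fdr_correct(self.make([0.2]))
        assert out[0].q_value == pytest.approx(0.2)

    def test_monotonization(self):
        out = fdr_correct(self.make([0.5, 1.0]))
        assert [r.q_value for r in out] == pytest.approx([1.0, 1.0])

    def test_q_at_least_p_and_groups_separate(self):
        results = self.make([0.01, 0.04], TRIMMING) + self.make([0.03], TAILING)
        out = fdr_correct(results)
        for r in out:
            assert r.q_value >= r.p_value
        # the lone tailing test is corrected alone
        assert out[2].q_value == pytest.approx(0.03)
        assert out[0].q_value == pytest.approx(0.02)

    def test_missing_p_passes_through(self):
        results = self.make([0.01]) + [TestResult("x", "ref", TRIMMING, 1, None, None)]
        out = fdr_correct(results)
        assert out[1].q_value is None


def test_significance_stars_thresholds():
    assert significance_stars(0.0005) == "***"
    assert significance_stars(0.005) == "**"
    assert significance_stars(0.04) == "*"
    assert significance_stars(0.05) == ""
    assert significance_stars(None) == ""
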