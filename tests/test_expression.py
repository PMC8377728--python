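"""Counting, normalization, the exact NB test and wave assignment."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import binom

from hivemzt import expression
from hivemzt.core import Annotation, GenomicInterval, TranscriptModel
from tests.conftest import make_record


def simple_annotation():
    return Annotation(
        [
            TranscriptModel("gA.t", "gA", [GenomicInterval("c", 0, 1000, "+")]),
            TranscriptModel("gB.t", "gB", [GenomicInterval("c", 1000, 1500, "+")]),
        ]
    )


class TestCountReads:
    def test_read_inside_single_exon_counts_once(self):
        recs = [make_record("c", [(100, 200)], sample_id="s1")]
        counts = expression.count_reads(recs, simple_annotation(), {"c": 2000})
        assert counts.loc["gA", "s1"] == 1
        assert counts.loc["gB", "s1"] == 0

    def test_majority_overlap_wins(self):
        # 60 bases in gA ([940, 1000)), 40 in gB ([1000, 1040))
        recs = [make_record("c", [(940, 1040)], sample_id="s1")]
        counts = expression.count_reads(recs, simple_annotation(), {"c": 2000})
        assert counts.loc["gA", "s1"] == 1 and counts.loc["gB", "s1"] == 0
        # oracle: per-base overlap fractions
        assert 60 / 100 >= 0.5 > 40 / 100

    def test_tie_between_genes_dropped(self):
        recs = [make_record("c", [(950, 1050)], sample_id="s1")]
        counts = expression.count_reads(recs, simple_annotation(), {"c": 2000})
        assert counts["s1"].sum() == 0

    def test_intergenic_read_not_counted(self):
        recs = [make_record("c", [(1600, 1700)], sample_id="s1")]
        counts = expression.count_reads(recs, simple_annotation(), {"c": 2000})
        assert counts["s1"].sum() == 0

    def test_empty_annotation_is_error(self):
        with pytest.raises(ValueError):
            expression.count_reads([], Annotation([]), {"c": 100})


class TestNormalization:
    def test_rpkm_reference_values(self):
        counts = pd.DataFrame({"s": [10, 10]}, index=["g1", "g2"])
        lengths = pd.Series({"g1": 1000, "g2": 500})
        lib = pd.Series({"s": 1_000_000})
        out = expression.rpkm(counts, lengths, lib)
        assert out.loc["g1", "s"] == pytest.approx(10.0)
        assert out.loc["g2", "s"] == pytest.approx(20.0)

    def test_rpkm_halves_when_library_doubles(self):
        counts = pd.DataFrame({"a": [10], "b": [10]}, index=["g"])
        lengths = pd.Series({"g": 1000})
        out = expression.rpkm(
            counts, lengths, pd.Series({"a": 1e6, "b": 2e6})
        )
        assert out.loc["g", "b"] == pytest.approx(out.loc["g", "a"] / 2)

    def test_tpm_single_gene_is_one_million(self):
        counts = pd.DataFrame({"s": [42, 0]}, index=["g1", "g2"])
        out = expression.tpm(counts, pd.Series({"g1": 500, "g2": 900}))
        assert out.loc["g1", "s"] == pytest.approx(1e6)

    def test_tpm_equal_counts_equal_lengths_split_evenly(self):
        counts = pd.DataFrame({"s": [7, 7]}, index=["g1", "g2"])
        out = expression.tpm(counts, pd.Series({"g1": 300, "g2": 300}))
        assert np.allclose(out["s"], [5e5, 5e5])

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_tpm_columns_sum_to_one_million(self, seed):
        rng = np.random.default_rng(seed)
        counts = pd.DataFrame(
            rng.integers(0, 500, size=(8, 4)),
            index=[f"g{i}" for i in range(8)],
            columns=list("abcd"),
        )
        counts.iloc[:, 0] += 1  # keep at least one non-degenerate column
        lengths = pd.Series(
            rng.integers(200, 5000, size=8), index=counts.index
        )
        out = expression.tpm(counts, lengths)
        sums = out.sum(axis=0)
        nonzero = counts.sum(axis=0) > 0
        assert np.allclose(sums[nonzero], 1e6)
        assert (sums[~nonzero] == 0).all()

    def test_size_factors_identical_samples_are_one(self):
        counts = pd.DataFrame({"a": [10, 20, 30], "b": [10, 20, 30]})
        assert np.allclose(expression.deseq_size_factors(counts), 1.0)

    def test_size_factors_doubled_sample_median_of_ratios(self):
        counts = pd.DataFrame({"a": [10, 20, 40], "b": [20, 40, 80]})
        factors = expression.deseq_size_factors(counts)
        # closed form: geometric mean reference -> (1/sqrt(2), sqrt(2))
        assert factors["a"] == pytest.approx(1 / np.sqrt(2))
        assert factors["b"] == pytest.approx(np.sqrt(2))

    def test_genes_with_zeros_excluded_from_reference(self):
        counts = pd.DataFrame({"a": [10, 0, 10], "b": [10, 500, 10]})
        factors = expression.deseq_size_factors(counts)
        assert np.allclose(factors, 1.0)  # the zero gene cannot distort

    def test_no_all_positive_gene_is_error(self):
        counts = pd.DataFrame({"a": [0, 5], "b": [5, 0]})
        with pytest.raises(ValueError, match="filter"):
            expression.deseq_size_factors(counts)


class TestDetection:
    def test_threshold_is_strict(self):
        layer = pd.DataFrame({"s1": [0.1, 0.11], "s2": [0.0, 0.2]},
                             index=["g1", "g2"])
        detected, summary = expression.detect_expressed(layer, threshold=0.1)
        assert not detected.loc["g1"].any()
        assert detected.loc["g2"].all()
        assert summary["union_rate"] >= summary["per_sample_rate"].max()
        assert summary["union_count"] == 1


class TestNBExactTest:
    def test_identical_groups_null(self):
        l2fc, p = expression.nb_exact_test([7, 7, 7], [7, 7, 7])
        assert l2fc == 0.0
        assert p == pytest.approx(1.0)

    def test_strong_difference_significant_with_pseudocount_fc(self):
        l2fc, p = expression.nb_exact_test([5, 5], [50, 50])
        assert l2fc == pytest.approx(np.log2(51 / 6))
        assert p < 0.01

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            expression.nb_exact_test([-1, 2], [3, 4])

    def test_dispersion_zero_limit_matches_conditional_binomial(self):
        """At phi -> 0 the conditional NB split becomes binomial."""
        rng = np.random.default_rng(3)
        worst = 0.0
        for _ in range(40):
            a = rng.poisson(25, 3)
            b = rng.poisson(40, 3)
            _, p = expression.nb_exact_test(a, b, dispersion=1e-12)
            total = int(a.sum() + b.sum())
            pmf = binom.pmf(np.arange(total + 1), total, 0.5)
            oracle = pmf[pmf <= pmf[int(a.sum())] * (1 + 1e-8)].sum()
            worst = max(worst, abs(p - oracle))
        assert worst < 1e-6

    def test_unbalanced_group_sizes_shift_null_split(self):
        # with 1 vs 3 replicates the null expects a 1:3 split, not 1:1
        _, p = expression.nb_exact_test([10], [10, 10, 10], dispersion=1e-12)
        assert p == pytest.approx(1.0, abs=0.2)


class TestDEGCalls:
    def frame(self, fc, p, padj=None):
        return pd.DataFrame(
            {
                "log2_fold_change": [np.log2(fc)],
                "p_value": [p],
                "adjusted_p": [padj if padj is not None else p],
            },
            index=["g"],
        )

    def test_fold_change_threshold_is_strict(self):
        out = expression.call_degs(self.frame(2.0, 1e-5), mode="rawp")
        assert out.loc["g", "class"] == "ns"
        out = expression.call_degs(self.frame(2.001, 1e-5), mode="rawp")
        assert out.loc["g", "class"] == "up"

    def test_large_fc_without_significance_is_ns(self):
        out = expression.call_degs(self.frame(4.0, 0.5), mode="rawp")
        assert out.loc["g", "class"] == "ns"
        out = expression.call_degs(self.frame(4.0, 0.5, 0.5), mode="fdr")
        assert out.loc["g", "class"] == "ns"

    def test_down_calls(self):
        out = expression.call_degs(self.frame(0.2, 1e-4), mode="rawp")
        assert out.loc["g", "class"] == "down"

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            expression.call_degs(self.frame(4.0, 0.001), mode="bogus")


class TestWaveAssignment:
    @pytest.mark.parametrize(
        "c1,c2,c3,expected",
        [
            ("up", "down", "ns", "wave1"),  # activated then re-silenced
            ("up", "down", "up", "wave1"),
            ("up", "ns", "up", "wave2"),  # sustained to 72 h
            ("up", "up", "up", "wave2"),
            ("ns", "up", "up", "wave3"),  # late activation only
            ("down", "up", "ns", "wave3"),
            ("down", "ns", "down", "maternal_degradation"),
            ("ns", "ns", "down", "maternal_degradation"),
            ("down", "up", "down", "wave3"),  # wave3 precedence over MD
            ("ns", "ns", "ns", "none"),
            ("ns", "down", "ns", "none"),
        ],
    )
    def test_decision_table(self, c1, c2, c3, expected):
        def tab(cls):
            return pd.DataFrame({"class": [cls]}, index=["g"])

        waves = expression.assign_waves(tab(c1), tab(c2), tab(c3))
        assert waves["g"] == expected

    def test_every_gene_gets_exactly_one_label(self):
        classes = ["up", "down", "ns"]
        rows = [(a, b, c) for a in classes for b in classes for c in classes]
        idx = [f"g{i}" for i in range(len(rows))]

        def tab(col):
            return pd.DataFrame({"class": [r[col] for r in rows]}, index=idx)

        waves = expression.assign_waves(tab(0), tab(1), tab(2))
        assert set(waves.unique()) <= set(expression.WAVE_LABELS)
        assert waves.notna().all() and len(waves) == len(rows)

    def test_mismatched_gene_sets_rejected(self):
        a = pd.DataFrame({"class": ["up"]}, index=["g1"])
        b = pd.DataFrame({"class": ["up"]}, index=["g2"])
        with pytest.raises(ValueError):
            expression.assign_waves(a, b, a)


class TestDdct:
    @pytest.mark.parametrize(
        "target,ref,target_cal,ref_cal,expected",
        [
            (20.0, 18.0, 22.0, 20.0, 1.0),  # ddCt = 0
            (20.0, 18.0, 23.0, 20.0, 2.0),  # ddCt = -1
            (25.0, 18.0, 24.0, 20.0, 0.125),  # ddCt = 3
        ],
    )
    def test_reference_values(self, target, ref, target_cal, ref_cal, expected):
        assert expression.ddct(target, ref, target_cal, ref_cal) == pytest.approx(
            expected
        )

    def test_non_finite_ct_rejected(self):
        with pytest.raises(ValueError):
            expression.ddct(np.nan, 18, 22, 20)


class TestRpkmScalingInvariance:
    def test_rpkm_invariant_under_uniform_scaling_after_size_factors(self):
        rng = np.random.default_rng(0)
        counts = pd.DataFrame(
            rng.integers(5, 500, size=(20, 4)),
            index=[f"g{i}" for i in range(20)],
            columns=list("abcd"),
        )
        lengths = pd.Series(rng.integers(300, 3000, 20), index=counts.index)
        scaled = counts * 3
        for frame in (counts, scaled):
            f = expression.deseq_size_factors(frame)
            norm = frame / f
            if frame is counts:
                base = expression.rpkm(norm, lengths, norm.sum(axis=0))
            else:
                other = expression.rpkm(norm, lengths, norm.sum(axis=0))
        assert np.allclose(base.values, other.values)
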