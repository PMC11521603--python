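"""Read counting, coverage QC, reference-gene CN estimation and threshold
calling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from defcnv.depth import (
    ReadCountMatrix,
    ReadDepthCopyNumberEstimator,
    count_reads,
    estimate_copy_number,
    qc_filter_samples,
    summarize_cohort,
)
from defcnv.simulate import write_alignment_fixture
from defcnv.thresholds import ThresholdRule, call_cnv


class TestCountReads:
    REGIONS = {
        "R1": ("chr1", 1001, 2000),
        "R2": ("chr1", 5001, 6000),
        "R3": ("chr2", 101, 1100),
    }

    def test_counts_alignment_starts_in_region(self, tmp_path):
        bam, bed = write_alignment_fixture(
            tmp_path, self.REGIONS, {"R1": 7, "R2": 3}
        )
        matrix = count_reads(bam, bed, sample_id="s")
        assert matrix.counts.loc["s", "R1"] == 7
        assert matrix.counts.loc["s", "R2"] == 3

    def test_duplicate_flagged_reads_excluded(self, tmp_path):
        bam, bed = write_alignment_fixture(
            tmp_path, self.REGIONS, {"R1": 7}, duplicate_counts={"R1": 2}
        )
        matrix = count_reads(bam, bed, sample_id="s")
        assert matrix.counts.loc["s", "R1"] == 5

    def test_empty_region_counts_zero(self, tmp_path):
        bam, bed = write_alignment_fixture(tmp_path, self.REGIONS, {"R1": 4})
        matrix = count_reads(bam, bed, sample_id="s")
        assert matrix.counts.loc["s", "R3"] == 0

    def test_assay_groups_summed(self, tmp_path):
        bam, bed = write_alignment_fixture(
            tmp_path, self.REGIONS, {"R1": 4, "R2": 6}
        )
        matrix = count_reads(
            bam, bed, sample_id="s", assay_group_map={"R1": "G", "R2": "G"}
        )
        assert matrix.counts.loc["s", "G"] == 10

    def test_absent_contig_is_an_error(self, tmp_path):
        bam, _ = write_alignment_fixture(tmp_path, self.REGIONS, {"R1": 1})
        bed = tmp_path / "other.bed"
        bed.write_text("chrMissing\t0\t100\tX\n")
        with pytest.raises(ValueError, match="chrMissing"):
            count_reads(bam, bed)

    def test_missing_index_is_an_error(self, tmp_path):
        bam, bed = write_alignment_fixture(tmp_path, self.REGIONS, {"R1": 1})
        bam.with_suffix(".bam.bai").unlink()
        with pytest.raises(ValueError, match="index"):
            count_reads(bam, bed)


class TestQcFilter:
    def make(self, coverages):
        counts = pd.DataFrame(
            {"G": [10] * len(coverages), "TP53": [100] * len(coverages)},
            index=[f"s{i}" for i in range(len(coverages))],
        )
        return ReadCountMatrix(
            counts, mean_coverage=pd.Series(coverages, index=counts.index)
        )

    def test_strictly_below_threshold_excluded(self):
        filtered, report = qc_filter_samples(self.make([9.9, 10.0, 31.2]))
        assert report.n_excluded == 1
        assert list(report.excluded.index) == ["s0"]
        # boundary sample at exactly 10.0x is retained
        assert list(filtered.counts.index) == ["s1", "s2"]

    def test_no_exclusions_when_all_pass(self):
        filtered, report = qc_filter_samples(self.make([10.0, 15.0]))
        assert report.n_excluded == 0
        assert len(filtered.counts) == 2

    def test_missing_coverage_metadata_is_an_error(self):
        counts = pd.DataFrame({"G": [1], "TP53": [10]}, index=["s0"])
        with pytest.raises(ValueError, match="mean_coverage"):
            qc_filter_samples(ReadCountMatrix(counts))


class TestCopyNumberEstimation:
    def test_cohort_mean_ratio_sample_estimates_two(self, small_counts):
        # every sample has ratio 0.1 = the cohort mean ratio -> estimate 2.0
        cn, expected = estimate_copy_number(small_counts)
        assert np.allclose(cn["GENE1"], 2.0)
        assert expected["GENE1"] == 2.0

    def test_multicopy_group_scales_to_six(self, small_counts):
        est = ReadDepthCopyNumberEstimator(expected_cn={"GENE1": 6.0})
        cn = est.fit_transform(small_counts)
        assert np.allclose(cn["GENE1"], 6.0)

    def test_ratio_one_and_a_half_times_mean_gives_three(self):
        # ratios 0.1, 0.1, 0.1, 0.3 -> mean 0.15; sample ratio 0.15 * 1.5
        counts = pd.DataFrame(
            {"G": [100, 100, 100, 300], "TP53": [1000] * 4},
            index=list("abcd"),
        )
        cn, _ = estimate_copy_number(counts)
        assert cn.loc["d", "G"] == pytest.approx(2 * 0.3 / 0.15)
        assert cn.loc["d", "G"] == pytest.approx(4.0)

    def test_zero_count_sample_estimates_zero(self):
        counts = pd.DataFrame({"G": [0, 100], "TP53": [1000, 1000]}, index=["a", "b"])
        cn, _ = estimate_copy_number(counts)
        assert cn.loc["a", "G"] == 0.0

    def test_zero_reference_count_is_an_error(self):
        counts = pd.DataFrame({"G": [10, 10], "TP53": [0, 100]}, index=["a", "b"])
        with pytest.raises(ValueError, match="reference"):
            estimate_copy_number(counts)

    def test_single_sample_is_an_error(self):
        counts = pd.DataFrame({"G": [10], "TP53": [100]}, index=["a"])
        with pytest.raises(ValueError, match="2 samples"):
            estimate_copy_number(counts)

    def test_zero_baseline_group_reported_missing(self):
        counts = pd.DataFrame({"G": [0, 0], "TP53": [100, 100]}, index=["a", "b"])
        with pytest.warns(RuntimeWarning, match="baseline"):
            cn, _ = estimate_copy_number(counts)
        assert cn["G"].isna().all()

    def test_normalization_identity_exact(self, cohort):
        cn, expected = estimate_copy_number(cohort.read_counts.counts)
        assert np.allclose(cn.mean(axis=0), expected, rtol=0, atol=1e-12)

    @given(
        st.integers(min_value=0, max_value=3),
        st.floats(min_value=0.1, max_value=50.0),
    )
    @settings(derandomize=True, deadline=None, max_examples=50)
    def test_scale_invariance_of_one_sample(self, row, factor):
        rng = np.random.default_rng(99)
        counts = pd.DataFrame(
            rng.integers(50, 500, size=(4, 3)).astype(float),
            index=list("abcd"),
            columns=["G1", "G2", "TP53"],
        )
        est = ReadDepthCopyNumberEstimator().fit(counts)
        scaled = counts.copy()
        scaled.iloc[row] *= factor
        est_scaled = ReadDepthCopyNumberEstimator().fit(scaled)
        pd.testing.assert_frame_equal(
            est.transform(counts), est_scaled.transform(scaled)
        )

    def test_median_baseline_option(self):
        counts = pd.DataFrame(
            {"G": [100, 100, 100, 900], "TP53": [1000] * 4}, index=list("abcd")
        )
        cn_med, _ = estimate_copy_number(counts, baseline="median")
        # median ratio 0.1 -> unperturbed samples sit exactly at CN 2
        assert cn_med.loc["a", "G"] == pytest.approx(2.0)


class TestThresholdCalling:
    @pytest.mark.parametrize(
        "estimate,expected,call",
        [
            (1.2, 2.0, "deletion"),
            (1.5, 2.0, "normal"),  # strict "less than 1.5"
            (2.5, 2.0, "normal"),  # strict "greater than 2.5"
            (2.0, 2.0, "normal"),
            (2.6, 2.0, "duplication"),
            (4.0, 6.0, "deletion"),
            (4.5, 6.0, "normal"),
            (8.1, 6.0, "duplication"),
        ],
    )
    def test_printed_threshold_examples(self, estimate, expected, call):
        assert ThresholdRule(0.25).call(estimate, expected) == call

    def test_fraction_reproduces_both_printed_threshold_sets(self):
        rule = ThresholdRule(0.25)
        assert (rule.lower(2), rule.upper(2)) == (1.5, 2.5)
        assert (rule.lower(6), rule.upper(6)) == (4.5, 7.5)

    def test_agrees_with_brute_force_on_grid(self):
        rule = ThresholdRule(0.25)
        for expected in (2.0, 6.0):
            grid = np.linspace(0, 2 * expected, 10**4)
            lower, upper = expected * 0.75, expected * 1.25
            for est in grid:
                brute = (
                    "deletion" if est < lower
                    else "duplication" if est > upper
                    else "normal"
                )
                assert rule.call(est, expected) == brute

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            ThresholdRule(0.0)
        with pytest.raises(ValueError):
            ThresholdRule(1.0)

    def test_call_table_shape(self):
        cn = pd.DataFrame({"G": [1.0, 2.0, 3.0]}, index=list("abc"))
        calls = call_cnv(cn)
        assert list(calls["call"]) == ["deletion", "normal", "duplication"]


class TestSummarizeCohort:
    def test_all_normal_cohort_has_no_cnv_genes(self):
        cn = pd.DataFrame({"G1": [2.0, 2.1], "G2": [1.9, 2.0]}, index=["a", "b"])
        calls = call_cnv(cn)
        breeds = pd.Series({"a": "Angus", "b": "Angus"})
        breed_summary, gene_ranges = summarize_cohort(calls, breeds)
        assert breed_summary.loc[0, "n_genes_no_cnv"] == 2
        assert (gene_ranges["n_cnv_calls"] == 0).all()

    def test_planted_deletion_flagged(self):
        cn = pd.DataFrame(
            {"G1": [2.0, 1.0, 2.0], "G2": [2.0, 2.0, 2.0]}, index=list("abc")
        )
        calls = call_cnv(cn)
        breeds = pd.Series({"a": "H", "b": "H", "c": "H"})
        breed_summary, gene_ranges = summarize_cohort(calls, breeds)
        flagged = gene_ranges.set_index("assay_group")["n_cnv_calls"]
        assert flagged["G1"] == 1 and flagged["G2"] == 0
        assert gene_ranges.set_index("assay_group").loc["G1", "cn_min"] == 1.0

    def test_multiallelic_range_spans_planted_extremes(self, cohort, expected_cn_map):
        cn, _ = estimate_copy_number(cohort.read_counts.counts)
        est = ReadDepthCopyNumberEstimator(expected_cn=expected_cn_map)
        cn = est.fit_transform(cohort.read_counts.counts)
        calls = call_cnv(cn, expected_cn_map)
        _, gene_ranges = summarize_cohort(calls, cohort.breed)
        row = gene_ranges.set_index("assay_group").loc["DEFB103"]
        truth = cohort.true_cn["DEFB103"].loc[cn.index]
        # the mean-baseline normalization pins the cohort mean to the
        # expected CN, so estimates carry a known expected/mean(truth) scale
        scale = expected_cn_map["DEFB103"] / truth.mean()
        assert row["cn_min"] == pytest.approx(truth.min() * scale, abs=0.75)
        assert row["cn_max"] == pytest.approx(truth.max() * scale, abs=1.0)

    def test_unknown_sample_in_breed_map_is_an_error(self):
        cn = pd.DataFrame({"G1": [2.0, 2.0]}, index=["a", "b"])
        calls = call_cnv(cn)
        with pytest.raises(ValueError, match="breed"):
            summarize_cohort(calls, pd.Series({"a": "H"}))
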