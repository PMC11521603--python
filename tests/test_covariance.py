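"""Pairwise CN correlation, covarying-pair thresholding, block chaining and
overlap-artifact flagging."""

import numpy as np
import pandas as pd
import pytest

from defcnv.catalogue import GeneCatalogue, GeneRecord
from defcnv.covariance import (
    CovariationBlockFinder,
    find_blocks,
    find_covarying_pairs,
    overlap_artifact_flags,
    pairwise_cn_correlation,
)


def make_cn(**cols):
    return pd.DataFrame(cols)


class TestPairwiseCorrelation:
    def test_identical_vectors_give_unit_correlation(self):
        cn = make_cn(A=[1.0, 2, 3, 2], B=[1.0, 2, 3, 2])
        corr = pairwise_cn_correlation(cn)
        assert corr.at["A", "B"] == pytest.approx(1.0)

    def test_negation_gives_minus_one(self):
        cn = make_cn(A=[1.0, 2, 3], B=[-1.0, -2, -3])
        assert pairwise_cn_correlation(cn).at["A", "B"] == pytest.approx(-1.0)

    def test_fewer_than_three_samples_is_an_error(self):
        with pytest.raises(ValueError, match="3 samples"):
            pairwise_cn_correlation(make_cn(A=[1.0, 2], B=[2.0, 1]))

    def test_zero_variance_gene_reported_missing(self):
        cn = make_cn(A=[2.0, 2, 2], B=[1.0, 2, 3])
        corr = pairwise_cn_correlation(cn)
        assert np.isnan(corr.at["A", "B"]) and np.isnan(corr.at["A", "A"])
        assert corr.at["B", "B"] == 1.0

    def test_agrees_with_textbook_computation(self, rng):
        cn = pd.DataFrame(
            rng.normal(size=(30, 6)), columns=[f"G{i}" for i in range(6)]
        )
        corr = pairwise_cn_correlation(cn)
        direct = np.corrcoef(cn.to_numpy(), rowvar=False)
        assert np.allclose(corr.to_numpy(), direct, atol=1e-12)

    def test_independent_genes_weakly_correlated(self, rng):
        cn = pd.DataFrame(
            rng.poisson(4, size=(500, 2)).astype(float), columns=["A", "B"]
        )
        assert abs(pairwise_cn_correlation(cn).at["A", "B"]) < 0.2

    def test_spearman_option(self, rng):
        x = rng.normal(size=50)
        cn = pd.DataFrame({"A": x, "B": np.exp(x)})  # monotone, nonlinear
        assert pairwise_cn_correlation(cn, method="spearman").at["A", "B"] == (
            pytest.approx(1.0)
        )


class TestCovaryingPairs:
    def test_planted_pair_found_exactly(self, rng):
        base = rng.normal(size=60)
        cn = pd.DataFrame(
            {
                "A": base + rng.normal(scale=0.1, size=60),
                "B": base + rng.normal(scale=0.1, size=60),
                "C": rng.normal(size=60),
            }
        )
        corr = pairwise_cn_correlation(cn)
        pairs = find_covarying_pairs(corr, threshold=0.9)
        assert len(pairs) == 1
        assert {pairs.loc[0, "gene_a"], pairs.loc[0, "gene_b"]} == {"A", "B"}

    def test_threshold_one_with_no_perfect_pairs_is_empty(self, rng):
        cn = pd.DataFrame(rng.normal(size=(20, 3)), columns=list("ABC"))
        corr = pairwise_cn_correlation(cn)
        assert find_covarying_pairs(corr, threshold=1.0).empty

    def test_lowering_threshold_never_removes_pairs(self, cohort, expected_cn_map):
        from defcnv.depth import ReadDepthCopyNumberEstimator

        cn = ReadDepthCopyNumberEstimator(
            expected_cn=expected_cn_map
        ).fit_transform(cohort.read_counts.counts)
        corr = pairwise_cn_correlation(cn)
        at_090 = find_covarying_pairs(corr, 0.9)
        at_085 = find_covarying_pairs(corr, 0.85)
        keys = lambda df: {frozenset((a, b)) for a, b in zip(df.gene_a, df.gene_b)}
        assert keys(at_090) <= keys(at_085)

    def test_sorted_by_descending_r(self, rng):
        base = rng.normal(size=100)
        cn = pd.DataFrame(
            {
                "A": base,
                "B": base + rng.normal(scale=0.05, size=100),
                "C": base + rng.normal(scale=0.3, size=100),
            }
        )
        pairs = find_covarying_pairs(pairwise_cn_correlation(cn), 0.5)
        assert list(pairs["r"]) == sorted(pairs["r"], reverse=True)

    def test_invalid_threshold_rejected(self):
        corr = pd.DataFrame(np.eye(2), columns=["A", "B"], index=["A", "B"])
        for bad in (0.0, -0.5, 1.5):
            with pytest.raises(ValueError):
                find_covarying_pairs(corr, bad)


class TestBlocks:
    def pairs_df(self, *pairs):
        return pd.DataFrame(
            [{"gene_a": a, "gene_b": b, "r": r} for a, b, r in pairs]
        )

    def test_chained_pairs_form_one_block(self):
        blocks = find_blocks(self.pairs_df(("A", "B", 0.95), ("B", "C", 0.92)))
        assert len(blocks) == 1
        assert blocks[0].members == ("A", "B", "C")

    def test_disjoint_pairs_form_two_blocks(self):
        blocks = find_blocks(self.pairs_df(("A", "B", 0.95), ("C", "D", 0.91)))
        assert [b.members for b in blocks] == [("A", "B"), ("C", "D")]

    def test_blocks_partition_genes(self, rng):
        cn = pd.DataFrame(rng.normal(size=(50, 8)), columns=list("ABCDEFGH"))
        base = rng.normal(size=50)
        for g in "ABC":
            cn[g] = base + rng.normal(scale=0.2, size=50)
        corr = pairwise_cn_correlation(cn)
        pairs = find_covarying_pairs(corr, 0.8)
        blocks = find_blocks(pairs, corr=corr, threshold=0.8)
        seen = [g for b in blocks for g in b.members]
        assert len(seen) == len(set(seen))
        assert set(seen) == set(pairs["gene_a"]) | set(pairs["gene_b"])

    def test_min_internal_r_from_full_matrix(self):
        corr = pd.DataFrame(
            [[1.0, 0.95, 0.7], [0.95, 1.0, 0.92], [0.7, 0.92, 1.0]],
            columns=list("ABC"),
            index=list("ABC"),
        )
        pairs = find_covarying_pairs(corr, 0.9)
        blocks = find_blocks(pairs, corr=corr, threshold=0.9)
        # A-C at 0.7 is below threshold but still the block's weakest link
        assert blocks[0].min_pairwise_r == pytest.approx(0.7)

    def test_planted_segment_recovered(self, cohort, expected_cn_map):
        from defcnv.depth import ReadDepthCopyNumberEstimator

        cn = ReadDepthCopyNumberEstimator(
            expected_cn=expected_cn_map
        ).fit_transform(cohort.read_counts.counts)
        finder = CovariationBlockFinder(threshold=0.85).fit(cn)
        members = {b.members for b in finder.blocks_}
        assert ("DEFB110-1", "DEFB112", "DEFB113") in members


class TestOverlapArtifacts:
    def test_overlapping_block_flagged(self, catalogue):
        blocks = find_blocks(
            pd.DataFrame([{"gene_a": "DEFB7", "gene_b": "DEFB9", "r": 1.0}])
        )
        flags = overlap_artifact_flags(blocks, catalogue)
        assert flags.loc[0, "overlap_artifact"]

    def test_distant_genes_not_flagged(self):
        cat = GeneCatalogue(
            [
                GeneRecord("A", "chr1", 1_000_000, 1_002_000),
                GeneRecord("B", "chr1", 2_000_000, 2_002_000),
            ]
        )
        blocks = find_blocks(
            pd.DataFrame([{"gene_a": "A", "gene_b": "B", "r": 0.95}])
        )
        assert not overlap_artifact_flags(blocks, cat).loc[0, "overlap_artifact"]

    def test_mixed_block_identifies_the_overlapping_pair(self):
        cat = GeneCatalogue(
            [
                GeneRecord("A", "chr1", 100, 200),
                GeneRecord("B", "chr1", 150, 250),
                GeneRecord("C", "chr1", 1_000_000, 1_000_500),
            ]
        )
        blocks = find_blocks(
            pd.DataFrame(
                [
                    {"gene_a": "A", "gene_b": "B", "r": 0.99},
                    {"gene_a": "B", "gene_b": "C", "r": 0.91},
                ]
            )
        )
        flags = overlap_artifact_flags(blocks, cat)
        assert flags.loc[0, "overlap_artifact"]
        assert flags.loc[0, "overlapping_pairs"] == "A|B"
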