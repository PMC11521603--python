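"""Copy-number covariation across individuals.

Genes that sit on one copy-number-variable genomic segment gain and lose
copies together, so their diploid CN estimates are strongly correlated across
a cohort. Pairs above a correlation threshold are chained into blocks
(connected components of the thresholded correlation graph). Blocks whose
member genes occupy overlapping genomic intervals are flagged: identical read
counts from a shared region produce r ≈ 1 as a counting artifact, not
evidence of a shared variable segment.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .catalogue import GeneCatalogue

__all__ = [
    "CovariationBlock",
    "pairwise_cn_correlation",
    "find_covarying_pairs",
    "find_blocks",
    "overlap_artifact_flags",
    "CovariationBlockFinder",
]


def pairwise_cn_correlation(
    cn: pd.DataFrame, method: str = "pearson"
) -> pd.DataFrame:
    """Gene x gene correlation of CN estimates across samples.

    Zero-variance genes yield undefined (NaN) rows/columns rather than an
    arbitrary value. Requires at least 3 samples for the coefficient to carry
    any information beyond sign.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError(f"method must be 'pearson' or 'spearman', got {method!r}")
    if len(cn) < 3:
        raise ValueError(f"need >= 3 samples for correlation, got {len(cn)}")
    corr = cn.corr(method=method)
    # pandas leaves the diagonal at 1 even for constant columns; mark them NaN
    constant = cn.std(axis=0, ddof=0) == 0
    corr.loc[constant, :] = np.nan
    corr.loc[:, constant] = np.nan
    return corr


def find_covarying_pairs(
    corr: pd.DataFrame, threshold: float = 0.9
) -> pd.DataFrame:
    """Unordered gene pairs with r >= threshold, sorted by descending r.

    Missing (zero-variance) entries never satisfy the threshold. The
    comparison uses signed r: negative covariation has no shared-segment
    interpretation.
    """
    if not 0 < threshold <= 1:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    genes = list(corr.columns)
    rows = []
    for i, a in enumerate(genes):
        for b in genes[i + 1 :]:
            r = corr.at[a, b]
            if pd.notna(r) and r >= threshold:
                rows.append({"gene_a": a, "gene_b": b, "r": float(r)})
    pairs = pd.DataFrame(rows, columns=["gene_a", "gene_b", "r"])
    return pairs.sort_values("r", ascending=False, kind="mergesort").reset_index(
        drop=True
    )


@dataclass(frozen=True)
class CovariationBlock:
    """Connected component of the thresholded correlation graph."""

    members: tuple[str, ...]
    min_pairwise_r: float
    threshold: float

    def __len__(self) -> int:
        return len(self.members)


def find_blocks(
    pairs: pd.DataFrame,
    corr: pd.DataFrame | None = None,
    threshold: float = 0.9,
) -> list[CovariationBlock]:
    """Chain covarying pairs into blocks by graph connectivity.

    Components rather than cliques: pairwise evidence A–B and B–C places A, B
    and C on one candidate segment even if A–C alone misses the threshold.
    ``min_pairwise_r`` is computed over all internal pairs from the full
    matrix when supplied, else over the threshold-passing pairs only.
    """
    graph = nx.Graph()
    for _, row in pairs.iterrows():
        graph.add_edge(row["gene_a"], row["gene_b"], r=row["r"])
    blocks = []
    for component in nx.connected_components(graph):
        members = tuple(sorted(component))
        if corr is not None:
            internal = [
                float(corr.at[a, b])
                for i, a in enumerate(members)
                for b in members[i + 1 :]
            ]
        else:
            internal = [
                graph.edges[e]["r"]
                for e in graph.subgraph(members).edges
            ]
        blocks.append(
            CovariationBlock(
                members=members,
                min_pairwise_r=float(np.nanmin(internal)),
                threshold=threshold,
            )
        )
    blocks.sort(key=lambda b: b.members)
    return blocks


def overlap_artifact_flags(
    blocks: list[CovariationBlock], catalogue: GeneCatalogue
) -> pd.DataFrame:
    """Flag blocks whose members' genomic intervals overlap.

    Returns one row per block with ``overlap_artifact`` True when any two
    members overlap, and the overlapping pairs listed. Block members are
    assay-group keys; they are matched to catalogue records by symbol or by
    assay-group membership.
    """
    by_group: dict[str, list] = {}
    for rec in catalogue:
        by_group.setdefault(rec.assay_group, []).append(rec)
        by_group.setdefault(rec.symbol, []).append(rec)
    rows = []
    for block in blocks:
        overlapping = []
        members = block.members
        for i, a in enumerate(members):
            for b in members[i + 1 :]:
                recs_a = by_group.get(a, [])
                recs_b = by_group.get(b, [])
                if any(ra.overlaps(rb) for ra in recs_a for rb in recs_b):
                    overlapping.append((a, b))
        rows.append(
            {
                "members": ",".join(members),
                "min_pairwise_r": block.min_pairwise_r,
                "overlap_artifact": bool(overlapping),
                "overlapping_pairs": ";".join(f"{a}|{b}" for a, b in overlapping),
            }
        )
    return pd.DataFrame(
        rows, columns=["members", "min_pairwise_r", "overlap_artifact", "overlapping_pairs"]
    )


class CovariationBlockFinder(BaseEstimator):
    """Detect copy-number covariation blocks from a CN estimate matrix.

    Parameters
    ----------
    threshold : float, default 0.9
        Minimum signed correlation for a pair to count as covarying.
    method : {"pearson", "spearman"}, default "pearson"

    Attributes
    ----------
    correlation_ : gene x gene correlation matrix.
    pairs_ : DataFrame of covarying pairs (gene_a, gene_b, r), descending r.
    blocks_ : list of :class:`CovariationBlock`.
    """

    def __init__(self, threshold: float = 0.9, method: str = "pearson"):
        self.threshold = threshold
        self.method = method

    def fit(self, X: pd.DataFrame, y=None):
        self.correlation_ = pairwise_cn_correlation(X, method=self.method)
        self.pairs_ = find_covarying_pairs(self.correlation_, self.threshold)
        self.blocks_ = find_blocks(
            self.pairs_, corr=self.correlation_, threshold=self.threshold
        )
        return self

    def flag_overlap_artifacts(self, catalogue: GeneCatalogue) -> pd.DataFrame:
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "blocks_")
        return overlap_artifact_flags(self.blocks_, catalogue)
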