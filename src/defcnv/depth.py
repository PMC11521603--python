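"""Read-depth copy-number estimation.

Reads per catalogue region are counted from coordinate-sorted, indexed BAM
alignments (or supplied directly as a TSV matrix), samples with insufficient
mean genome coverage are excluded, and diploid copy numbers are estimated by
reference-gene normalization: per sample the region count is divided by the
*TP53* count, that ratio is divided by the cohort baseline ratio for the
region, and the result is scaled to the region's expected diploid copy number
(2 for single-copy genes, 6 for the three-copy *DEFB103* assay group).

The normalization forces each gene's cohort mean to the expected copy number,
so estimates are unbiased only when deletions and duplications are rare in
the cohort; a median baseline is available to resist common variants.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .catalogue import GeneCatalogue, from_bed
from .thresholds import CALL_NORMAL

__all__ = [
    "ReadCountMatrix",
    "count_reads",
    "qc_filter_samples",
    "ReadDepthCopyNumberEstimator",
    "estimate_copy_number",
    "summarize_cohort",
]

DEFAULT_REFERENCE_GENE = "TP53"


@dataclass
class ReadCountMatrix:
    """Samples x regions integer read counts with optional metadata.

    ``counts`` columns are assay-group keys plus the reference gene key;
    ``mean_coverage`` is per-sample mean genome coverage in x units.
    """

    counts: pd.DataFrame
    mean_coverage: pd.Series | None = None
    breed: pd.Series | None = None

    def __post_init__(self) -> None:
        arr = self.counts.to_numpy()
        if (arr < 0).any():
            raise ValueError("read counts must be non-negative")
        if self.mean_coverage is not None:
            self.mean_coverage = self.mean_coverage.reindex(self.counts.index)
        if self.breed is not None:
            self.breed = self.breed.reindex(self.counts.index)

    @property
    def samples(self) -> list:
        return list(self.counts.index)

    def to_tsv(self, path: str | Path) -> None:
        out = self.counts.copy()
        if self.mean_coverage is not None:
            out.insert(0, "mean_coverage", self.mean_coverage)
        if self.breed is not None:
            out.insert(0, "breed", self.breed)
        out.to_csv(path, sep="\t", index_label="sample")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ReadCountMatrix":
        df = pd.read_csv(path, sep="\t", index_col="sample")
        coverage = None
        breed = None
        if "mean_coverage" in df.columns:
            coverage = df.pop("mean_coverage").astype(float)
        if "breed" in df.columns:
            breed = df.pop("breed").astype(str)
        return cls(df.astype(int), mean_coverage=coverage, breed=breed)


def count_reads(
    alignments: str | Path,
    regions: str | Path | GeneCatalogue,
    sample_id: str | None = None,
    assay_group_map: dict[str, str] | None = None,
    mean_coverage: float | None = None,
) -> ReadCountMatrix:
    """Count mapped reads per region for one sample.

    A read is assigned to a region when its alignment start (0-based leftmost
    reference position) lies within the region. Unmapped and duplicate-flagged
    reads are excluded; multi-mapping reads are retained regardless of mapping
    quality, since paralogous β-defensin regions legitimately attract MAPQ-0
    reads and discarding them would deflate multi-copy estimates. Counts for
    regions sharing an assay group are summed.

    Parameters
    ----------
    alignments : path to a coordinate-sorted, indexed BAM file.
    regions : BED path (0-based half-open, 4 columns) or a GeneCatalogue.
    assay_group_map : optional symbol -> assay_group mapping; regions whose
        name is absent map to themselves. Ignored when ``regions`` is a
        catalogue (its own grouping is used).
    """
    import pysam

    if isinstance(regions, GeneCatalogue):
        catalogue = regions
    else:
        catalogue = from_bed(Path(regions))
        if assay_group_map:
            catalogue = GeneCatalogue(
                [
                    _regroup(rec, assay_group_map.get(rec.symbol, rec.symbol))
                    for rec in catalogue
                ]
            )

    path = Path(alignments)
    try:
        bam = pysam.AlignmentFile(str(path), "rb")
    except (ValueError, OSError) as exc:
        raise ValueError(f"cannot open alignment file {path}: {exc}") from exc
    with bam:
        if not bam.has_index():
            raise ValueError(
                f"{path} has no index; coordinate-sort and index the BAM first"
            )
        contigs = set(bam.references)
        totals: dict[str, int] = {}
        for rec in catalogue:
            if rec.chromosome not in contigs:
                raise ValueError(
                    f"region contig {rec.chromosome!r} absent from alignment header"
                )
            start0, end = rec.start - 1, rec.end
            n = 0
            for read in bam.fetch(rec.chromosome, start0, end):
                if read.is_unmapped or read.is_duplicate:
                    continue
                if start0 <= read.reference_start < end:
                    n += 1
            totals[rec.assay_group] = totals.get(rec.assay_group, 0) + n

    sample = sample_id or path.stem
    counts = pd.DataFrame([totals], index=[sample])
    coverage = (
        pd.Series({sample: mean_coverage}) if mean_coverage is not None else None
    )
    return ReadCountMatrix(counts, mean_coverage=coverage)


def _regroup(rec, group):
    from dataclasses import replace

    return replace(rec, assay_group=group)


@dataclass
class QcReport:
    """Samples excluded by the coverage filter, with their coverages."""

    threshold: float
    excluded: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))

    @property
    def n_excluded(self) -> int:
        return len(self.excluded)


def qc_filter_samples(
    matrix: ReadCountMatrix, min_mean_coverage: float = 10.0
) -> tuple[ReadCountMatrix, QcReport]:
    """Drop samples whose mean genome coverage fell below the threshold.

    The boundary is strict: a sample at exactly the threshold is retained.
    Raises if any sample lacks coverage metadata — silent retention of
    unassessable samples is never acceptable.
    """
    if matrix.mean_coverage is None:
        raise ValueError("mean_coverage metadata required for QC filtering")
    cov = matrix.mean_coverage
    if cov.isna().any():
        bad = list(cov.index[cov.isna()])
        raise ValueError(f"samples missing mean_coverage: {bad}")
    keep = cov >= min_mean_coverage
    report = QcReport(threshold=min_mean_coverage, excluded=cov[~keep])
    filtered = ReadCountMatrix(
        matrix.counts.loc[keep],
        mean_coverage=cov[keep],
        breed=matrix.breed[keep] if matrix.breed is not None else None,
    )
    return filtered, report


class ReadDepthCopyNumberEstimator(BaseEstimator, TransformerMixin):
    """Diploid copy number from read counts by reference-gene normalization.

    For sample ``s`` and assay group ``g`` with reference gene ``ref``::

        ratio(s, g)    = count(s, g) / count(s, ref)
        estimate(s, g) = expected_cn(g) * ratio(s, g) / baseline(g)

    where ``baseline(g)`` is the cohort mean (or median) of ``ratio(., g)``
    learned in :meth:`fit`. With the mean baseline the cohort mean of the
    estimates equals ``expected_cn(g)`` exactly, by construction.

    Parameters
    ----------
    reference_gene : str, default "TP53"
        Column holding the two-copy reference gene counts.
    expected_cn : mapping or None
        Expected diploid CN per assay group; groups not listed default to 2.
        Pass ``catalogue.expected_cn()`` to use catalogue annotations.
    baseline : {"mean", "median"}, default "mean"
        Cohort statistic defining the per-gene baseline ratio. The mean
        reproduces the published normalization; the median resists bias when
        a deletion or duplication allele is common.

    Attributes
    ----------
    groups_ : list of assay-group columns (reference excluded).
    baseline_ratio_ : pd.Series, learned per-group baseline ratio.
    expected_cn_ : pd.Series, expected diploid CN per group.
    n_samples_fit_ : int
    """

    def __init__(
        self,
        reference_gene: str = DEFAULT_REFERENCE_GENE,
        expected_cn=None,
        baseline: str = "mean",
    ):
        self.reference_gene = reference_gene
        self.expected_cn = expected_cn
        self.baseline = baseline

    def _counts_frame(self, X) -> pd.DataFrame:
        if isinstance(X, ReadCountMatrix):
            X = X.counts
        if not isinstance(X, pd.DataFrame):
            raise TypeError("X must be a ReadCountMatrix or a pandas DataFrame")
        if self.reference_gene not in X.columns:
            raise ValueError(
                f"reference gene {self.reference_gene!r} not in count columns"
            )
        return X

    def _ratios(self, X: pd.DataFrame) -> pd.DataFrame:
        ref = X[self.reference_gene].astype(float)
        if (ref <= 0).any():
            bad = list(X.index[ref <= 0])
            raise ValueError(f"non-positive reference-gene counts for samples {bad}")
        groups = [c for c in X.columns if c != self.reference_gene]
        return X[groups].astype(float).div(ref, axis=0)

    def fit(self, X, y=None):
        if self.baseline not in ("mean", "median"):
            raise ValueError("baseline must be 'mean' or 'median'")
        X = self._counts_frame(X)
        if len(X) < 2:
            raise ValueError("cohort baseline requires at least 2 samples")
        ratios = self._ratios(X)
        self.groups_ = list(ratios.columns)
        self.baseline_ratio_ = (
            ratios.mean(axis=0) if self.baseline == "mean" else ratios.median(axis=0)
        )
        expected = pd.Series(2.0, index=self.groups_)
        if self.expected_cn is not None:
            for g in self.groups_:
                if g in self.expected_cn:
                    expected[g] = float(self.expected_cn[g])
        self.expected_cn_ = expected
        self.n_samples_fit_ = len(X)
        return self

    def transform(self, X) -> pd.DataFrame:
        """Copy-number estimates for ``X`` using the fitted cohort baseline."""
        check_is_fitted(self, "baseline_ratio_")
        X = self._counts_frame(X)
        ratios = self._ratios(X)[self.groups_]
        zero_baseline = self.baseline_ratio_ == 0
        if zero_baseline.any():
            warnings.warn(
                "cohort baseline ratio is 0 for groups "
                f"{list(self.baseline_ratio_.index[zero_baseline])}; "
                "estimates reported as missing",
                RuntimeWarning,
                stacklevel=2,
            )
        baseline = self.baseline_ratio_.replace(0, np.nan)
        return ratios.div(baseline, axis=1).mul(self.expected_cn_, axis=1)


def estimate_copy_number(
    matrix: ReadCountMatrix | pd.DataFrame,
    catalogue: GeneCatalogue | None = None,
    reference_gene: str = DEFAULT_REFERENCE_GENE,
    baseline: str = "mean",
) -> tuple[pd.DataFrame, pd.Series]:
    """Fit-and-transform convenience wrapper.

    Returns ``(cn, expected_cn)`` where ``cn`` is the samples x groups
    estimate matrix and ``expected_cn`` the per-group expected diploid CN.
    """
    expected = catalogue.expected_cn() if catalogue is not None else None
    est = ReadDepthCopyNumberEstimator(
        reference_gene=reference_gene, expected_cn=expected, baseline=baseline
    )
    cn = est.fit_transform(matrix)
    return cn, est.expected_cn_


def summarize_cohort(
    calls: pd.DataFrame, breed_labels: pd.Series | dict
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-breed CNV summary and per-gene estimate ranges.

    Parameters
    ----------
    calls : tidy call table (sample, assay_group, estimate, call) as produced
        by :func:`defcnv.thresholds.call_cnv`.
    breed_labels : sample -> breed mapping covering every sample in ``calls``.

    Returns
    -------
    breed_summary : per breed, the number of assay groups with no non-normal
        call in that breed (``n_genes_no_cnv``) plus totals.
    gene_ranges : per assay group, min/max estimate across the cohort and the
        number of non-normal calls.
    """
    breeds = pd.Series(breed_labels)
    unknown = set(calls["sample"]) - set(breeds.index)
    if unknown:
        raise ValueError(f"samples missing from breed map: {sorted(map(str, unknown))}")
    df = calls.copy()
    df["breed"] = df["sample"].map(breeds)
    # "missing" estimates are neither normal nor evidence of CNV
    df["is_cnv"] = df["call"].isin(["deletion", "duplication"])

    rows = []
    for breed, sub in df.groupby("breed", sort=True):
        per_gene = sub.groupby("assay_group")["is_cnv"].any()
        rows.append(
            {
                "breed": breed,
                "n_samples": sub["sample"].nunique(),
                "n_genes": len(per_gene),
                "n_genes_no_cnv": int((~per_gene).sum()),
                "n_genes_cnv": int(per_gene.sum()),
            }
        )
    breed_summary = pd.DataFrame(rows)

    gene_ranges = (
        df.groupby("assay_group")
        .agg(
            cn_min=("estimate", "min"),
            cn_max=("estimate", "max"),
            n_cnv_calls=("is_cnv", "sum"),
        )
        .reset_index()
    )
    return breed_summary, gene_ranges
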