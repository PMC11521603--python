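"""Expression ingestion, a simple two-group differential-expression stage,
and copy-number–expression dosage correlation.

Expression is handled in transcripts-per-million (TPM). The differential
stage is deliberately lightweight — a Welch t-test on log2(TPM + 1) with
Benjamini–Hochberg correction — suited to flagging large maturation-driven
shifts, not a replacement for count-based negative-binomial modelling. The
dosage analysis asks, gene by gene, whether transcript abundance tracks
genomic copy number across matched individuals; a positive slope is the
classic dosage effect, a negative slope points to regulatory disruption.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "compute_tpm",
    "read_tpm",
    "group_differential_expression",
    "dosage_correlation",
    "zero_expression_report",
]


def compute_tpm(counts: pd.DataFrame, lengths: pd.Series) -> pd.DataFrame:
    """Transcripts per million from a samples x genes count matrix.

    TPM(s, g) = 1e6 * (count/length) / sum_g(count/length). Rows sum to 1e6
    except all-zero samples, which stay all-zero with a warning.
    """
    lengths = lengths.reindex(counts.columns)
    if lengths.isna().any():
        missing = list(lengths.index[lengths.isna()])
        raise ValueError(f"genes missing effective lengths: {missing}")
    if (lengths <= 0).any():
        bad = list(lengths.index[lengths <= 0])
        raise ValueError(f"non-positive gene lengths: {bad}")
    if (counts.to_numpy() < 0).any():
        raise ValueError("counts must be non-negative")
    rate = counts.div(lengths, axis=1)
    denom = rate.sum(axis=1)
    zero_rows = denom == 0
    if zero_rows.any():
        warnings.warn(
            f"samples with all-zero counts left as zero rows: "
            f"{list(counts.index[zero_rows])}",
            RuntimeWarning,
            stacklevel=2,
        )
    tpm = rate.div(denom.replace(0, np.nan), axis=0) * 1e6
    return tpm.fillna(0.0)


def read_tpm(path) -> pd.DataFrame:
    """Read a samples x genes TPM matrix from TSV (index column ``sample``)."""
    df = pd.read_csv(path, sep="\t", index_col="sample")
    if (df.to_numpy() < 0).any():
        raise ValueError("TPM values must be non-negative")
    return df.astype(float)


def group_differential_expression(
    expr: pd.DataFrame,
    groups: pd.Series | dict,
    fdr_cutoff: float = 0.1,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Two-group differential expression on TPM.

    Per gene: log2 fold change of group means with a pseudo-count,
    log2FC = log2((mean2 + eps) / (mean1 + eps)); p from a Welch (unequal
    variance) t-test on log2(TPM + eps); FDR by Benjamini–Hochberg. Group 1
    is the lexicographically first label (e.g. adult vs calf: fold change is
    reported as the second group over the first).

    Returns a DataFrame with columns gene, mean_<g1>, mean_<g2>, log2fc,
    p_value, fdr, significant.
    """
    groups = pd.Series(groups)
    groups = groups.reindex(expr.index)
    if groups.isna().any():
        raise ValueError(
            f"samples missing group labels: {list(expr.index[groups.isna()])}"
        )
    labels = sorted(groups.unique())
    if len(labels) != 2:
        raise ValueError(f"exactly two group labels required, got {labels}")
    g1, g2 = labels
    idx1, idx2 = groups == g1, groups == g2
    if idx1.sum() < 2 or idx2.sum() < 2:
        raise ValueError("each group needs at least 2 samples")

    eps = pseudocount
    log_expr = np.log2(expr + eps)
    mean1 = expr.loc[idx1].mean(axis=0)
    mean2 = expr.loc[idx2].mean(axis=0)
    log2fc = np.log2((mean2 + eps) / (mean1 + eps))
    tstat, pvals = stats.ttest_ind(
        log_expr.loc[idx2], log_expr.loc[idx1], equal_var=False
    )
    # constant genes in both groups give NaN p; treat as no evidence
    pvals = np.where(np.isnan(pvals), 1.0, pvals)
    _, fdr, _, _ = multipletests(pvals, method="fdr_bh")
    out = pd.DataFrame(
        {
            "gene": expr.columns,
            f"mean_{g1}": mean1.to_numpy(),
            f"mean_{g2}": mean2.to_numpy(),
            "log2fc": log2fc.to_numpy(),
            "p_value": pvals,
            "fdr": fdr,
        }
    )
    out["significant"] = out["fdr"] < fdr_cutoff
    return out


def dosage_correlation(
    cn: pd.DataFrame,
    expr: pd.DataFrame,
    method: str = "pearson",
    log_transform: bool = False,
) -> pd.DataFrame:
    """Correlate per-gene expression with per-gene copy number.

    Matches samples by index and genes by column name. Per gene: correlation
    coefficient across matched samples, two-sided nominal p-value, variance
    explained r², and slope sign. Genes with zero variance in either variable
    are reported with NaN statistics. A BH-adjusted column is included
    alongside the nominal p for transparency; the nominal p is the decision
    statistic.

    Parameters
    ----------
    log_transform : bool
        Correlate against log1p(TPM) instead of raw TPM.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError(f"method must be 'pearson' or 'spearman', got {method!r}")
    samples = cn.index.intersection(expr.index)
    if len(samples) == 0:
        raise ValueError("no matched samples between CN and expression matrices")
    if len(samples) < 3:
        raise ValueError(f"need >= 3 matched samples, got {len(samples)}")
    genes = [g for g in cn.columns if g in expr.columns]

    corr_fn = stats.pearsonr if method == "pearson" else stats.spearmanr
    rows = []
    for gene in genes:
        x = cn.loc[samples, gene].astype(float)
        y = expr.loc[samples, gene].astype(float)
        if log_transform:
            y = np.log1p(y)
        ok = x.notna() & y.notna()
        x, y = x[ok], y[ok]
        if len(x) < 3 or x.std(ddof=0) == 0 or y.std(ddof=0) == 0:
            r, p = np.nan, np.nan
        else:
            r, p = corr_fn(x, y)
            r, p = float(r), float(p)
        rows.append(
            {
                "gene": gene,
                "n": int(ok.sum()),
                "r": r,
                "p_value": p,
                "r_squared": r * r if not np.isnan(r) else np.nan,
                "slope_sign": (
                    0 if np.isnan(r) or r == 0 else int(np.sign(r))
                ),
            }
        )
    out = pd.DataFrame(rows, columns=["gene", "n", "r", "p_value", "r_squared", "slope_sign"])
    finite = out["p_value"].notna()
    out["fdr"] = np.nan
    if finite.any():
        _, fdr, _, _ = multipletests(out.loc[finite, "p_value"], method="fdr_bh")
        out.loc[finite, "fdr"] = fdr
    return out


def zero_expression_report(expr: pd.DataFrame) -> pd.DataFrame:
    """Per gene, how many samples show no expression at all.

    Captures the pattern where a gene's expression range spans from high TPM
    down to complete absence in some individuals.
    """
    n = len(expr)
    zeros = (expr == 0).sum(axis=0)
    return pd.DataFrame(
        {
            "gene": expr.columns,
            "n_zero": zeros.to_numpy(dtype=int),
            "fraction_zero": (zeros / n).to_numpy() if n else zeros.to_numpy(dtype=float),
        }
    )
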