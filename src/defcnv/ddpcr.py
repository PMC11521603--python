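"""Droplet-digital-PCR copy-number quantification.

A ddPCR reaction partitions the sample into ~20000 droplets; template
molecules distribute among droplets approximately as a Poisson process, so
the mean template copies per droplet is recovered from the fraction of
negative droplets as λ = −ln(1 − k/N). Copy number is the λ ratio of the
target assay to a two-copy reference gene assay (*TP53*), scaled to the
reference's diploid copy number; droplet volume cancels in the ratio.

With intercalating-dye (EvaGreen) chemistry each well measures one assay, so
target and reference are separate wells of the same sample; replicate wells
are pooled by summing droplets before λ estimation (the maximum-likelihood
combination for Poisson partitions).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .thresholds import CnvCaller

__all__ = [
    "SaturationError",
    "poisson_lambda",
    "concentration_copies_per_ul",
    "normalized_copy_number",
    "DdpcrQuantifier",
    "quantify_wells",
    "classify_ddpcr",
    "concordance",
]

WELL_COLUMNS = ["sample", "gene", "role", "droplets_total", "droplets_positive"]
DEFAULT_DROPLET_VOLUME_NL = 0.85


class SaturationError(ValueError):
    """All droplets positive: λ is unbounded and the assay is outside its
    dynamic range (dilute and repeat)."""


def poisson_lambda(positives: int, total: int) -> float:
    """Mean template copies per droplet from droplet counts.

    λ = −ln(1 − positives/total), the Poisson rate at which the probability
    of an empty droplet equals the observed negative fraction.
    """
    if total <= 0:
        raise ValueError(f"droplets_total must be positive, got {total}")
    if positives < 0 or positives > total:
        raise ValueError(
            f"droplets_positive must be in [0, total], got {positives}/{total}"
        )
    if positives == total:
        raise SaturationError(
            f"all {total} droplets positive; lambda undefined (saturated assay)"
        )
    return -math.log(1.0 - positives / total)


def concentration_copies_per_ul(
    lam: float, droplet_volume_nl: float = DEFAULT_DROPLET_VOLUME_NL
) -> float:
    """Template concentration in copies/µL (reporting only; cancels in CN)."""
    if droplet_volume_nl <= 0:
        raise ValueError("droplet volume must be positive")
    return lam / (droplet_volume_nl * 1e-3)


def normalized_copy_number(
    lambda_target: float, lambda_reference: float, reference_diploid_cn: float = 2.0
) -> float:
    """Diploid CN of the target from the target/reference λ ratio."""
    if lambda_reference <= 0:
        raise ValueError(
            f"lambda_reference must be positive, got {lambda_reference}"
        )
    if lambda_target < 0:
        raise ValueError(f"lambda_target must be >= 0, got {lambda_target}")
    return reference_diploid_cn * lambda_target / lambda_reference


class DdpcrQuantifier(BaseEstimator, TransformerMixin):
    """Turn a well table into per-sample per-gene copy-number estimates.

    Input is a tidy DataFrame with columns ``sample, gene, role,
    droplets_total, droplets_positive`` where role is ``target`` or
    ``reference``. Replicate wells for one (sample, assay) are pooled by
    summing droplet counts before λ estimation.

    Parameters
    ----------
    reference_diploid_cn : float, default 2
        Diploid copy number of the reference gene.
    droplet_volume_nl : float, default 0.85
        Droplet volume, used only for the reported concentration column.
    """

    def __init__(
        self,
        reference_diploid_cn: float = 2.0,
        droplet_volume_nl: float = DEFAULT_DROPLET_VOLUME_NL,
    ):
        self.reference_diploid_cn = reference_diploid_cn
        self.droplet_volume_nl = droplet_volume_nl

    def fit(self, X=None, y=None):
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        """Per (sample, target gene): λs, concentration and normalized CN."""
        missing = set(WELL_COLUMNS) - set(X.columns)
        if missing:
            raise ValueError(f"well table missing columns {sorted(missing)}")
        bad_roles = set(X["role"]) - {"target", "reference"}
        if bad_roles:
            raise ValueError(f"unknown well roles {sorted(bad_roles)}")

        pooled = (
            X.groupby(["sample", "role", "gene"], sort=False)[
                ["droplets_total", "droplets_positive"]
            ]
            .sum()
            .reset_index()
        )
        lambdas = {
            (row["sample"], row["role"], row["gene"]): poisson_lambda(
                int(row["droplets_positive"]), int(row["droplets_total"])
            )
            for _, row in pooled.iterrows()
        }
        ref_lambda: dict = {}
        for (sample, role, gene), lam in lambdas.items():
            if role == "reference":
                ref_lambda[sample] = lam

        rows = []
        for _, row in pooled[pooled["role"] == "target"].iterrows():
            sample, gene = row["sample"], row["gene"]
            if sample not in ref_lambda:
                raise ValueError(f"sample {sample!r} has no reference well")
            lam_t = lambdas[(sample, "target", gene)]
            lam_r = ref_lambda[sample]
            rows.append(
                {
                    "sample": sample,
                    "assay_group": gene,
                    "lambda_target": lam_t,
                    "lambda_reference": lam_r,
                    "concentration_target_per_ul": concentration_copies_per_ul(
                        lam_t, self.droplet_volume_nl
                    ),
                    "cn": normalized_copy_number(
                        lam_t, lam_r, self.reference_diploid_cn
                    ),
                }
            )
        return pd.DataFrame(
            rows,
            columns=[
                "sample",
                "assay_group",
                "lambda_target",
                "lambda_reference",
                "concentration_target_per_ul",
                "cn",
            ],
        )


def quantify_wells(
    wells: pd.DataFrame,
    reference_diploid_cn: float = 2.0,
    droplet_volume_nl: float = DEFAULT_DROPLET_VOLUME_NL,
) -> pd.DataFrame:
    """Thin wrapper over :class:`DdpcrQuantifier`."""
    return DdpcrQuantifier(
        reference_diploid_cn=reference_diploid_cn,
        droplet_volume_nl=droplet_volume_nl,
    ).fit().transform(wells)


def classify_ddpcr(
    results: pd.DataFrame, expected_cn=None, fraction: float = 0.25
) -> pd.DataFrame:
    """Call ddPCR copy numbers with the shared fractional threshold rule.

    Identical contract to the sequencing-based caller: with fraction 0.25 a
    two-copy gene is called at <1.5 / >2.5 and the six-copy *DEFB103* group
    at <4.5 / >7.5.
    """
    wide = results.pivot(index="sample", columns="assay_group", values="cn")
    calls = CnvCaller(fraction=fraction, expected_cn=expected_cn).fit().predict(wide)
    return calls.dropna(subset=["estimate"]).reset_index(drop=True)


@dataclass(frozen=True)
class ConcordanceReport:
    """Agreement between ddPCR and sequencing-based CN for matched samples."""

    n: int
    pearson_r: float
    mean_bias: float  # mean(ddPCR − WGS)
    call_agreement: float  # fraction of identical categorical calls


def concordance(
    wgs_cn: pd.DataFrame,
    ddpcr_results: pd.DataFrame,
    expected_cn=None,
    fraction: float = 0.25,
) -> ConcordanceReport:
    """Compare matched ddPCR and read-depth estimates.

    Matches on (sample, assay_group); requires at least 3 matched
    observations. ``mean_bias`` is the mean ddPCR − WGS difference;
    ``call_agreement`` the fraction of matched observations receiving the
    same categorical call under the shared threshold rule.
    """
    ddpcr_long = ddpcr_results[["sample", "assay_group", "cn"]]
    wgs_long = (
        wgs_cn.stack().rename("wgs_cn").reset_index()
    )
    wgs_long.columns = ["sample", "assay_group", "wgs_cn"]
    merged = ddpcr_long.merge(wgs_long, on=["sample", "assay_group"], how="inner")
    merged = merged.dropna(subset=["cn", "wgs_cn"])
    if len(merged) == 0:
        raise ValueError("no matched sample x gene observations")
    if len(merged) < 3:
        raise ValueError(
            f"need >= 3 matched observations for concordance, got {len(merged)}"
        )
    if merged["cn"].std(ddof=0) == 0 or merged["wgs_cn"].std(ddof=0) == 0:
        r = float("nan")
    else:
        r = float(np.corrcoef(merged["cn"], merged["wgs_cn"])[0, 1])
    bias = float((merged["cn"] - merged["wgs_cn"]).mean())

    caller = CnvCaller(fraction=fraction, expected_cn=expected_cn).fit()
    agree = [
        caller.rule_.call(row["cn"], caller._expected(row["assay_group"]))
        == caller.rule_.call(row["wgs_cn"], caller._expected(row["assay_group"]))
        for _, row in merged.iterrows()
    ]
    return ConcordanceReport(
        n=len(merged),
        pearson_r=r,
        mean_bias=bias,
        call_agreement=float(np.mean(agree)),
    )
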