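"""Expected-copy-scaled threshold calling, shared by the sequencing and ddPCR
quantification paths.

A single fractional rule reproduces both printed threshold sets: with
fraction 0.25, a two-copy gene is called at <1.5 / >2.5 and the six-copy
*DEFB103* group at <4.5 / >7.5.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

__all__ = ["ThresholdRule", "CnvCaller", "call_cnv", "CALL_DELETION", "CALL_NORMAL", "CALL_DUPLICATION"]

# For multi-copy groups "deletion"/"duplication" read as low/high copy number.
CALL_DELETION = "deletion"
CALL_NORMAL = "normal"
CALL_DUPLICATION = "duplication"


@dataclass(frozen=True)
class ThresholdRule:
    """Call band as a fraction of the expected diploid copy number.

    lower = expected_cn * (1 - fraction), upper = expected_cn * (1 + fraction);
    estimates strictly below ``lower`` are deletions (low copy number),
    strictly above ``upper`` duplications (high copy number).
    """

    fraction: float = 0.25

    def __post_init__(self) -> None:
        if not 0 < self.fraction < 1:
            raise ValueError(f"fraction must be in (0, 1), got {self.fraction}")

    def lower(self, expected_cn: float) -> float:
        return expected_cn * (1 - self.fraction)

    def upper(self, expected_cn: float) -> float:
        return expected_cn * (1 + self.fraction)

    def call(self, estimate: float, expected_cn: float) -> str:
        if np.isnan(estimate):
            return "missing"
        if estimate < self.lower(expected_cn):
            return CALL_DELETION
        if estimate > self.upper(expected_cn):
            return CALL_DUPLICATION
        return CALL_NORMAL


class CnvCaller(BaseEstimator):
    """Classify copy-number estimates against expected values.

    Parameters
    ----------
    fraction : float, default 0.25
        Half-width of the "normal" band as a fraction of expected CN.
    expected_cn : mapping or None
        Expected diploid CN per assay group. Groups absent from the mapping
        (or all groups, when None) default to 2.
    """

    def __init__(self, fraction: float = 0.25, expected_cn=None):
        self.fraction = fraction
        self.expected_cn = expected_cn

    def fit(self, X=None, y=None):
        self.rule_ = ThresholdRule(self.fraction)
        return self

    def _expected(self, group: str) -> float:
        if self.expected_cn is None:
            return 2.0
        try:
            return float(self.expected_cn[group])
        except KeyError:
            return 2.0

    def predict(self, X: pd.DataFrame) -> pd.DataFrame:
        """Tidy call table for a samples x assay-groups CN matrix.

        Returns a DataFrame with columns sample, assay_group, estimate,
        expected_cn, call. NaN estimates (undefined normalization) are
        reported as "missing", never as a CNV call.
        """
        if not hasattr(self, "rule_"):
            self.fit()
        rows = []
        for group in X.columns:
            expected = self._expected(group)
            for sample, est in X[group].items():
                rows.append(
                    {
                        "sample": sample,
                        "assay_group": group,
                        "estimate": float(est),
                        "expected_cn": expected,
                        "call": self.rule_.call(float(est), expected),
                    }
                )
        return pd.DataFrame(rows, columns=["sample", "assay_group", "estimate", "expected_cn", "call"])


def call_cnv(
    cn: pd.DataFrame,
    expected_cn=None,
    fraction: float = 0.25,
) -> pd.DataFrame:
    """Call deletions/duplications from a CN matrix (thin wrapper over
    :class:`CnvCaller`)."""
    return CnvCaller(fraction=fraction, expected_cn=expected_cn).fit().predict(cn)
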