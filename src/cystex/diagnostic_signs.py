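"""Diagnostic accuracy of reader-assessed binary MRI signs.

The two classic endometrioma signs — "T2 shading" (signal loss between
T1- and T2-weighted images) and "T2 dark spots" (discrete hypointense
foci from retracted clot) — are read by humans; this module only scores
consensus annotations against the reference diagnosis, reporting
sensitivity, specificity and accuracy with exact 95% confidence
intervals.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping

import pandas as pd

from .errors import DataError
from .stats_pipeline import clopper_pearson

T2_SHADING = "T2_shading"
T2_DARK_SPOTS = "T2_dark_spots"
SIGNS = (T2_SHADING, T2_DARK_SPOTS)


@dataclasses.dataclass
class ContingencyMetrics:
    """2x2 contingency counts and derived proportions (with 95% CIs)."""

    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float
    sensitivity_ci: tuple[float, float]
    specificity: float
    specificity_ci: tuple[float, float]
    accuracy: float
    accuracy_ci: tuple[float, float]

    @classmethod
    def from_counts(cls, tp: int, fp: int, tn: int, fn: int, level: float = 0.95):
        if min(tp, fp, tn, fn) < 0:
            raise DataError("contingency counts must be non-negative")
        n_pos, n_neg = tp + fn, tn + fp
        total = n_pos + n_neg
        if n_pos == 0 or n_neg == 0:
            raise DataError("both classes must be represented")
        return cls(
            tp=tp, fp=fp, tn=tn, fn=fn,
            sensitivity=tp / n_pos,
            sensitivity_ci=clopper_pearson(tp, n_pos, level),
            specificity=tn / n_neg,
            specificity_ci=clopper_pearson(tn, n_neg, level),
            accuracy=(tp + tn) / total,
            accuracy_ci=clopper_pearson(tp + tn, total, level),
        )

    @classmethod
    def from_sign_counts(
        cls, pos_with_sign: int, n_pos: int, neg_with_sign: int, n_neg: int,
        level: float = 0.95,
    ):
        """Build from 'sign present in a/N positives and b/M negatives'."""
        return cls.from_counts(
            tp=pos_with_sign,
            fn=n_pos - pos_with_sign,
            fp=neg_with_sign,
            tn=n_neg - neg_with_sign,
            level=level,
        )

    def to_row(self) -> dict:
        pct = lambda x: 100.0 * x
        return {
            "tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn,
            "accuracy_pct": pct(self.accuracy),
            "accuracy_ci_low": pct(self.accuracy_ci[0]),
            "accuracy_ci_high": pct(self.accuracy_ci[1]),
            "sensitivity_pct": pct(self.sensitivity),
            "sensitivity_ci_low": pct(self.sensitivity_ci[0]),
            "sensitivity_ci_high": pct(self.sensitivity_ci[1]),
            "specificity_pct": pct(self.specificity),
            "specificity_ci_low": pct(self.specificity_ci[0]),
            "specificity_ci_high": pct(self.specificity_ci[1]),
        }


def sign_accuracy(
    annotations: pd.DataFrame, truth: Mapping[str, bool]
) -> dict[str, ContingencyMetrics]:
    """Score each annotated sign against the reference diagnosis.

    ``annotations`` has columns ``lesion_id, sign, present`` (one record
    per lesion per sign); ``truth`` maps lesion_id to True for the
    positive (endometrioma) class.  Every annotated lesion must carry a
    truth label.
    """
    required = {"lesion_id", "sign", "present"}
    missing = required - set(annotations.columns)
    if missing:
        raise DataError(f"annotations missing columns {sorted(missing)}")
    if annotations.duplicated(["lesion_id", "sign"]).any():
        raise DataError("duplicate (lesion_id, sign) annotation records")

    out = {}
    for sign, group in annotations.groupby("sign"):
        tp = fp = tn = fn = 0
        for rec in group.itertuples(index=False):
            lid = str(rec.lesion_id)
            if lid not in truth:
                raise DataError(f"lesion {lid!r} has no truth label")
            present = bool(rec.present)
            if truth[lid]:
                tp += present
                fn += not present
            else:
                fp += present
                tn += not present
        out[str(sign)] = ContingencyMetrics.from_counts(tp, fp, tn, fn)
    return out


def signs_report(metrics: dict[str, ContingencyMetrics]) -> pd.DataFrame:
    """Tabular layout of per-sign accuracy metrics (percent scale)."""
    return pd.DataFrame(
        {sign: m.to_row() for sign, m in metrics.items()}
    ).T.rename_axis("sign")
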