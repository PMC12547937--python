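"""Plate-based secretion normalization and fold-change statistics.

Each ELISA plate carries its own basal (vehicle) wells; every well's analyte
concentration is expressed as a fold change over the mean basal concentration
of the same plate, which removes plate-to-plate scale. Wells outside the
assay's validated range are flagged and excluded from means by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["normalize_plate", "condition_test", "ConditionTestResult"]

ASSAY_RANGE = (0.015, 2.5)  # ng/mL


def normalize_plate(
    table: pd.DataFrame,
    basal_label: str = "basal",
    include_out_of_range: bool = False,
) -> pd.DataFrame:
    """Per-well fold changes over the same-plate mean basal concentration.

    ``table`` needs columns plate_id, well, condition, ng_per_ml and
    optionally in_range. Basal wells get folds relative to their own plate
    mean (so basal folds average exactly 1 per plate). Out-of-range wells are
    dropped from the basal mean and from the output unless
    ``include_out_of_range``.
    """
    required = {"plate_id", "well", "condition", "ng_per_ml"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"plate table missing column(s) {sorted(missing)}")
    df = table.copy()
    if "in_range" not in df.columns:
        df["in_range"] = df["ng_per_ml"].between(*ASSAY_RANGE)
    if (df["ng_per_ml"] < 0).any():
        raise ValueError("negative analyte concentration")
    if not include_out_of_range:
        df = df[df["in_range"]].copy()
    out = []
    for plate_id, g in df.groupby("plate_id", sort=False):
        basal = g.loc[g["condition"] == basal_label, "ng_per_ml"]
        if basal.empty:
            raise ValueError(f"plate {plate_id!r} has no usable basal wells")
        basal_mean = float(basal.mean())
        if basal_mean <= 0:
            raise ValueError(f"plate {plate_id!r}: non-positive mean basal")
        g = g.copy()
        g["fold"] = g["ng_per_ml"] / basal_mean
        out.append(g)
    return pd.concat(out, ignore_index=True)


@dataclass(frozen=True)
class ConditionTestResult:
    condition: str
    n: int
    mean_fold: float
    ci_low: float
    ci_high: float
    p_value: float  # one-sample t vs 1, two-sided; nan when degenerate
    degenerate: bool  # zero variance: no evidence either way


def condition_test(
    folds: np.ndarray | pd.Series, condition: str = "", confidence: float = 0.95
) -> ConditionTestResult:
    """Mean fold change with 95% CI and a one-sample t-test against 1.

    Zero-variance inputs (all folds identical) are returned flagged as
    degenerate with an undefined p rather than raising.
    """
    x = np.asarray(folds, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 fold values per condition")
    mean = float(x.mean())
    sd = float(x.std(ddof=1))
    n = x.size
    if sd == 0:
        return ConditionTestResult(condition, n, mean, mean, mean, float("nan"), True)
    sem = sd / np.sqrt(n)
    tcrit = stats.t.ppf(0.5 + confidence / 2.0, df=n - 1)
    t_res = stats.ttest_1samp(x, popmean=1.0)
    return ConditionTestResult(
        condition=condition,
        n=n,
        mean_fold=mean,
        ci_low=mean - tcrit * sem,
        ci_high=mean + tcrit * sem,
        p_value=float(t_res.pvalue),
        degenerate=False,
    )
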