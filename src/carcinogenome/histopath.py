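"""Histopathology-derived binary scoring and concordance reporting.

Short-term pathology findings are coded as ordinal covariates in
{0..4} per sample (0: not observed, 4: severe). The data-driven score is
the logical OR over all covariates: a sample is pathology-positive if
any finding was observed at all. Confident classifier calls are compared
against such scores, treating the score as the gold standard, with
Wilson 95% intervals per reported proportion.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from carcinogenome.core import ValidationError


def validate_histopathology(table: pd.DataFrame) -> pd.DataFrame:
    """Check covariate values are ordinals in {0..4} with no gaps."""
    covs = [c for c in table.columns if c != "manual_score"]
    if not covs:
        raise ValidationError("no covariate columns")
    values = table[covs]
    if values.isna().any().any():
        bad = values.index[values.isna().any(axis=1)][0]
        raise ValidationError(f"missing covariate value in row {bad!r}")
    arr = values.to_numpy()
    if not np.isin(arr, [0, 1, 2, 3, 4]).all():
        raise ValidationError("covariates must take values in {0,1,2,3,4}")
    return table


def h_score_d(table: pd.DataFrame) -> pd.Series:
    """Data-driven binary pathology score: positive iff any covariate > 0."""
    validate_histopathology(table)
    covs = [c for c in table.columns if c != "manual_score"]
    return (table[covs] > 0).any(axis=1).rename("h_score_d")


def _wilson(successes: int, total: int) -> tuple[float, float]:
    if total == 0:
        return (np.nan, np.nan)
    lo, hi = proportion_confint(successes, total, alpha=0.05, method="wilson")
    return float(lo), float(hi)


def concordance_report(calls: pd.Series, scores: pd.Series) -> pd.DataFrame:
    """Metric suite of confident calls against a pathology gold standard.

    ``calls`` holds boolean confident classifier calls (from
    ``confidence_filter``); ``scores`` boolean pathology positivity. Rows
    are accuracy, sensitivity, specificity, PPV, NPV and FDR, each with
    its Wilson 95% interval over its own denominator.
    """
    shared = [s for s in calls.index if s in set(scores.index)]
    if not shared:
        raise ValidationError("no samples shared between calls and scores")
    c = calls.loc[shared].astype(bool)
    g = scores.loc[shared].astype(bool)
    tp = int((c & g).sum())
    fp = int((c & ~g).sum())
    fn = int((~c & g).sum())
    tn = int((~c & ~g).sum())
    n = tp + fp + fn + tn
    rows = {
        "accuracy": (tp + tn, n),
        "sensitivity": (tp, tp + fn),
        "specificity": (tn, tn + fp),
        "ppv": (tp, tp + fp),
        "npv": (tn, tn + fn),
    }
    out = []
    for name, (k, tot) in rows.items():
        est = k / tot if tot else np.nan
        lo, hi = _wilson(k, tot)
        out.append({"metric": name, "estimate": est, "ci_low": lo, "ci_high": hi, "n": tot})
    # FDR = 1 - PPV, interval mirrored
    ppv_row = out[3]
    out.append(
        {
            "metric": "fdr",
            "estimate": 1.0 - ppv_row["estimate"] if not np.isnan(ppv_row["estimate"]) else np.nan,
            "ci_low": 1.0 - ppv_row["ci_high"],
            "ci_high": 1.0 - ppv_row["ci_low"],
            "n": ppv_row["n"],
        }
    )
    return pd.DataFrame(out).set_index("metric")
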