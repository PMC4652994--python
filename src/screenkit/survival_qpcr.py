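"""Supporting analytics: Kaplan-Meier survival and comparative-Ct qPCR.

Kaplan-Meier estimation and the two-group log-rank test are delegated to
lifelines; relative quantification follows the comparative cycle threshold
(delta-delta-Ct) method with an assumed amplification efficiency of exactly
2 per cycle and replicate Ct values averaged before normalization.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank

from .errors import InvalidParameterError


def km_estimate(table: pd.DataFrame, group_col: str = "group") -> dict:
    """Product-limit survival estimate per group.

    ``table`` needs columns time_days, event (1 = death observed) and the
    group column.  Returns, per group, the step function (DataFrame with
    time and survival columns) and the median survival time — the smallest
    time with S(t) <= 0.5, NaN when never reached.
    """
    if (table["time_days"] <= 0).any():
        raise InvalidParameterError("survival times must be positive")
    out = {}
    for name, sub in table.groupby(group_col):
        if len(sub) == 0:
            raise InvalidParameterError(f"empty group {name!r}")
        kmf = KaplanMeierFitter()
        kmf.fit(sub["time_days"], sub["event"])
        step = kmf.survival_function_.reset_index()
        step.columns = ["time", "survival"]
        median = float(kmf.median_survival_time_)
        out[name] = {
            "curve": step,
            "median": median if np.isfinite(median) else np.nan,
            "n": int(len(sub)),
            "events": int(sub["event"].sum()),
        }
    return out


def logrank(table: pd.DataFrame, group_a: str, group_b: str, group_col: str = "group") -> tuple:
    """Two-group log-rank test (1 df); returns (chi-square, p)."""
    a = table[table[group_col] == group_a]
    b = table[table[group_col] == group_b]
    if len(a) < 1 or len(b) < 1:
        raise InvalidParameterError("both groups need >=1 subject")
    if a["event"].sum() + b["event"].sum() == 0:
        return 0.0, 1.0
    res = _ll_logrank(
        a["time_days"], b["time_days"], event_observed_A=a["event"], event_observed_B=b["event"]
    )
    stat = float(res.test_statistic)
    p = float(res.p_value)
    if not np.isfinite(stat):  # e.g. identical degenerate groups
        return 0.0, 1.0
    return stat, p


def ddct(
    ct_table: pd.DataFrame,
    reference_gene: str,
    calibrator_sample: str,
) -> pd.DataFrame:
    """Comparative-Ct relative quantities, 2^(-ddCt).

    Replicates are averaged per sample x gene first; dCt = Ct_target -
    Ct_reference within each sample; ddCt subtracts the calibrator's dCt.
    Samples missing the reference gene are skipped with a warning.
    """
    needed = {"sample", "gene", "ct"}
    if not needed <= set(ct_table.columns):
        raise InvalidParameterError(f"Ct table needs columns {sorted(needed)}")
    mean_ct = ct_table.groupby(["sample", "gene"])["ct"].mean().unstack("gene")
    if reference_gene not in mean_ct.columns:
        raise InvalidParameterError(f"reference gene {reference_gene!r} absent")
    if calibrator_sample not in mean_ct.index:
        raise InvalidParameterError(f"calibrator sample {calibrator_sample!r} absent")
    has_ref = mean_ct[reference_gene].notna()
    skipped = mean_ct.index[~has_ref].tolist()
    if skipped:
        warnings.warn(f"samples missing reference gene skipped: {skipped}", stacklevel=2)
    mean_ct = mean_ct[has_ref]
    dct = mean_ct.sub(mean_ct[reference_gene], axis=0)
    ddct_mat = dct - dct.loc[calibrator_sample]
    rq = np.power(2.0, -ddct_mat)
    out = rq.drop(columns=[reference_gene]).stack().rename("relative_quantity").reset_index()
    out.columns = ["sample", "gene", "relative_quantity"]
    dd = ddct_mat.drop(columns=[reference_gene]).stack().to_numpy()
    out["ddct"] = dd
    return out
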