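"""Candidate tumor-suppressor selection from paired CNV/expression cohorts.

A gene is nominated when (a) its linear copy number falls strictly below a
cutoff (default 1.6, vs 2.0 diploid) in strictly more than a given fraction
of tumors (default 15%), and (b) it is significantly underexpressed in
tumors versus normals (Welch t-test, Benjamini-Hochberg adjusted).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import InvalidParameterError


def deletion_frequency(
    cnv: pd.DataFrame, tumor_samples, cn_thresh: float = 1.6
) -> pd.Series:
    """Fraction of tumor samples with copy number strictly below ``cn_thresh``.

    Missing values are excluded from both numerator and denominator; a gene
    with all-missing CNV gets NaN.
    """
    if cn_thresh <= 0:
        raise InvalidParameterError("cn_thresh must be > 0")
    tumor_samples = list(tumor_samples)
    if not tumor_samples:
        raise InvalidParameterError("need >=1 tumor sample")
    sub = cnv[tumor_samples]
    below = (sub < cn_thresh).sum(axis=1)
    observed = sub.notna().sum(axis=1)
    frac = below / observed.replace(0, np.nan)
    return frac.rename("deletion_fraction")


def differential_expression(
    expr: pd.DataFrame, tumor_samples, normal_samples
) -> pd.DataFrame:
    """Per-gene Welch t-test of tumor vs normal with BH adjustment.

    Returns columns statistic, p, q, direction (sign of tumor - normal mean
    difference).  Genes with zero variance in both groups and equal means
    get p = 1 by convention; zero variance with unequal means gets p = 0.
    """
    tumor_samples, normal_samples = list(tumor_samples), list(normal_samples)
    if len(tumor_samples) < 2 or len(normal_samples) < 2:
        raise InvalidParameterError("need >=2 samples per group")
    a = expr[tumor_samples].to_numpy(dtype=float)
    b = expr[normal_samples].to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        res = stats.ttest_ind(a, b, axis=1, equal_var=False, nan_policy="omit")
        stat = np.asarray(res.statistic, dtype=float)
        p = np.asarray(res.pvalue, dtype=float)
    mean_a = np.nanmean(a, axis=1)
    mean_b = np.nanmean(b, axis=1)
    diff = mean_a - mean_b
    degenerate = np.isnan(p)
    p = np.where(degenerate & (diff == 0), 1.0, p)
    p = np.where(degenerate & (diff != 0), 0.0, p)
    stat = np.where(np.isnan(stat), 0.0, stat)
    q = multipletests(p, method="fdr_bh")[1]
    return pd.DataFrame(
        {
            "statistic": stat,
            "p": p,
            "q": q,
            "direction": np.sign(diff),
            "mean_tumor": mean_a,
            "mean_normal": mean_b,
        },
        index=expr.index,
    )


def select_candidates(
    cnv: pd.DataFrame,
    expr: pd.DataFrame,
    labels: pd.Series,
    cn_thresh: float = 1.6,
    frac_thresh: float = 0.15,
    alpha: float = 0.05,
    mutation_annotation: pd.Series | None = None,
) -> pd.DataFrame:
    """Apply the deletion-frequency + underexpression filters jointly.

    ``labels`` maps sample -> {"tumor", "normal"}.  A gene is selected when
    deletion_fraction > frac_thresh (strict), BH q < alpha, and the tumor
    mean lies below the normal mean.  Output is sorted by deletion_fraction
    descending, ties broken by gene symbol.  ``mutation_annotation`` is an
    optional user-supplied per-gene pass-through column.
    """
    genes = cnv.index.intersection(expr.index)
    if len(genes) == 0:
        raise InvalidParameterError("no overlap between CNV and expression genes")
    tumors = labels.index[labels == "tumor"]
    normals = labels.index[labels == "normal"]
    tumors_cn = [s for s in tumors if s in cnv.columns]
    tumors_ex = [s for s in tumors if s in expr.columns]
    normals_ex = [s for s in normals if s in expr.columns]
    frac = deletion_frequency(cnv.loc[genes], tumors_cn, cn_thresh)
    de = differential_expression(expr.loc[genes], tumors_ex, normals_ex)
    out = pd.DataFrame(
        {
            "deletion_fraction": frac,
            "de_statistic": de["statistic"],
            "de_p": de["p"],
            "de_q": de["q"],
            "direction": de["direction"],
        },
        index=genes,
    )
    out["selected"] = (
        (out["deletion_fraction"] > frac_thresh)
        & (out["de_q"] < alpha)
        & (out["direction"] < 0)
    )
    if mutation_annotation is not None:
        out["mutation_frequency"] = mutation_annotation.reindex(genes)
    out = out.rename_axis("gene").reset_index()
    out = out.sort_values(
        ["deletion_fraction", "gene"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    return out
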