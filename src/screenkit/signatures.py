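"""Metagene activity scoring, subtype assignment and marker stratification.

Activity of a gene set (e.g. a WNT or mesenchymal signature) is the mean of
row-standardized (z-scored) expression over the set's genes present in the
matrix.  Subtypes are assigned by nearest centroid under Pearson
correlation; cohorts are stratified into marker-high/low groups either by
quartile or by a fixed number of extreme samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InvalidParameterError

SUBTYPE_ORDER = ("Proneural", "Neural", "Classical", "Mesenchymal")


@dataclass(frozen=True)
class GeneSet:
    name: str
    genes: tuple

    def __init__(self, name: str, genes):
        # dedupe preserving order
        seen, out = set(), []
        for g in genes:
            if g not in seen:
                seen.add(g)
                out.append(g)
        if not out:
            raise InvalidParameterError(f"gene set {name!r} is empty")
        object.__setattr__(self, "name", name)
        object.__setattr__(self, "genes", tuple(out))

    def __len__(self):
        return len(self.genes)


def zscore(expr: pd.DataFrame) -> pd.DataFrame:
    """Row-standardize: per gene, mean 0 and population SD 1 across samples.

    Zero-variance genes are set to 0 with a warning.
    """
    if expr.shape[1] < 2:
        raise InvalidParameterError("z-scoring needs >=2 samples")
    vals = expr.to_numpy(dtype=float)
    mu = vals.mean(axis=1, keepdims=True)
    sd = vals.std(axis=1, keepdims=True)  # population SD (n denominator)
    flat = (sd == 0).ravel()
    if flat.any():
        warnings.warn(
            f"{int(flat.sum())} zero-variance gene(s) set to 0", stacklevel=2
        )
    sd_safe = np.where(sd == 0, 1.0, sd)
    out = (vals - mu) / sd_safe
    out[flat, :] = 0.0
    return pd.DataFrame(out, index=expr.index, columns=expr.columns)


def metagene_score(expr: pd.DataFrame, gene_set: GeneSet) -> pd.Series:
    """Per-sample activity: mean z-scored expression over present set genes."""
    present = [g for g in gene_set.genes if g in expr.index]
    missing = [g for g in gene_set.genes if g not in expr.index]
    if not present:
        raise InvalidParameterError(f"no genes of set {gene_set.name!r} in matrix")
    if len(present) < 5:
        warnings.warn(
            f"only {len(present)} gene(s) of set {gene_set.name!r} present", stacklevel=2
        )
    z = zscore(expr)
    score = z.loc[present].mean(axis=0).rename(gene_set.name)
    score.attrs["missing_genes"] = missing
    return score


def build_centroids(expr: pd.DataFrame, labels: pd.Series) -> pd.DataFrame:
    """Per-subtype mean of z-scored expression from labeled training samples."""
    z = zscore(expr)
    cols = {}
    for subtype in labels.unique():
        members = labels.index[labels == subtype]
        cols[subtype] = z[members].mean(axis=1)
    return pd.DataFrame(cols)


def assign_subtype(expr: pd.DataFrame, centroids: pd.DataFrame) -> pd.DataFrame:
    """Nearest-centroid subtype call by Pearson correlation on shared genes.

    Ties break by the fixed subtype order (Proneural, Neural, Classical,
    Mesenchymal); zero-variance sample profiles are left unassigned.
    Returns the per-subtype correlations plus the ``subtype`` column.
    """
    shared = expr.index.intersection(centroids.index)
    if len(shared) < 10:
        raise InvalidParameterError(f"only {len(shared)} genes shared with centroids")
    order = [s for s in SUBTYPE_ORDER if s in centroids.columns] + [
        s for s in centroids.columns if s not in SUBTYPE_ORDER
    ]
    c = centroids.loc[shared, order].to_numpy(dtype=float)
    # Pearson over genes is invariant to per-sample affine maps, so the raw
    # profile is correlated directly; centroids live in z-space by construction
    x = expr.loc[shared].to_numpy(dtype=float)
    xc = x - x.mean(axis=0, keepdims=True)
    cc = c - c.mean(axis=0, keepdims=True)
    xn = np.linalg.norm(xc, axis=0)
    cn = np.linalg.norm(cc, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = (xc.T @ cc) / np.outer(xn, cn)
    out = pd.DataFrame(corr, index=expr.columns, columns=order)
    degenerate = xn == 0
    best = np.argmax(np.nan_to_num(corr, nan=-2.0), axis=1)
    calls = np.array(order, dtype=object)[best]
    calls[degenerate] = None
    out["subtype"] = calls
    return out


def stratify(
    expr_or_values,
    marker_gene: str | None = None,
    mode: str = "quartile",
    n: int | None = None,
) -> pd.Series:
    """Split samples into marker high / low / mid groups.

    ``quartile`` mode: high = top 25%, low = bottom 25% by marker value.
    ``extreme_n`` mode: exactly ``n`` highest and ``n`` lowest.  Ties break
    deterministically by sample-ID order.
    """
    if isinstance(expr_or_values, pd.DataFrame):
        if marker_gene not in expr_or_values.index:
            raise InvalidParameterError(f"marker gene {marker_gene!r} not in matrix")
        values = expr_or_values.loc[marker_gene]
    else:
        values = expr_or_values
    values = values.sort_index(kind="mergesort")
    order = values.sort_values(kind="mergesort")  # stable: ties by sample ID
    m = len(values)
    if mode == "quartile":
        k = m // 4
    elif mode == "extreme_n":
        if n is None:
            raise InvalidParameterError("extreme_n mode requires n")
        if n > m // 2:
            raise InvalidParameterError(f"n={n} exceeds half the cohort ({m} samples)")
        k = n
    else:
        raise InvalidParameterError(f"unknown mode {mode!r}")
    groups = pd.Series("mid", index=values.index, name="marker_group")
    groups.loc[order.index[:k]] = "low"
    groups.loc[order.index[-k:]] = "high"
    return groups


def activity_correlation(
    scores_a: pd.Series, scores_b: pd.Series, samples=None
) -> tuple:
    """Pearson r (and two-sided t-transform p) between two activity scores."""
    if samples is not None:
        scores_a = scores_a.loc[list(samples)]
        scores_b = scores_b.loc[list(samples)]
    a, b = scores_a.align(scores_b, join="inner")
    if len(a) < 3:
        raise InvalidParameterError("need >=3 samples for correlation")
    if a.std() == 0 or b.std() == 0:
        raise InvalidParameterError("zero variance in an activity score")
    r, p = stats.pearsonr(a, b)
    return float(r), float(p)


def group_composition(subtypes: pd.Series, group_samples) -> pd.Series:
    """Subtype percentages (summing to 100) within a sample group."""
    group_samples = list(group_samples)
    if not group_samples:
        raise InvalidParameterError("empty group")
    sub = subtypes.loc[group_samples]
    pct = sub.value_counts(normalize=True) * 100.0
    return pct.reindex(
        [s for s in SUBTYPE_ORDER if s in pct.index]
        + [s for s in pct.index if s not in SUBTYPE_ORDER]
    ).rename("percent")
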