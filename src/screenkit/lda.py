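"""Limiting-dilution analysis under the single-hit Poisson model.

Cells are seeded at a range of doses; a well stays negative (no sphere) when
it received zero clonogenic cells, so P(negative | dose d) = exp(-f d) where
f is the clonogenic frequency.  The primary estimator regresses
ln(negative fraction) on dose through the origin by weighted least squares;
-slope estimates f, reported as the familiar "1 in N cells" reciprocal.

A literal unweighted regression of raw negative-well counts on dose
(``fit_lda_raw``) is retained for comparison with historical "x-intercept"
recipes; it is not the primary estimator because raw counts do not decay
linearly in dose under the single-hit model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InvalidParameterError, NoGrowthError, SaturatedError


@dataclass
class LdaExperiment:
    """Well outcomes of one limiting-dilution assay condition."""

    condition: str
    data: pd.DataFrame  # columns: dose, wells, negative_wells

    def __post_init__(self):
        d = self.data
        for col in ("dose", "wells", "negative_wells"):
            if col not in d.columns:
                raise InvalidParameterError(f"LDA table missing column {col!r}")
        if (d["dose"] <= 0).any():
            raise InvalidParameterError("doses must be positive")
        if ((d["negative_wells"] < 0) | (d["negative_wells"] > d["wells"])).any():
            raise InvalidParameterError("negative_wells must lie in [0, wells]")

    @classmethod
    def from_tsv(cls, path, condition: str | None = None) -> "LdaExperiment":
        df = pd.read_csv(path, sep="\t", comment="#")
        cond = condition or (df["condition"].iloc[0] if "condition" in df else "unknown")
        return cls(cond, df[["dose", "wells", "negative_wells"]])

    def to_tsv(self, path):
        out = self.data.copy()
        out.insert(0, "condition", self.condition)
        out.to_csv(path, sep="\t", index=False)


@dataclass
class LdaFit:
    """Fitted clonogenic frequency with Wald CI and goodness of fit."""

    condition: str
    frequency: float
    slope_se: float
    ci95: tuple
    gof_p: float
    excluded_doses: list = field(default_factory=list)
    n_doses_used: int = 0

    @property
    def reciprocal(self) -> float:
        return 1.0 / self.frequency

    @property
    def display(self) -> str:
        return f"1/{round(self.reciprocal):d}"


def fit_lda(exp: LdaExperiment) -> LdaFit:
    """Weighted log-linear fit of the negative-well fraction.

    Doses where every well grew (negative_wells = 0) are excluded with a
    warning, since ln(0) is undefined; doses where no well grew are retained.
    Weights are the delta-method inverse variances of ln(p-hat),
    wells * p / (1 - p), with a half-well continuity adjustment at p = 1.
    """
    d = exp.data
    if d["dose"].nunique() < 2:
        raise InvalidParameterError("need >=2 distinct doses for slope estimation")
    if (d["negative_wells"] == d["wells"]).all():
        raise NoGrowthError(
            f"{exp.condition}: every well negative at every dose; "
            "frequency indistinguishable from 0"
        )
    usable = d[d["negative_wells"] >= 1]
    excluded = sorted(d.loc[d["negative_wells"] == 0, "dose"].tolist())
    if excluded:
        warnings.warn(
            f"{exp.condition}: excluding doses with zero negative wells: {excluded}",
            stacklevel=2,
        )
    if len(usable) == 0 or usable["dose"].nunique() < 1:
        raise SaturatedError(
            f"{exp.condition}: all wells positive at every dose; seed lower doses"
        )
    x = usable["dose"].to_numpy(dtype=float)
    n = usable["wells"].to_numpy(dtype=float)
    neg = usable["negative_wells"].to_numpy(dtype=float)
    p = neg / n
    # half-well adjustment keeps the starting weight finite when every well was negative
    p_w = np.minimum(p, (n - 0.5) / n)
    w = n * p_w / (1.0 - p_w)
    # second-order bias correction: E[ln p-hat] = ln p - (1-p)/(2 n p) + O(n^-2)
    y = np.log(p) + (1.0 - p) / (2.0 * n * p)
    f = np.nan
    for _ in range(10):  # reweight at the fitted single-hit probabilities
        slope = float(np.sum(w * x * y)) / float(np.sum(w * x * x))
        if not slope < 0:
            break
        f_new = -slope
        if np.isfinite(f) and abs(f_new - f) <= 1e-12 * f:
            f = f_new
            break
        f = f_new
        p_fit = np.exp(-f * x)
        w = n * p_fit / (1.0 - p_fit)
    se = 1.0 / np.sqrt(float(np.sum(w * x * x)))
    if not (np.isfinite(f) and f > 0):
        raise SaturatedError(
            f"{exp.condition}: non-positive frequency estimate ({f:.3g}); "
            "negative-well fractions do not decay with dose"
        )
    lo = max(f - 1.96 * se, np.finfo(float).tiny)
    hi = min(f + 1.96 * se, 1.0)
    # Pearson chi-square of observed vs fitted negative counts across doses
    p_fit = np.exp(-f * x)
    var = n * p_fit * (1.0 - p_fit)
    ok = var > 0
    chi2 = float(np.sum((neg[ok] - n[ok] * p_fit[ok]) ** 2 / var[ok]))
    dof = max(int(ok.sum()) - 1, 1)
    gof_p = float(stats.chi2.sf(chi2, dof))
    return LdaFit(
        condition=exp.condition,
        frequency=f,
        slope_se=se,
        ci95=(lo, hi),
        gof_p=gof_p,
        excluded_doses=excluded,
        n_doses_used=int(len(usable)),
    )


def fit_lda_raw(exp: LdaExperiment) -> float:
    """Literal x-intercept recipe: unweighted regression of negative-well counts on dose.

    Returns the inverse of the x-intercept.  Provided only for comparison;
    see module docstring.
    """
    d = exp.data
    x = d["dose"].to_numpy(dtype=float)
    y = d["negative_wells"].to_numpy(dtype=float)
    slope, intercept, *_ = stats.linregress(x, y)
    if slope == 0:
        raise SaturatedError("flat raw-count regression; x-intercept undefined")
    x_int = -intercept / slope
    if x_int == 0:
        raise SaturatedError("x-intercept at zero dose")
    return 1.0 / x_int


def compare_lda(a: LdaExperiment, b: LdaExperiment) -> dict:
    """Two-group comparison of clonogenic frequencies.

    z-test on the difference of fitted slopes using their Wald SEs; the
    frequency ratio f_a / f_b carries a delta-method 95% CI on the log scale.
    """
    fit_a, fit_b = fit_lda(a), fit_lda(b)
    se = np.hypot(fit_a.slope_se, fit_b.slope_se)
    z = (fit_a.frequency - fit_b.frequency) / se
    p = 2.0 * stats.norm.sf(abs(z))
    ratio = fit_a.frequency / fit_b.frequency
    se_log = np.hypot(
        fit_a.slope_se / fit_a.frequency, fit_b.slope_se / fit_b.frequency
    )
    ci = (ratio * np.exp(-1.96 * se_log), ratio * np.exp(1.96 * se_log))
    return {
        "fit_a": fit_a,
        "fit_b": fit_b,
        "ratio": float(ratio),
        "ratio_ci95": (float(ci[0]), float(ci[1])),
        "z": float(z),
        "p": float(p),
    }
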