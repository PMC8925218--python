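"""Cohort statistics: summary tables, correlation matrices, paired tests.

Observations are heels (two per subject, left and right pooled), matching
the source study's treatment; a ``per_subject_mean`` switch averages the
two sides first for users worried about intra-subject correlation. All
summaries are median and min-max range; group contrasts use the paired
Wilcoxon signed-rank test (zeros dropped, exact null when sample size
permits and no ranks tie); associations use Pearson's R with two-sided
p-values from the t transform. No multiple-testing correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import AllTiesError, EmptyInputError, InsufficientDataError
from .mechanics import HeelProperties

__all__ = [
    "CohortRecord",
    "PROPERTY_NAMES",
    "CORRELATION_VARIABLES",
    "records_to_frame",
    "summarize",
    "pearson_matrix",
    "paired_wilcoxon",
    "compare_conditions",
]

PROPERTY_NAMES = ("primary_thickness", "peak_strain", "peak_stress", "E", "eta", "edr")
CORRELATION_VARIABLES = ("bmi", "age") + PROPERTY_NAMES


@dataclass(frozen=True)
class CohortRecord:
    """One heel in one condition, with covariates and measured properties."""

    subject_id: str
    side: str
    condition: str
    age: float
    bmi: float
    properties: HeelProperties


def records_to_frame(records: list[CohortRecord]) -> pd.DataFrame:
    """Flatten records to a tidy DataFrame, one row per heel-condition."""
    if not records:
        raise EmptyInputError("no cohort records")
    rows = []
    for r in records:
        row = {
            "subject_id": r.subject_id,
            "side": r.side,
            "condition": r.condition,
            "age": r.age,
            "bmi": r.bmi,
        }
        row.update(r.properties.as_dict())
        rows.append(row)
    df = pd.DataFrame(rows)
    if df.duplicated(["subject_id", "side", "condition"]).any():
        raise ValueError("duplicate (subject_id, side, condition) records")
    return df


def summarize(records: list[CohortRecord]) -> pd.DataFrame:
    """Median and min-max range per property, by side and condition.

    Returns a tidy table with columns (condition, side, property, median,
    min, max, n); ``side='combined'`` pools left and right heels. Cells
    with no records are simply absent from the table.
    """
    df = records_to_frame(records)
    out = []
    for condition, cdf in df.groupby("condition", sort=False):
        groups = [(side, sdf) for side, sdf in cdf.groupby("side", sort=False)]
        groups.append(("combined", cdf))
        for side, sdf in groups:
            for prop in PROPERTY_NAMES:
                vals = sdf[prop].to_numpy(dtype=float)
                out.append(
                    {
                        "condition": condition,
                        "side": side,
                        "property": prop,
                        "median": float(np.median(vals)),
                        "min": float(vals.min()),
                        "max": float(vals.max()),
                        "n": int(vals.size),
                    }
                )
    return pd.DataFrame(out)


@dataclass
class CorrelationMatrix:
    """Pearson R and p-value layers plus bookkeeping."""

    r: pd.DataFrame
    p: pd.DataFrame
    n: int
    condition: str
    degenerate: list[str] = field(default_factory=list)


def pearson_matrix(
    records: list[CohortRecord],
    variables: tuple[str, ...] = CORRELATION_VARIABLES,
    condition: str | None = None,
    per_subject_mean: bool = False,
) -> CorrelationMatrix:
    """Pearson correlation matrix over heels of one condition.

    R is symmetric with unit diagonal; two-sided p-values come from the
    t transform with n-2 degrees of freedom. Variables with zero variance
    are listed in ``degenerate`` and their off-diagonal entries set to NaN
    (flagged, not silent).
    """
    df = records_to_frame(records)
    if condition is not None:
        df = df[df["condition"] == condition]
    else:
        conds = df["condition"].unique()
        if len(conds) != 1:
            raise ValueError("records span several conditions; pass condition=")
        condition = conds[0]
    if per_subject_mean:
        df = df.groupby("subject_id", as_index=False)[list(variables)].mean()
    n = len(df)
    if n < 3:
        raise InsufficientDataError(f"need >= 3 observations, got {n}")
    k = len(variables)
    r = np.eye(k)
    p = np.zeros((k, k))
    degenerate = [v for v in variables if np.std(df[v].to_numpy(dtype=float)) == 0]
    for i in range(k):
        for j in range(i + 1, k):
            x = df[variables[i]].to_numpy(dtype=float)
            y = df[variables[j]].to_numpy(dtype=float)
            if variables[i] in degenerate or variables[j] in degenerate:
                r[i, j] = r[j, i] = np.nan
                p[i, j] = p[j, i] = np.nan
                continue
            res = sps.pearsonr(x, y)
            r[i, j] = r[j, i] = res.statistic
            p[i, j] = p[j, i] = res.pvalue
    idx = list(variables)
    return CorrelationMatrix(
        r=pd.DataFrame(r, index=idx, columns=idx),
        p=pd.DataFrame(p, index=idx, columns=idx),
        n=n,
        condition=condition,
        degenerate=degenerate,
    )


def paired_wilcoxon(
    pre: np.ndarray | list[float],
    post: np.ndarray | list[float],
    pairing: list | None = None,
) -> tuple[float, float, int]:
    """Paired Wilcoxon signed-rank test: (statistic, two-sided p, n_effective).

    Zero differences are dropped (Wilcoxon's convention); ``n_effective``
    excludes them. The exact null distribution is used when n_effective
    <= 25 and no |difference| ranks tie, otherwise the normal approximation
    with continuity correction and tie-corrected variance.

    Raises
    ------
    AllTiesError
        If every paired difference is zero.
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.size != post.size:
        raise ValueError("pre and post must have equal length")
    if pairing is not None and len(pairing) != pre.size:
        raise ValueError("pairing must match the series length")
    d = post - pre
    d = d[d != 0.0]
    n_eff = int(d.size)
    if n_eff == 0:
        raise AllTiesError("all paired differences are zero")
    has_ties = np.unique(np.abs(d)).size < n_eff
    method = "exact" if (n_eff <= 25 and not has_ties) else "approx"
    res = sps.wilcoxon(d, zero_method="wilcox", correction=True, method=method)
    return float(res.statistic), float(res.pvalue), n_eff


def compare_conditions(
    records: list[CohortRecord],
    properties: tuple[str, ...] = PROPERTY_NAMES,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Paired time-zero vs post-loading contrast for each property.

    Heels are paired by (subject, side) across conditions. Returns
    ``(comparison, standardized)``: the comparison table has one row per
    property (both condition medians, Wilcoxon statistic, two-sided p,
    effective n); the all-zero-differences case is reported as p = 1. The
    standardized table carries per-property z-scores of the paired values
    (pooled mean/sd over both conditions) for paired box plots.
    """
    df = records_to_frame(records)
    wide = df.pivot_table(
        index=["subject_id", "side"],
        columns="condition",
        values=list(properties) + ["age", "bmi"],
        aggfunc="first",
    )
    have_both = wide[(properties[0], "time_zero")].notna() & wide[
        (properties[0], "post_loading")
    ].notna()
    wide = wide[have_both]
    if len(wide) < 3:
        raise InsufficientDataError(
            f"need >= 3 heels present in both conditions, got {len(wide)}"
        )
    rows = []
    z_rows = []
    for prop in properties:
        pre = wide[(prop, "time_zero")].to_numpy(dtype=float)
        post = wide[(prop, "post_loading")].to_numpy(dtype=float)
        try:
            stat, pval, n_eff = paired_wilcoxon(pre, post)
        except AllTiesError:
            stat, pval, n_eff = np.nan, 1.0, 0
        rows.append(
            {
                "property": prop,
                "median_time_zero": float(np.median(pre)),
                "median_post_loading": float(np.median(post)),
                "statistic": stat,
                "p_value": pval,
                "n_effective": n_eff,
                "n_pairs": int(pre.size),
            }
        )
        pooled = np.concatenate([pre, post])
        mu, sd = pooled.mean(), pooled.std(ddof=1)
        sd = sd if sd > 0 else 1.0
        for (sid, side), a, b in zip(wide.index, pre, post):
            z_rows.append(
                {
                    "subject_id": sid,
                    "side": side,
                    "property": prop,
                    "z_time_zero": (a - mu) / sd,
                    "z_post_loading": (b - mu) / sd,
                }
            )
    return pd.DataFrame(rows), pd.DataFrame(z_rows)
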