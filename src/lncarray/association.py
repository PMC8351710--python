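"""Median-split association with clinicopathological covariates.

Samples are dichotomized at the median of one feature's expression and each
covariate is tested against the split: categorical covariates by Pearson
chi-squared on the levels x groups contingency table (no continuity
correction), continuous covariates by one-way ANOVA.  Missing covariate
values are dropped per covariate, so the n used can differ between rows of
one report.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ContingencyResult",
    "median_split",
    "contingency_test",
    "anova_oneway",
    "association_table",
]


@dataclass
class ContingencyResult:
    """Chi-squared association between one categorical covariate and the split."""

    covariate: str
    table: pd.DataFrame  # levels x groups counts
    chi2: float
    df: int
    p_value: float
    n_used: int


def median_split(values: Union[pd.Series, Sequence[float]]) -> pd.Series:
    """Dichotomize at the median: values <= median -> "low", > median -> "high".

    Ties at the median go to the low group.  With an even number of distinct
    values the split is n/2 vs n/2; with odd n it is (n+1)/2 low vs (n-1)/2
    high.  All-identical values are a degenerate split and raise.
    """
    s = pd.Series(values, dtype=float)
    if len(s) < 2:
        raise ValueError("median split needs at least 2 samples")
    if s.isna().any():
        raise ValueError("median split input contains missing values")
    if s.nunique() == 1:
        raise ValueError("degenerate split: all values identical")
    med = s.median()
    return pd.Series(np.where(s.to_numpy() <= med, "low", "high"), index=s.index, name="group")


def contingency_test(
    labels: Union[pd.Series, Sequence],
    covariate: Union[pd.Series, Sequence],
    name: str = "covariate",
    correction: bool = False,
    exact: bool = False,
) -> ContingencyResult:
    """Pearson chi-squared test of a categorical covariate against group labels.

    Samples with a missing covariate value are excluded; levels with an
    all-zero row are dropped (df recomputed).  ``correction=True`` applies
    the Yates continuity correction and ``exact=True`` Fisher's exact test
    (2x2 only); the default matches the plain Pearson statistic.
    """
    lab = pd.Series(labels)
    cov = pd.Series(covariate)
    if len(lab) != len(cov):
        cov = cov.reindex(lab.index)
    keep = cov.notna()
    lab, cov = lab[keep], cov[keep]
    table = pd.crosstab(cov, lab)
    table = table.loc[table.sum(axis=1) > 0, table.sum(axis=0) > 0]
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError(f"covariate {name!r}: fewer than 2 levels or groups after dropping")
    counts = table.to_numpy()
    if exact:
        if counts.shape != (2, 2):
            raise ValueError("Fisher's exact test requires a 2x2 table")
        _, p = stats.fisher_exact(counts)
        chi2, dof = float("nan"), 1
    else:
        chi2, p, dof, _ = stats.chi2_contingency(counts, correction=correction)
    return ContingencyResult(name, table, float(chi2), int(dof), float(p), int(counts.sum()))


def anova_oneway(*groups: Sequence[float]) -> Dict[str, float]:
    """Classical one-way ANOVA across two or more groups of reals.

    For two groups F equals the squared pooled-variance t statistic.  Groups
    with identical values throughout (zero total variance) yield F = 0, p = 1.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("one-way ANOVA needs at least 2 groups")
    for g in arrays:
        if g.size < 2:
            raise ValueError("each group needs at least 2 values")
    pooled = np.concatenate(arrays)
    if np.ptp(pooled) == 0:
        return {"F": 0.0, "p": 1.0}
    f, p = stats.f_oneway(*arrays)
    return {"F": float(f), "p": float(p)}


def association_table(
    expr_row: Union[pd.Series, Sequence[float]],
    clinical: pd.DataFrame,
    covariates: Sequence[str],
    continuous: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Assemble a Table 1-style association report for one expression feature.

    Samples are median-split on ``expr_row`` (indexed by sample id, aligned
    with ``clinical``).  Each requested covariate yields one row: categorical
    covariates report the chi-squared p with per-level ``count (percent)``
    strings per group; continuous covariates report the one-way ANOVA p with
    per-group ``mean ± dispersion`` (standard error).  ``continuous`` forces
    covariates into the ANOVA branch; otherwise numeric dtype decides.
    """
    expr_row = pd.Series(expr_row)
    missing = [c for c in covariates if c not in clinical.columns]
    if missing:
        raise KeyError(f"covariates absent from clinical table: {missing}")
    clin = clinical.loc[expr_row.index] if set(expr_row.index) <= set(clinical.index) else clinical
    split = median_split(expr_row)
    continuous = set(continuous or [])
    groups = ["low", "high"]
    rows: List[dict] = []
    for cov in covariates:
        col = clin[cov]
        if cov in continuous or pd.api.types.is_numeric_dtype(col):
            keep = col.notna()
            vals = [col[keep & (split == g)].to_numpy(dtype=float) for g in groups]
            res = anova_oneway(*vals)
            low, high = (
                f"{v.mean():.1f} ± {v.std(ddof=1) / np.sqrt(len(v)):.2f}" for v in vals
            )
            rows.append(
                {
                    "covariate": cov, "kind": "continuous", "low": low, "high": high,
                    "statistic": res["F"], "df": len(vals) - 1,
                    "p_value": res["p"], "n_used": int(sum(len(v) for v in vals)),
                }
            )
        else:
            res = contingency_test(split, col, name=cov)
            tab = res.table.reindex(columns=groups)
            pct = tab / tab.sum(axis=0) * 100.0
            cells = {
                g: "; ".join(
                    f"{level}: {tab.loc[level, g]} ({pct.loc[level, g]:.1f}%)"
                    for level in tab.index
                )
                for g in groups
            }
            rows.append(
                {
                    "covariate": cov, "kind": "categorical",
                    "low": cells["low"], "high": cells["high"],
                    "statistic": res.chi2, "df": res.df,
                    "p_value": res.p_value, "n_used": res.n_used,
                }
            )
    return pd.DataFrame(rows)
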