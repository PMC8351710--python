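"""Probe-to-transcript expression summarization, differential expression, qPCR.

Expression matrices are pandas DataFrames, features x samples, already on the
log2 scale (the pipeline assumes normalized input; no background correction).
Probe-level rows are keyed ``"<probeset_id>:<probe_index>"``.
"""

from __future__ import annotations

from typing import Iterable, Literal, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .reannotation import ProbeSetAssignment

__all__ = [
    "probe_row_id",
    "summarize_expression",
    "differential_expression",
    "ddct_fold_change",
    "bh_adjust",
]

DE_COLUMNS = [
    "feature_id", "mean_a", "mean_b", "log2_fold_change",
    "statistic", "p_value", "q_value", "zero_variance",
]


def probe_row_id(probeset_id: str, probe_index: int) -> str:
    """Row key used for probe-level matrices: ``probeset:index``."""
    return f"{probeset_id}:{probe_index}"


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def summarize_expression(
    probe_values: pd.DataFrame,
    assignments: Iterable[ProbeSetAssignment],
    method: Literal["median", "mean"] = "median",
) -> pd.DataFrame:
    """Collapse probe-level intensities to one row per assigned transcript.

    For each transcript, the value per sample is the ``method`` over all its
    matched probes (pooled across probe sets if several sets were assigned to
    the same transcript).  Probes of unassigned sets are ignored.  Raises if
    an assignment references probe rows absent from ``probe_values``.
    """
    if method not in ("median", "mean"):
        raise ValueError(f"unknown summarization method {method!r}")
    rows_by_transcript: dict = {}
    missing = []
    for a in assignments:
        if a.status != "assigned":
            continue
        for idx in a.matched_probe_indices:
            rid = probe_row_id(a.probeset_id, idx)
            if rid not in probe_values.index:
                missing.append(rid)
            else:
                rows_by_transcript.setdefault(a.transcript_id, []).append(rid)
    if missing:
        raise KeyError(f"assigned probes absent from probe matrix: {sorted(missing)}")
    agg = np.median if method == "median" else np.mean
    data = {
        tid: agg(probe_values.loc[rids].to_numpy(), axis=0)
        for tid, rids in rows_by_transcript.items()
    }
    out = pd.DataFrame.from_dict(data, orient="index", columns=probe_values.columns)
    out.index.name = "transcript_id"
    return out.sort_index()


def _group_masks(labels: pd.Series, columns: pd.Index, group_order: Optional[Sequence] = None):
    labels = pd.Series(labels)
    if set(labels.index) >= set(columns):
        labels = labels.loc[columns]
    elif len(labels) != len(columns):
        raise ValueError("labels do not align with matrix samples")
    vals = labels.to_numpy()
    groups = list(group_order) if group_order is not None else sorted(pd.unique(vals))
    if len(groups) != 2:
        raise ValueError(f"exactly two groups required, got {groups}")
    mask_a = vals == groups[0]
    mask_b = vals == groups[1]
    if mask_a.sum() < 2 or mask_b.sum() < 2:
        raise ValueError("each group needs at least 2 samples")
    if not (mask_a | mask_b).all():
        raise ValueError("labels contain values outside the two groups")
    return groups, mask_a, mask_b


def differential_expression(
    expr: pd.DataFrame,
    group_labels: Sequence,
    paired: bool = False,
    pair_ids: Optional[Sequence] = None,
    group_order: Optional[Sequence] = None,
    welch: bool = False,
) -> pd.DataFrame:
    """Two-group differential expression over all features.

    Unpaired mode is the pooled-variance two-sample t test, equivalent to a
    two-group one-way ANOVA (F = t^2); ``welch=True`` switches to unequal
    variances.  Paired mode is the paired t test and requires ``pair_ids``
    forming a perfect matching across groups.  ``log2_fold_change`` is
    mean(group b) - mean(group a), with (a, b) the sorted group labels unless
    ``group_order`` is given.  q-values are Benjamini-Hochberg over all
    features.  Features with zero variance in both groups and equal means get
    p = 1 with ``zero_variance=True`` rather than NaN.
    """
    groups, mask_a, mask_b = _group_masks(pd.Series(group_labels), expr.columns, group_order)
    xa = expr.to_numpy()[:, mask_a]
    xb = expr.to_numpy()[:, mask_b]
    mean_a = xa.mean(axis=1)
    mean_b = xb.mean(axis=1)

    if paired:
        if pair_ids is None:
            raise ValueError("paired mode requires pair_ids")
        pid = np.asarray(pair_ids)
        pa, pb = pid[mask_a], pid[mask_b]
        if sorted(pa) != sorted(pb) or len(set(pa)) != len(pa):
            raise ValueError("pair_ids do not form a perfect matching between groups")
        xa = xa[:, np.argsort(pa)]  # align columns of both groups by pair id
        xb = xb[:, np.argsort(pb)]
        with np.errstate(invalid="ignore", divide="ignore"):
            stat, p = stats.ttest_rel(xb, xa, axis=1)
    else:
        with np.errstate(invalid="ignore", divide="ignore"):
            stat, p = stats.ttest_ind(xb, xa, axis=1, equal_var=not welch)

    stat = np.asarray(stat, dtype=float)
    p = np.asarray(p, dtype=float)
    zero_var = ~np.isfinite(stat)
    equal_means = np.isclose(mean_a, mean_b)
    stat[zero_var & equal_means] = 0.0
    p[zero_var & equal_means] = 1.0
    stat[zero_var & ~equal_means] = np.sign((mean_b - mean_a)[zero_var & ~equal_means]) * np.inf
    p[zero_var & ~equal_means] = 0.0

    return pd.DataFrame(
        {
            "feature_id": expr.index,
            "mean_a": mean_a,
            "mean_b": mean_b,
            "log2_fold_change": mean_b - mean_a,
            "statistic": stat,
            "p_value": p,
            "q_value": bh_adjust(p),
            "zero_variance": zero_var,
        }
    ).reset_index(drop=True)


def ddct_fold_change(delta_ct_target_condition: float, delta_ct_target_calibrator: float) -> float:
    """Relative qPCR expression by the 2^-ddCt method.

    ddCt = dCt(condition) - dCt(calibrator); each dCt is target Ct minus
    reference-gene Ct.  Returns the fold change 2^-ddCt (1.0 when ddCt = 0,
    2.0 per cycle earlier in the condition sample).
    """
    ddct = float(delta_ct_target_condition) - float(delta_ct_target_calibrator)
    if not np.isfinite(ddct):
        raise ValueError("delta-Ct inputs must be finite")
    return float(2.0 ** (-ddct))
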