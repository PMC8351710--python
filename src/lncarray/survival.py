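"""Kaplan-Meier estimation, log-rank comparison and univariate Cox regression.

Used downstream of the median split: the prognosis question is whether the
high-expression group has a different hazard than the low group, summarized
as a hazard ratio with a 95% Wald confidence interval (HR < 1 means lower
event risk for a unit increase of the covariate).

Kaplan-Meier curves and the log-rank statistic come from lifelines.  The Cox
model is a purpose-built univariate partial-likelihood fit with Breslow tie
handling by default (Efron by flag), maximized by Newton-Raphson with
step-halving; for a binary covariate its score test at beta = 0 coincides
with the log-rank chi-squared under Breslow ties, which the test suite
exploits as a consistency check.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Literal, Sequence, Union

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats

__all__ = ["CoxResult", "ConvergenceError", "km_estimate", "cox_univariate", "cox_score_test"]


class ConvergenceError(RuntimeError):
    """Partial-likelihood maximization failed (e.g. monotone likelihood)."""


@dataclass
class CoxResult:
    """Univariate Cox fit: log-hazard ``beta`` and Wald inference on HR scale."""

    beta: float
    hazard_ratio: float
    ci_low: float
    ci_high: float
    se: float
    p_value: float
    n: int
    n_events: int
    log_likelihood: float
    n_iter: int


def _validate(time, event):
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if time.shape != event.shape or time.ndim != 1:
        raise ValueError("time and event must be 1-d arrays of equal length")
    if (time <= 0).any():
        raise ValueError("survival times must be positive")
    if not np.isin(event, [0, 1]).all():
        raise ValueError("event must be 0 (censored) or 1 (event)")
    if event.sum() == 0:
        raise ValueError("no events observed")
    return time, event


def km_estimate(
    time: Sequence[float],
    event: Sequence[int],
    group: Sequence,
) -> Dict[str, object]:
    """Product-limit survival curves per group plus the unweighted log-rank test.

    Returns ``{"curves": {group: DataFrame(time, survival, at_risk)},
    "logrank": {"chi2": ..., "p": ..., "df": ...}}``.  Censoring is handled by
    the product-limit estimator; curves start at S(0) = 1 and are step
    functions constant between event times.
    """
    time, event = _validate(time, event)
    group = np.asarray(group)
    curves = {}
    for g in sorted(map(str, np.unique(group))):
        mask = group.astype(str) == g
        kmf = KaplanMeierFitter()
        kmf.fit(time[mask], event[mask])
        tab = kmf.event_table
        curves[g] = pd.DataFrame(
            {
                "time": kmf.survival_function_.index.to_numpy(),
                "survival": kmf.survival_function_.iloc[:, 0].to_numpy(),
                "at_risk": tab["at_risk"].reindex(kmf.survival_function_.index).to_numpy(),
            }
        )
    lr = multivariate_logrank_test(time, group, event)
    return {
        "curves": curves,
        "logrank": {
            "chi2": float(lr.test_statistic),
            "p": float(lr.p_value),
            "df": int(lr.degrees_of_freedom) if hasattr(lr, "degrees_of_freedom") else len(curves) - 1,
        },
    }


def _breslow_quantities(beta, x, time, event):
    """Log partial likelihood, score and information for univariate Cox.

    Assumes inputs sorted by descending time so that risk sets are prefix
    sums.  Breslow ties: each tied death at a time sees the full risk set.
    """
    eta = beta * x
    w = np.exp(eta)
    # cumulative risk-set sums: S0 = sum w, S1 = sum x w, S2 = sum x^2 w over R(t)
    c0 = np.cumsum(w)
    c1 = np.cumsum(x * w)
    c2 = np.cumsum(x * x * w)
    loglik = score = info = 0.0
    n = len(x)
    i = 0
    while i < n:
        j = i
        while j + 1 < n and time[j + 1] == time[i]:
            j += 1
        # risk set for this time = indices 0..j (all with time >= t since sorted desc)
        deaths = event[i : j + 1] == 1
        d = int(deaths.sum())
        if d:
            s0, s1, s2 = c0[j], c1[j], c2[j]
            sx = float(x[i : j + 1][deaths].sum())
            loglik += beta * sx - d * np.log(s0)
            mu = s1 / s0
            score += sx - d * mu
            info += d * (s2 / s0 - mu * mu)
        i = j + 1
    return loglik, score, info


def _efron_quantities(beta, x, time, event):
    """Efron tie-corrected log partial likelihood, score and information."""
    eta = beta * x
    w = np.exp(eta)
    c0 = np.cumsum(w)
    c1 = np.cumsum(x * w)
    c2 = np.cumsum(x * x * w)
    loglik = score = info = 0.0
    n = len(x)
    i = 0
    while i < n:
        j = i
        while j + 1 < n and time[j + 1] == time[i]:
            j += 1
        deaths = event[i : j + 1] == 1
        d = int(deaths.sum())
        if d:
            xd = x[i : j + 1][deaths]
            wd = w[i : j + 1][deaths]
            d0, d1, d2 = float(wd.sum()), float((xd * wd).sum()), float((xd * xd * wd).sum())
            sx = float(xd.sum())
            loglik += beta * sx
            for k in range(d):
                f = k / d
                s0 = c0[j] - f * d0
                s1 = c1[j] - f * d1
                s2 = c2[j] - f * d2
                loglik -= np.log(s0)
                mu = s1 / s0
                score += -mu + sx / d  # sx spread evenly over the d factors
                info += s2 / s0 - mu * mu
        i = j + 1
    return loglik, score, info


def cox_score_test(
    time: Sequence[float], event: Sequence[int], covariate: Sequence[float]
) -> float:
    """Cox score chi-squared at beta = 0 (Breslow ties)."""
    time, event = _validate(time, event)
    x = np.asarray(covariate, dtype=float)
    order = np.lexsort((-event, -time))  # desc time; within ties events after censored is
    # irrelevant for prefix risk sets since ties share one block
    _, score, info = _breslow_quantities(0.0, x[order], time[order], event[order])
    if info <= 0:
        raise ValueError("covariate does not vary")
    return float(score * score / info)


def cox_univariate(
    time: Sequence[float],
    event: Sequence[int],
    covariate: Sequence[float],
    ties: Literal["breslow", "efron"] = "breslow",
    max_iter: int = 50,
    tol: float = 1e-9,
    alpha: float = 0.05,
) -> CoxResult:
    """Fit a univariate Cox proportional-hazards model.

    Newton-Raphson on the log partial likelihood with step-halving,
    converging when the log-likelihood improves by less than ``tol``
    (default 1e-9, max 50 iterations).  Monotone likelihood (complete
    separation of events by the covariate) is reported as
    :class:`ConvergenceError` rather than returned as a huge coefficient.
    The confidence interval is Wald on the log-hazard scale, exponentiated.
    """
    time, event = _validate(time, event)
    x = np.asarray(covariate, dtype=float)
    if x.shape != time.shape:
        raise ValueError("covariate length mismatch")
    if np.ptp(x) == 0:
        raise ValueError("covariate does not vary")
    order = np.argsort(-time, kind="stable")
    x, t, e = x[order], time[order], event[order]
    quantities = _breslow_quantities if ties == "breslow" else _efron_quantities

    beta = 0.0
    loglik, score, info = quantities(beta, x, t, e)
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        if info <= 1e-12:
            raise ConvergenceError("information is zero; likelihood is flat or monotone")
        step = score / info
        new_beta = beta + step
        new_ll, new_score, new_info = quantities(new_beta, x, t, e)
        halvings = 0
        while (not np.isfinite(new_ll) or new_ll < loglik) and halvings < 30:
            step /= 2.0
            new_beta = beta + step
            new_ll, new_score, new_info = quantities(new_beta, x, t, e)
            halvings += 1
        if abs(new_beta) > 20:
            raise ConvergenceError(
                "coefficient diverging (|beta| > 20): monotone likelihood / separation"
            )
        delta = new_ll - loglik
        beta, loglik, score, info = new_beta, new_ll, new_score, new_info
        if abs(delta) < tol:
            break
    else:
        raise ConvergenceError(f"no convergence in {max_iter} iterations")

    se = float(1.0 / np.sqrt(info))
    z = stats.norm.ppf(1 - alpha / 2)
    p = float(2 * stats.norm.sf(abs(beta) / se))
    return CoxResult(
        beta=float(beta),
        hazard_ratio=float(np.exp(beta)),
        ci_low=float(np.exp(beta - z * se)),
        ci_high=float(np.exp(beta + z * se)),
        se=se,
        p_value=p,
        n=int(len(t)),
        n_events=int(e.sum()),
        log_likelihood=float(loglik),
        n_iter=n_iter,
    )
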