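"""Gene set enrichment between median-split groups, plus over-representation.

The enrichment score (ES) is the classic weighted Kolmogorov-Smirnov running
sum over a gene list ranked by a signal-to-noise metric between the high and
low expression groups.  Significance comes from permuting the phenotype
labels with a seeded generator; the normalized score (NES) divides the
observed ES by the mean |null ES| of matching sign, the permutation p-value
uses the plus-one correction (so it is never 0), and the q-value is
Benjamini-Hochberg across gene sets — a documented simplification of the
original pooled-NES false-discovery estimate.

A local one-sided hypergeometric over-representation test is also provided
for querying a gene list (e.g. leading-edge members) against a collection.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple, Union

import numpy as np
import pandas as pd
from scipy import stats

from .expression import bh_adjust

__all__ = [
    "EnrichmentResult",
    "rank_genes",
    "enrichment_score",
    "gsea_permutation",
    "overrepresentation_test",
    "signal_to_noise",
]


@dataclass
class EnrichmentResult:
    """Per-set GSEA outcome with permutation inference."""

    set_name: str
    es: float
    nes: float
    p_perm: float
    q_value: float
    leading_edge: List[str]
    set_size_used: int


def signal_to_noise(
    values: np.ndarray,
    mask_pos: np.ndarray,
    mask_neg: np.ndarray,
    sd_floor_frac: float = 0.2,
    sd_floor_abs: float = 1e-4,
) -> np.ndarray:
    """Signal-to-noise ratio per feature (rows of ``values``).

    (mean_pos - mean_neg) / (sd_pos + sd_neg), with each group standard
    deviation floored at ``sd_floor_frac * |group mean|`` and at
    ``sd_floor_abs``, following the GSEA convention that keeps near-constant
    genes from dominating the ranking.
    """
    a, b = values[:, mask_pos], values[:, mask_neg]
    ma, mb = a.mean(axis=1), b.mean(axis=1)
    sa, sb = a.std(axis=1, ddof=1), b.std(axis=1, ddof=1)
    sa = np.maximum(np.maximum(sa, sd_floor_frac * np.abs(ma)), sd_floor_abs)
    sb = np.maximum(np.maximum(sb, sd_floor_frac * np.abs(mb)), sd_floor_abs)
    return (ma - mb) / (sa + sb)


def rank_genes(
    expr: pd.DataFrame,
    labels: Sequence,
    sd_floor_frac: float = 0.2,
    sd_floor_abs: float = 1e-4,
) -> pd.Series:
    """Rank genes by signal-to-noise between "high" and "low" labelled samples.

    Positive metric = higher in the high-expression group.  Both groups need
    at least 3 samples; a ranking in which every metric is identical (e.g.
    constant expression) is degenerate and raises.  Ties are broken by gene
    id so the ordering is deterministic.
    """
    labels = pd.Series(labels)
    if set(labels.index) >= set(expr.columns):
        labels = labels.loc[expr.columns]
    vals = labels.to_numpy().astype(str)
    mask_hi, mask_lo = vals == "high", vals == "low"
    if not (mask_hi | mask_lo).all() or mask_hi.sum() < 3 or mask_lo.sum() < 3:
        raise ValueError('labels must be "low"/"high" with >= 3 samples per group')
    metric = signal_to_noise(expr.to_numpy(), mask_hi, mask_lo, sd_floor_frac, sd_floor_abs)
    s = pd.Series(metric, index=expr.index, name="signal_to_noise")
    if s.nunique() == 1:
        raise ValueError("degenerate ranking: all metrics identical")
    order = np.lexsort((s.index.to_numpy(), -s.to_numpy()))
    return s.iloc[order]


def _es_from_positions(
    positions: np.ndarray, hit_weights: np.ndarray, n_total: int
) -> np.ndarray:
    """ES from sorted 0-based hit positions and matching unnormalized weights.

    The running sum rises by the normalized hit weight at each member and
    falls by 1/(N - k) at each non-member; its extremum (largest absolute
    excursion, signed) is the ES.  Extrema can only occur immediately after
    a hit (maxima) or immediately before one (minima), so only 2k candidate
    values need inspection.  When the set covers the whole universe there are
    no misses; the uniform CDF i/N serves as the reference so the excursion
    of the weighted hit CDF around it is returned (exactly 0 at weight 0).
    """
    k = positions.shape[-1]
    total = hit_weights.sum(axis=-1, keepdims=True)
    safe = np.where(total > 0, total, 1.0)
    w = np.where(total > 0, hit_weights / safe, 1.0 / k)  # all-zero metrics: equal steps
    cum = np.cumsum(w, axis=-1)
    idx = np.arange(k)
    if k == n_total:
        dev_hi = cum - (positions + 1) / n_total
        dev_lo = (cum - w) - positions / n_total
    else:
        miss = 1.0 / (n_total - k)
        dev_hi = cum - (positions - idx) * miss  # right after hit i
        dev_lo = (cum - w) - (positions - idx) * miss  # just before hit i
    hi = dev_hi.max(axis=-1)
    lo = np.minimum(dev_lo.min(axis=-1), 0.0)
    return np.where(hi >= -lo, hi, lo)


def enrichment_score(
    ranked: Union[pd.Series, Sequence[Tuple[str, float]]],
    gene_set: Set[str],
    weight: float = 1.0,
    min_set_size: int = 5,
) -> Dict[str, object]:
    """Weighted KS enrichment score of one gene set on a ranked list.

    ``ranked`` is a descending-ordered (gene, metric) sequence or Series.
    Returns ``{"es", "running_sum", "leading_edge", "set_size_used"}``; the
    running sum has one entry per ranked gene and ends at 0 (within fp
    tolerance).  The leading edge is the set members at or before the
    extremum for positive ES, at or after it for negative ES.
    """
    if isinstance(ranked, pd.Series):
        genes = list(ranked.index)
        metrics = ranked.to_numpy(dtype=float)
    else:
        genes = [g for g, _ in ranked]
        metrics = np.array([m for _, m in ranked], dtype=float)
    n = len(genes)
    is_hit = np.fromiter((g in gene_set for g in genes), dtype=bool, count=n)
    k = int(is_hit.sum())
    if k == 0:
        raise ValueError("gene set has empty intersection with the ranked universe")
    if k < min_set_size:
        raise ValueError(f"gene set intersection {k} below min_set_size={min_set_size}")
    hit_w = np.where(is_hit, np.abs(metrics) ** weight, 0.0)
    total = hit_w.sum()
    increments = np.zeros(n)
    if total > 0:
        increments[is_hit] = hit_w[is_hit] / total
    else:
        increments[is_hit] = 1.0 / k
    if k < n:
        increments[~is_hit] = -1.0 / (n - k)
        running = np.cumsum(increments)
    else:
        running = np.cumsum(increments) - np.arange(1, n + 1) / n
    i_max = int(np.argmax(running))
    i_min = int(np.argmin(running))
    es = running[i_max] if running[i_max] >= -min(running[i_min], 0.0) else min(running[i_min], 0.0)
    if es >= 0:
        leading = [g for g, h in zip(genes[: i_max + 1], is_hit[: i_max + 1]) if h]
    else:
        leading = [g for g, h in zip(genes[i_min:], is_hit[i_min:]) if h]
    return {
        "es": float(es),
        "running_sum": running,
        "leading_edge": leading,
        "set_size_used": k,
    }


def _max_distinct_splits(n: int, n_low: int) -> int:
    return math.comb(n, n_low)


def gsea_permutation(
    expr: pd.DataFrame,
    labels: Sequence,
    collection: Dict[str, Set[str]],
    n_perm: int = 1000,
    seed: Optional[int] = None,
    weight: float = 1.0,
    min_set_size: int = 5,
    sd_floor_frac: float = 0.2,
    sd_floor_abs: float = 1e-4,
) -> List[EnrichmentResult]:
    """GSEA with a phenotype-permutation null for every set in a collection.

    Labels are permuted ``n_perm`` times with ``numpy.random.default_rng(seed)``
    (capped with a warning if fewer distinct label arrangements exist), the
    ranking is recomputed per permutation, and each set's null ES distribution
    yields NES, the plus-one permutation p and a BH q across sets.  Sets whose
    intersection with the expression universe is below ``min_set_size`` are
    dropped.  Seeded runs are reproducible.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    labels = pd.Series(labels)
    if set(labels.index) >= set(expr.columns):
        labels = labels.loc[expr.columns]
    vals = labels.to_numpy().astype(str)
    mask_hi = vals == "high"
    n_low = int((~mask_hi).sum())
    cap = _max_distinct_splits(len(vals), n_low)
    if cap < n_perm:
        warnings.warn(
            f"only {cap} distinct label permutations exist; capping n_perm={n_perm} to {cap}"
        )
        n_perm = cap

    genes = expr.index.to_numpy()
    universe = set(genes)
    usable = {
        name: {g for g in gs if g in universe}
        for name, gs in collection.items()
    }
    usable = {name: gs for name, gs in usable.items() if len(gs) >= min_set_size}
    if not usable:
        raise ValueError("no gene set meets min_set_size in the expression universe")

    observed_rank = rank_genes(expr, labels, sd_floor_frac, sd_floor_abs)

    rng = np.random.default_rng(seed)
    x = expr.to_numpy()
    n_genes, n_samples = x.shape
    # per-permutation rank position and |metric| of every gene
    pos = np.empty((n_perm, n_genes), dtype=np.int32)
    absm = np.empty((n_perm, n_genes), dtype=np.float64)
    gene_ids = expr.index.to_numpy()
    for p_i in range(n_perm):
        perm = rng.permutation(n_samples)
        m_hi = np.zeros(n_samples, dtype=bool)
        m_hi[perm[: int(mask_hi.sum())]] = True
        metric = signal_to_noise(x, m_hi, ~m_hi, sd_floor_frac, sd_floor_abs)
        order = np.lexsort((gene_ids, -metric))
        pos[p_i, order] = np.arange(n_genes, dtype=np.int32)
        absm[p_i] = np.abs(metric)

    gene_index = {g: i for i, g in enumerate(genes)}
    results = []
    p_values = []
    for name in sorted(usable):
        gs = usable[name]
        obs = enrichment_score(observed_rank, gs, weight=weight, min_set_size=min_set_size)
        members = np.array(sorted(gene_index[g] for g in gs))
        hit_pos = pos[:, members].astype(np.float64)
        hit_w = absm[:, members] ** weight
        sort_idx = np.argsort(hit_pos, axis=1)
        hit_pos_sorted = np.take_along_axis(hit_pos, sort_idx, axis=1)
        hit_w_sorted = np.take_along_axis(hit_w, sort_idx, axis=1)
        null_es = _es_from_positions(hit_pos_sorted, hit_w_sorted, n_genes)
        es = obs["es"]
        same_sign = null_es >= 0 if es >= 0 else null_es <= 0
        denom = np.abs(null_es[same_sign]).mean() if same_sign.any() else np.abs(null_es).mean()
        nes = es / denom if denom > 0 else 0.0
        if es >= 0:
            n_extreme = int((null_es[same_sign] >= es).sum())
        else:
            n_extreme = int((null_es[same_sign] <= es).sum())
        # plus-one permutation p, conditional on the observed sign: dividing
        # by the same-sign null count keeps the null p approximately uniform
        # on (0, 1] and never exactly 0
        p_perm = (1 + n_extreme) / (1 + int(same_sign.sum()))
        p_values.append(p_perm)
        results.append(
            EnrichmentResult(
                set_name=name, es=float(es), nes=float(nes), p_perm=float(p_perm),
                q_value=np.nan, leading_edge=list(obs["leading_edge"]),
                set_size_used=int(obs["set_size_used"]),
            )
        )
    q = bh_adjust(p_values)
    for r, qv in zip(results, q):
        r.q_value = float(qv)
    return results


def overrepresentation_test(
    query_genes: Sequence[str],
    collection: Dict[str, Set[str]],
    universe: Sequence[str],
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation of a query in each set.

    For a universe of M genes, a set of n (restricted to the universe) and a
    query of N, the p-value is P(overlap >= observed) under sampling without
    replacement; q-values are BH across sets.  The query must be a subset of
    the universe.
    """
    query = set(query_genes)
    if not query:
        raise ValueError("empty query gene list")
    uni = set(universe)
    if not query <= uni:
        raise ValueError(f"query genes outside the universe: {sorted(query - uni)[:5]}")
    m = len(uni)
    rows = []
    for name in sorted(collection):
        members = collection[name] & uni
        overlap = len(members & query)
        if len(members) == 0:
            continue
        p = float(stats.hypergeom.sf(overlap - 1, m, len(members), len(query)))
        rows.append(
            {
                "set_name": name,
                "set_size": len(members),
                "overlap": overlap,
                "overlap_genes": ",".join(sorted(members & query)),
                "p_value": min(p, 1.0),
            }
        )
    out = pd.DataFrame(rows)
    if len(out):
        out["q_value"] = bh_adjust(out["p_value"])
    return out
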