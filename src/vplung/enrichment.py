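"""Cluster enrichment statistics and between-arm comparison.

One-sided hypergeometric over-representation tests of diagnosis codes
and hospital of origin within clusters (Benjamini-Hochberg corrected per
category family), plus a Welch t-test comparison of the clustering
quality distributions of the raw-feature and model-derived arms.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .consensus import OUTLIER

__all__ = [
    "EnrichmentResult",
    "ArmComparison",
    "hypergeom_upper",
    "bh_adjust",
    "enrich_clusters",
    "compare_arms",
]


@dataclass(frozen=True)
class EnrichmentResult:
    cluster_id: int
    category: str
    family: str        # "condition" or "hospital"
    N: int             # population size (non-outlier items)
    K: int             # category members in the population
    n: int             # cluster size
    k_obs: int         # category members in the cluster
    p_raw: float
    p_adj: float
    significant: bool


@dataclass(frozen=True)
class ArmComparison:
    k: int
    mean_quality_raw: float
    mean_quality_model: float
    t_stat: float
    p_value: float
    conclusion: str  # which arm has higher mean quality


def hypergeom_upper(N: int, K: int, n: int, k_obs: int) -> float:
    """Upper-tail hypergeometric probability P(X >= k_obs).

    X counts category members in a size-n draw without replacement from a
    population of N with K category members.  Computed via the stable
    survival function of :mod:`scipy.stats`.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"inconsistent counts N={N}, K={K}, n={n}")
    if not (max(0, n + K - N) <= k_obs <= min(K, n)):
        raise ValueError(
            f"k_obs={k_obs} impossible for N={N}, K={K}, n={n}")
    if k_obs == 0:
        return 1.0
    # sf(k-1) = P(X >= k); guard against negative rounding
    p = float(stats.hypergeom.sf(k_obs - 1, N, K, n))
    return min(max(p, np.exp(stats.hypergeom.logsf(k_obs - 1, N, K, n))), 1.0)


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (original order)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def enrich_clusters(
    labels: np.ndarray,
    categories: pd.DataFrame,
    alpha: float = 0.05,
) -> Tuple[List[EnrichmentResult], pd.DataFrame]:
    """Test every (cluster x category) pair for over-representation.

    ``categories`` has one row per item (aligned with ``labels``) and the
    columns ``conditions`` (iterable of diagnosis codes) and ``hospital``.
    Outlier items are excluded from both the population and the clusters.
    BH correction is applied within each family (all condition tests
    together, all hospital tests together).  Also returns a per-cluster
    table of the most significant condition and hospital.
    """
    labels = np.asarray(labels)
    if len(labels) != len(categories):
        raise ValueError("labels and categories must align")
    keep = labels != OUTLIER
    labels = labels[keep]
    cats = categories.loc[keep].reset_index(drop=True)
    N = len(cats)
    clusters = sorted(set(labels.tolist()))

    cond_sets = [frozenset(c) for c in cats["conditions"]]
    all_codes = sorted(set().union(*cond_sets)) if cond_sets else []
    hospitals = sorted(cats["hospital"].unique())

    results: List[EnrichmentResult] = []
    tests: List[Tuple[str, int, str, int, int, int, float]] = []
    for cl in clusters:
        members = labels == cl
        n = int(members.sum())
        if n == 0:
            continue
        for code in all_codes:
            has = np.array([code in s for s in cond_sets])
            K = int(has.sum())
            k_obs = int(has[members].sum())
            tests.append(("condition", cl, code, N, K, n,
                          hypergeom_upper(N, K, n, k_obs), k_obs))
        for hosp in hospitals:
            has = (cats["hospital"] == hosp).to_numpy()
            K = int(has.sum())
            k_obs = int(has[members].sum())
            tests.append(("hospital", cl, hosp, N, K, n,
                          hypergeom_upper(N, K, n, k_obs), k_obs))

    for family in ("condition", "hospital"):
        fam = [t for t in tests if t[0] == family]
        if not fam:
            continue
        adj = bh_adjust([t[6] for t in fam])
        for t, pa in zip(fam, adj):
            results.append(EnrichmentResult(
                cluster_id=int(t[1]), category=t[2], family=family,
                N=t[3], K=t[4], n=t[5], k_obs=t[7],
                p_raw=float(t[6]), p_adj=float(pa),
                significant=bool(pa < alpha)))

    top_rows = []
    for cl in clusters:
        row: Dict[str, object] = {"cluster_id": int(cl)}
        for family in ("condition", "hospital"):
            fam = [r for r in results
                   if r.cluster_id == cl and r.family == family]
            if fam:
                best = min(fam, key=lambda r: (r.p_adj, r.p_raw))
                row[f"top_{family}"] = best.category
                row[f"top_{family}_p_adj"] = best.p_adj
                row[f"top_{family}_p_raw"] = best.p_raw
                row[f"top_{family}_significant"] = best.significant
        top_rows.append(row)
    return results, pd.DataFrame(top_rows)


def compare_arms(
    quality_raw: Sequence[float],
    quality_model: Sequence[float],
    k: int = 0,
    equal_var: bool = False,
) -> ArmComparison:
    """Two-tailed two-sample t-test on per-repeat quality samples.

    Welch's unequal-variance form by default.  Identical degenerate
    samples (zero variance, equal means) yield t = 0, p = 1.
    """
    a = np.asarray(quality_raw, dtype=float)
    b = np.asarray(quality_model, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 quality samples per arm")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if a.mean() == b.mean():
            t_stat, p = 0.0, 1.0
        else:
            # scipy's sign convention: positive t means the first sample
            # has the larger mean
            t_stat, p = np.inf * np.sign(a.mean() - b.mean()), 0.0
    else:
        t_stat, p = stats.ttest_ind(a, b, equal_var=equal_var)
    if b.mean() > a.mean():
        concl = "model"
    elif a.mean() > b.mean():
        concl = "raw"
    else:
        concl = "tie"
    return ArmComparison(
        k=int(k), mean_quality_raw=float(a.mean()),
        mean_quality_model=float(b.mean()),
        t_stat=float(t_stat), p_value=float(p), conclusion=concl)
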