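"""Consensus k-means clustering with resampling-based stability.

The data are clustered many times on random 80% subsamples; the
consensus matrix D records, for every pair of items, the fraction of
co-sampled resamples in which the pair landed in the same k-means
cluster:

    D(i, j) = sum_h M_h(i, j) / sum_h I_h(i, j)

where M_h is the connectivity matrix of the h-th resample (1 if i and j
share a cluster) and I_h indicates joint presence in the h-th subsample.
The final partition is average-linkage hierarchical clustering on the
dissimilarity 1 - D; items that do not sit firmly inside their cluster
(mean consensus to the other members below a threshold) receive an
outlier label.  Cluster stability is summarized by the within-cluster
mean consensus m(k) and its unweighted average over clusters, and a
quality curve over k is obtained by repeating the whole procedure on
80% subsamples.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

__all__ = [
    "OUTLIER",
    "FeatureMatrix",
    "ConsensusResult",
    "QualityCurve",
    "resample_partitions",
    "consensus_matrix",
    "final_partition",
    "cluster_consensus",
    "consensus_cluster",
    "quality_curve",
]

OUTLIER = -1  # label assigned to items without a secure cluster


class DegenerateClusteringError(ValueError):
    pass


@dataclass
class FeatureMatrix:
    """Items x features matrix, z-scored per feature."""

    items: List[str]
    features: List[str]
    X: np.ndarray

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "FeatureMatrix":
        """Build from a DataFrame (rows = items, columns = features).

        Features are standardized to zero mean / unit SD; constant
        features are centered only (zero variance carries no distance
        information either way).
        """
        if df.isna().any().any():
            raise ValueError("feature matrix must not contain missing values")
        X = df.to_numpy(dtype=float)
        mu = X.mean(axis=0)
        sd = X.std(axis=0, ddof=0)
        sd = np.where(sd > 0, sd, 1.0)
        return cls(items=list(df.index.astype(str)),
                   features=list(df.columns.astype(str)),
                   X=(X - mu) / sd)

    @property
    def n(self) -> int:
        return self.X.shape[0]


@dataclass
class ConsensusResult:
    D: np.ndarray           # consensus indices, 0 where never co-sampled
    M_sum: np.ndarray       # co-cluster tallies
    I_sum: np.ndarray       # co-sample tallies
    never_cosampled: np.ndarray  # bool mask of undefined pairs
    labels: np.ndarray      # final assignment, OUTLIER allowed
    m_k: Dict[int, float]   # per-cluster consensus
    mean_consensus: float
    k: int
    n_resamples: int


@dataclass
class QualityCurve:
    k_values: List[int]
    mean: List[float]
    ci_halfwidth: List[float]  # 1.96 * SE over repeats
    samples: Dict[int, np.ndarray]  # per-k quality samples


def resample_partitions(
    X: np.ndarray,
    k: int,
    n_resamples: int = 1000,
    frac: float = 0.8,
    seed: int = 0,
) -> List[Tuple[np.ndarray, np.ndarray]]:
    """Cluster ``n_resamples`` random subsamples with single-run k-means.

    Each resample draws ceil(frac * N) items without replacement and runs
    one k-means (random init, Euclidean).  Returns (index mask, labels)
    pairs; deterministic under the seed.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if not 0 < frac <= 1:
        raise ValueError("frac must be in (0, 1]")
    n = X.shape[0]
    m = int(np.ceil(frac * n))
    if k > m:
        raise ValueError(f"k={k} exceeds subsample size {m}")
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_resamples):
        idx = np.sort(rng.choice(n, size=m, replace=False))
        # randomized k-means++ seeding, one run per resample: the resampling
        # provides the perturbation, the seeding keeps single runs sane
        km = KMeans(n_clusters=k, n_init=1, init="k-means++", max_iter=300,
                    tol=1e-4, random_state=int(rng.integers(2 ** 31)))
        labels = km.fit_predict(X[idx])
        out.append((idx, labels))
    return out


def consensus_matrix(
    partitions: Sequence[Tuple[np.ndarray, np.ndarray]],
    n: int,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Entrywise ratio of co-cluster to co-sample counts.

    Pairs that were never co-sampled have an undefined consensus; they
    are stored as 0 and flagged in the returned mask.
    """
    if not partitions:
        raise ValueError("at least one partition is required")
    M = np.zeros((n, n))
    I = np.zeros((n, n))
    for idx, labels in partitions:
        I[np.ix_(idx, idx)] += 1.0
        for lab in np.unique(labels):
            members = idx[labels == lab]
            M[np.ix_(members, members)] += 1.0
    never = I == 0
    D = np.divide(M, I, out=np.zeros_like(M), where=~never)
    np.fill_diagonal(D, 1.0)
    return D, M, I, never


def _average_linkage_cut(dist: np.ndarray, k: int) -> np.ndarray:
    """Agglomerative average linkage stopped at k clusters.

    Implemented directly (Lance-Williams updates) so that exact distance
    ties resolve deterministically: prefer the merge with the smaller
    combined size, then the lexicographically smallest indices.  This
    keeps hand-checkable consensus matrices (which are full of exact
    rational ties) reproducible.
    """
    n = dist.shape[0]
    d = dist.astype(float).copy()
    np.fill_diagonal(d, np.inf)
    sizes = np.ones(n)
    labels = np.arange(n)
    active = np.ones(n, dtype=bool)
    for _ in range(n - k):
        dmin = d.min()
        ii, jj = np.where(d == dmin)
        upper = ii < jj
        ii, jj = ii[upper], jj[upper]
        order = np.lexsort((jj, ii, sizes[ii] + sizes[jj]))
        i, j = int(ii[order[0]]), int(jj[order[0]])
        # Lance-Williams update for average linkage
        merged = (sizes[i] * d[i] + sizes[j] * d[j]) / (sizes[i] + sizes[j])
        d[i], d[:, i] = merged, merged
        d[j], d[:, j] = np.inf, np.inf
        d[i, i] = np.inf
        sizes[i] += sizes[j]
        active[j] = False
        labels[labels == j] = i
    # relabel clusters 0..k-1 in order of first appearance
    remap = {old: new for new, old in
             enumerate(dict.fromkeys(labels.tolist()))}
    return np.array([remap[l] for l in labels])


def final_partition(
    D: np.ndarray,
    k: int,
    tau: float = 0.5,
) -> np.ndarray:
    """Cut average-linkage hierarchy of 1 - D at k clusters, mark outliers.

    An item is an outlier when its mean consensus with the other members
    of its own cluster falls below ``tau``; all items becoming outliers
    is reported as a degenerate result.
    """
    n = D.shape[0]
    dist = 1.0 - D
    np.fill_diagonal(dist, 0.0)
    labels = _average_linkage_cut(dist, k)
    out = labels.copy()
    for lab in np.unique(labels):
        members = np.where(labels == lab)[0]
        if len(members) < 2:
            continue
        sub = D[np.ix_(members, members)]
        mean_own = (sub.sum(axis=1) - 1.0) / (len(members) - 1)
        out[members[mean_own < tau]] = OUTLIER
    if (out == OUTLIER).all():
        raise DegenerateClusteringError("all items labelled as outliers")
    return out


def cluster_consensus(
    D: np.ndarray,
    labels: np.ndarray,
) -> Tuple[Dict[int, float], float]:
    """Within-cluster mean pairwise consensus m(k) and its cluster average.

    Outlier items are excluded; singleton clusters receive m(k) = 1 (a
    single item is trivially consistent with itself).
    """
    m_k: Dict[int, float] = {}
    for lab in sorted(set(labels.tolist()) - {OUTLIER}):
        members = np.where(labels == lab)[0]
        if len(members) < 2:
            m_k[int(lab)] = 1.0
            continue
        sub = D[np.ix_(members, members)]
        iu = np.triu_indices(len(members), 1)
        m_k[int(lab)] = float(sub[iu].mean())
    if not m_k:
        raise DegenerateClusteringError("no non-outlier cluster present")
    return m_k, float(np.mean(list(m_k.values())))


def consensus_cluster(
    X: np.ndarray,
    k: int,
    n_resamples: int = 1000,
    frac: float = 0.8,
    tau: float = 0.5,
    seed: int = 0,
) -> ConsensusResult:
    """Full consensus clustering of one feature matrix at one k."""
    parts = resample_partitions(X, k, n_resamples=n_resamples, frac=frac,
                                seed=seed)
    D, M, I, never = consensus_matrix(parts, X.shape[0])
    labels = final_partition(D, k, tau=tau)
    m_k, mean_c = cluster_consensus(D, labels)
    return ConsensusResult(D=D, M_sum=M, I_sum=I, never_cosampled=never,
                           labels=labels, m_k=m_k, mean_consensus=mean_c,
                           k=k, n_resamples=n_resamples)


def quality_curve(
    X: np.ndarray,
    k_values: Sequence[int],
    repeats: int = 100,
    frac: float = 0.8,
    inner_resamples: int = 100,
    tau: float = 0.5,
    seed: int = 0,
) -> QualityCurve:
    """Mean clustering quality with 95% CIs over repeated subsampling.

    Per k, the full consensus procedure runs ``repeats`` times on fresh
    80% subsamples of the data (with ``inner_resamples`` resamples per
    run); quality of one run is its mean cluster consensus.
    """
    if min(k_values) < 2 or max(k_values) > 10:
        raise ValueError("k range must lie within [2, 10]")
    rng = np.random.default_rng(seed)
    n = X.shape[0]
    m = int(np.ceil(frac * n))
    means: List[float] = []
    cis: List[float] = []
    samples: Dict[int, np.ndarray] = {}
    for k in k_values:
        vals = np.empty(repeats)
        for r in range(repeats):
            idx = np.sort(rng.choice(n, size=m, replace=False))
            try:
                res = consensus_cluster(
                    X[idx], k, n_resamples=inner_resamples, frac=frac,
                    tau=tau, seed=int(rng.integers(2 ** 31)))
                vals[r] = res.mean_consensus
            except DegenerateClusteringError:
                vals[r] = 0.0
        samples[int(k)] = vals
        means.append(float(vals.mean()))
        cis.append(float(1.96 * vals.std(ddof=1) / np.sqrt(repeats)))
    return QualityCurve(k_values=[int(k) for k in k_values], mean=means,
                        ci_halfwidth=cis, samples=samples)
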