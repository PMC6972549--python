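"""Enterotype-style discovery of rumen community types ("ruminotypes").

The procedure mirrors the classic human-gut enterotyping recipe: a
probability-distribution distance (square root of the Jensen-Shannon
divergence, which is a metric) between genus relative-abundance profiles,
partitioning around medoids (PAM) clustering, model selection by the
Calinski-Harabasz (CH) variance-ratio index with silhouette reported
alongside, cluster-wise Jaccard bootstrap stability, and least-squares-means
association of the resulting clusters with an adjusted phenotype.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.metrics import calinski_harabasz_score, silhouette_samples

from .data_model import AbundanceTable
from .diversity import DistanceMatrix

__all__ = [
    "jsd_distance",
    "PAMMedoids",
    "pam",
    "ClusterSolution",
    "pcoa_embedding",
    "ch_index",
    "silhouette",
    "select_k",
    "ClusterQuality",
    "jaccard_bootstrap",
    "StabilityReport",
    "cluster_phenotype_assoc",
]


# ---------------------------------------------------------------------------
# Jensen-Shannon distance
# ---------------------------------------------------------------------------

def jsd_distance(x, pseudo=1e-9, sqrt=True) -> DistanceMatrix:
    """Pairwise (square-root) Jensen-Shannon divergence between sample profiles.

    JSD(p, q) = KL(p||m)/2 + KL(q||m)/2 with m = (p+q)/2, natural log. Zeros
    are replaced by ``pseudo`` and the profiles renormalised. The default
    returns sqrt(JSD), which satisfies the triangle inequality.
    """
    if isinstance(x, AbundanceTable):
        if x.transform != "relative":
            raise ValueError("jsd_distance expects relative abundances")
        P = x.values.copy()
        ids = list(x.sample_ids)
    else:
        P = np.asarray(x, dtype=float).copy()
        ids = [str(i) for i in range(P.shape[1])]
    P = np.where(P <= 0, pseudo, P)
    P /= P.sum(axis=0, keepdims=True)
    logP = np.log(P)
    # entropy of each profile
    H = -(P * logP).sum(axis=0)
    n = P.shape[1]
    D = np.zeros((n, n))
    for i in range(n):
        M = 0.5 * (P[:, i : i + 1] + P[:, i + 1 :])
        Hm = -(M * np.log(M)).sum(axis=0)
        jsd = Hm - 0.5 * (H[i] + H[i + 1 :])
        D[i, i + 1 :] = D[i + 1 :, i] = np.maximum(jsd, 0.0)
    if sqrt:
        D = np.sqrt(D)
    return DistanceMatrix(ids, D, "jsd_sqrt" if sqrt else "other")


# ---------------------------------------------------------------------------
# PAM
# ---------------------------------------------------------------------------

class PAMMedoids(BaseEstimator, ClusterMixin):
    """Partitioning around medoids on a precomputed dissimilarity matrix.

    BUILD seeds medoids greedily (first medoid minimises the total distance,
    each next medoid maximises the cost reduction); SWAP exchanges a medoid
    with a non-medoid while any exchange lowers the total cost. Because the
    swap neighbourhood has local optima, small problems (``n <=
    multistart_max_n``) additionally restart SWAP from alternative greedy
    seedings, one per forced first medoid, and keep the cheapest local
    optimum. Every tie breaks toward the lowest sample index, so the
    algorithm is fully deterministic: no randomness is involved.

    Attributes (after ``fit``): ``medoid_indices_``, ``labels_``,
    ``inertia_`` (total within-cluster distance to medoids) and
    ``cost_trace_`` (cost after BUILD and after each accepted swap of the
    winning start, which is strictly decreasing).
    """

    def __init__(self, n_clusters=3, max_swaps=200, multistart_max_n=32):
        self.n_clusters = n_clusters
        self.max_swaps = max_swaps
        self.multistart_max_n = multistart_max_n

    def _build(self, D, first):
        medoids = [first]
        dist_near = D[first].copy()
        while len(medoids) < self.n_clusters:
            gains = np.maximum(dist_near[None, :] - D, 0.0).sum(axis=1)
            gains[medoids] = -np.inf
            c = int(np.argmax(gains))
            medoids.append(c)
            dist_near = np.minimum(dist_near, D[c])
        return sorted(medoids)

    def _swap(self, D, medoids):
        n = D.shape[0]
        medoids = list(medoids)
        cost = float(np.minimum.reduce(D[medoids]).sum())
        trace = [cost]
        for _ in range(self.max_swaps):
            best = (0.0, None, None)
            med_arr = np.array(medoids)
            cur = D[med_arr].min(axis=0).sum()
            for mi in range(len(medoids)):
                others = np.delete(med_arr, mi)
                d_others = np.min(D[others], axis=0) if others.size else np.full(n, np.inf)
                for h in range(n):
                    if h in medoids:
                        continue
                    delta = np.minimum(d_others, D[h]).sum() - cur
                    if delta < best[0] - 1e-12:
                        best = (delta, mi, h)
            if best[1] is None:
                break
            medoids[best[1]] = best[2]
            medoids = sorted(medoids)
            cost = float(np.minimum.reduce(D[medoids]).sum())
            trace.append(cost)
        return medoids, cost, trace

    def fit(self, X, y=None):
        D = X.values if isinstance(X, DistanceMatrix) else np.asarray(X, dtype=float)
        n = D.shape[0]
        k = self.n_clusters
        if not 2 <= k < n:
            raise ValueError(f"n_clusters must satisfy 2 <= k < n (got k={k}, n={n})")

        starts = [int(np.argmin(D.sum(axis=1)))]
        if n <= self.multistart_max_n:
            starts += [s for s in range(n) if s != starts[0]]
        best = None
        for first in starts:
            medoids, cost, trace = self._swap(D, self._build(D, first))
            key = (cost, tuple(medoids))
            if best is None or key < best[0]:
                best = (key, medoids, cost, trace)

        _, medoids, cost, trace = best
        med_arr = np.array(medoids)
        self.medoid_indices_ = med_arr
        self.labels_ = np.argmin(D[med_arr], axis=0)
        self.inertia_ = cost
        self.cost_trace_ = np.array(trace)
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


@dataclass
class ClusterSolution:
    k: int
    labels: np.ndarray
    medoid_ids: list
    cost: float


def pam(d: DistanceMatrix, k: int, seed=None) -> ClusterSolution:
    """Cluster a distance matrix with PAM (deterministic; ``seed`` ignored)."""
    model = PAMMedoids(n_clusters=k).fit(d)
    medoid_ids = [d.sample_ids[i] for i in model.medoid_indices_]
    return ClusterSolution(k, model.labels_, medoid_ids, model.inertia_)


# ---------------------------------------------------------------------------
# cluster-number selection
# ---------------------------------------------------------------------------

def pcoa_embedding(d: DistanceMatrix) -> np.ndarray:
    """Classical MDS coordinates of a distance matrix, nonnegative eigenvalues only."""
    D = d.values
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    G = -0.5 * J @ (D**2) @ J
    vals, vecs = np.linalg.eigh(G)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    keep = vals > max(vals.max(), 0) * 1e-10
    if not keep.any():
        raise ValueError("distance matrix has no positive eigenvalues")
    return vecs[:, keep] * np.sqrt(vals[keep])


def ch_index(d: DistanceMatrix, labels, embedding="pcoa") -> float:
    """Calinski-Harabasz index [B/(k-1)] / [W/(n-k)].

    ``embedding="pcoa"`` (default) computes variances on the classical-MDS
    coordinates of the distance matrix; ``embedding="direct"`` uses the
    pairwise-distance identity for sums of squares without embedding.
    """
    labels = np.asarray(labels)
    n = d.n_samples
    k = len(np.unique(labels))
    if not 2 <= k <= n - 1:
        raise ValueError("CH index requires 2 <= k <= n-1")
    if embedding == "pcoa":
        coords = pcoa_embedding(d)
        return float(calinski_harabasz_score(coords, labels))
    if embedding == "direct":
        D2 = d.values**2
        total = D2.sum() / (2 * n)
        within = 0.0
        for c in np.unique(labels):
            idx = np.flatnonzero(labels == c)
            within += D2[np.ix_(idx, idx)].sum() / (2 * len(idx))
        between = total - within
        if within <= 0:
            return np.inf
        return float((between / (k - 1)) / (within / (n - k)))
    raise ValueError(f"unknown embedding {embedding!r}")


def silhouette(d: DistanceMatrix, labels) -> tuple[float, np.ndarray]:
    """Mean and per-sample silhouette widths on a precomputed distance matrix."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("silhouette requires >= 2 clusters")
    per = silhouette_samples(d.values, labels, metric="precomputed")
    return float(per.mean()), per


@dataclass
class ClusterQuality:
    ks: list
    ch: list
    silhouette_mean: list
    chosen_k: int
    solutions: dict = field(repr=False, default_factory=dict)


def select_k(d: DistanceMatrix, k_range=range(2, 9), embedding="pcoa") -> ClusterQuality:
    """PAM at each candidate k; the chosen k maximises the CH index."""
    ks, chs, sils, sols = [], [], [], {}
    for k in k_range:
        sol = pam(d, k)
        ks.append(k)
        chs.append(ch_index(d, sol.labels, embedding=embedding))
        sils.append(silhouette(d, sol.labels)[0])
        sols[k] = sol
    chosen = ks[int(np.argmax(chs))]
    return ClusterQuality(ks, chs, sils, chosen, sols)


# ---------------------------------------------------------------------------
# bootstrap stability
# ---------------------------------------------------------------------------

@dataclass
class StabilityReport:
    per_cluster: np.ndarray  # mean Jaccard similarity per original cluster
    n_boot: int


def jaccard_bootstrap(d: DistanceMatrix, k: int, n_boot=100, seed=0) -> StabilityReport:
    """Cluster-wise Jaccard bootstrap stability (Hennig-style).

    Each repetition reclusters a bootstrap resample (with replacement) of the
    samples, extends the bootstrap solution to every original sample by
    nearest-medoid classification, and matches each original cluster to the
    bootstrap cluster with maximal Jaccard similarity. Reported is the mean
    best-match Jaccard per original cluster.
    """
    rng = np.random.default_rng(seed)
    base = pam(d, k)
    orig = [set(np.flatnonzero(base.labels == c)) for c in range(k)]
    n = d.n_samples
    sums = np.zeros(k)
    for _ in range(n_boot):
        idx = np.sort(rng.integers(0, n, n))
        model = PAMMedoids(n_clusters=k).fit(d.values[np.ix_(idx, idx)])
        medoids = idx[model.medoid_indices_]
        full_labels = np.argmin(d.values[medoids], axis=0)
        boot_clusters = [set(np.flatnonzero(full_labels == c)) for c in range(k)]
        for c in range(k):
            a = orig[c]
            best = max((len(a & b) / len(a | b) for b in boot_clusters if b), default=0.0)
            sums[c] += best
    return StabilityReport(sums / n_boot, n_boot)


# ---------------------------------------------------------------------------
# cluster-phenotype association
# ---------------------------------------------------------------------------

def cluster_phenotype_assoc(labels, values, alpha=0.05) -> dict:
    """Least-squares means per cluster and all pairwise contrasts.

    The one-way model pools the residual variance across clusters; each
    contrast reports the plain pooled-variance t-test p-value and the
    Tukey-HSD adjusted p-value (studentized range). Returns a dict with
    ``means`` (per-cluster lsmeans) and ``contrasts`` DataFrames.
    """
    labels = np.asarray(labels)
    values = np.asarray(values, dtype=float)
    groups = np.unique(labels)
    if len(groups) < 2:
        raise ValueError("association test needs >= 2 clusters")
    n = len(values)
    k = len(groups)
    means = {g: values[labels == g].mean() for g in groups}
    sizes = {g: int((labels == g).sum()) for g in groups}
    sse = sum(((values[labels == g] - means[g]) ** 2).sum() for g in groups)
    df_resid = n - k
    mse = sse / df_resid
    se_mean = {g: np.sqrt(mse / sizes[g]) for g in groups}

    rows = []
    for a, b in itertools.combinations(groups, 2):
        diff = means[a] - means[b]
        se = np.sqrt(mse * (1 / sizes[a] + 1 / sizes[b]))
        t = diff / se
        p_t = 2 * stats.t.sf(abs(t), df_resid)
        q = abs(t) * np.sqrt(2)
        p_tukey = float(stats.studentized_range.sf(q, k, df_resid))
        rows.append(
            {
                "group_a": a,
                "group_b": b,
                "diff": diff,
                "se": se,
                "t": t,
                "p_value": p_t,
                "p_tukey": min(p_tukey, 1.0),
                "significant": p_tukey < alpha,
            }
        )
    means_df = pd.DataFrame(
        {
            "cluster": groups,
            "n": [sizes[g] for g in groups],
            "lsmean": [means[g] for g in groups],
            "se": [se_mean[g] for g in groups],
        }
    )
    return {"means": means_df, "contrasts": pd.DataFrame(rows)}
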