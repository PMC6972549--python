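"""Alpha/beta diversity, ecological dissimilarities, RV co-structure and PERMANOVA.

These are the community-comparison primitives of the pipeline: Shannon alpha
diversity, Whittaker multiplicative beta diversity, Bray-Curtis and binary
Jaccard dissimilarity matrices, the RV coefficient quantifying co-structure
between two sample-matched tables (used for temporal stability of the
community), and a PERMANOVA with covariates fitted before the factor of
interest (sequential sums of squares, adonis-style).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .data_model import AbundanceTable, CountTable, to_relative

__all__ = [
    "DistanceMatrix",
    "shannon",
    "shannon_per_sample",
    "whittaker_beta",
    "bray_curtis",
    "jaccard_binary",
    "rv_coefficient",
    "permanova",
    "PermanovaResult",
]


@dataclass
class DistanceMatrix:
    """Symmetric dissimilarity matrix over samples with a metric tag."""

    sample_ids: list
    values: np.ndarray
    metric: str = "other"

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        n = len(self.sample_ids)
        if v.shape != (n, n):
            raise ValueError("distance matrix shape does not match sample ids")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0, atol=1e-10):
            raise ValueError("distance matrix diagonal must be zero")
        if v.size and v.min() < -1e-12:
            raise ValueError("distances must be nonnegative")
        if self.metric in ("bray_curtis", "jaccard_binary") and v.size and v.max() > 1 + 1e-9:
            raise ValueError(f"{self.metric} distances must be <= 1")
        self.values = 0.5 * (v + v.T)
        np.fill_diagonal(self.values, 0.0)

    @property
    def n_samples(self):
        return len(self.sample_ids)

    def condensed(self) -> np.ndarray:
        return squareform(self.values, checks=False)


def _sample_matrix(x) -> tuple[np.ndarray, list]:
    """Return (samples x features array, sample ids) from a table or array."""
    if isinstance(x, CountTable):
        return x.counts.T.astype(float), list(x.sample_ids)
    if isinstance(x, AbundanceTable):
        return x.values.T.copy(), list(x.sample_ids)
    arr = np.asarray(x, dtype=float)
    return arr, [str(i) for i in range(arr.shape[0])]


def shannon(p, check=True) -> float:
    """Shannon diversity H = -sum p_i ln p_i (nats), zero entries skipped."""
    p = np.asarray(p, dtype=float)
    if check and not np.isclose(p.sum(), 1.0, atol=1e-6):
        raise ValueError("probabilities must sum to 1")
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum())


def shannon_per_sample(table) -> pd.Series:
    """Shannon index (nats) for every sample of a count or relative table."""
    if isinstance(table, CountTable):
        table = to_relative(table)
    vals = table.values if isinstance(table, AbundanceTable) else np.asarray(table, float)
    ids = table.sample_ids if isinstance(table, AbundanceTable) else range(vals.shape[1])
    return pd.Series([shannon(vals[:, j]) for j in range(vals.shape[1])], index=list(ids))


def whittaker_beta(table) -> float:
    """Whittaker multiplicative beta diversity: gamma / mean alpha - 1.

    gamma is the pooled richness over all samples; mean alpha the average
    per-sample richness (presence = count > 0).
    """
    if isinstance(table, CountTable):
        presence = table.counts > 0
    elif isinstance(table, AbundanceTable):
        presence = table.values > 0
    else:
        presence = np.asarray(table) > 0
    alpha = presence.sum(axis=0)
    if (alpha == 0).any():
        raise ValueError("sample with zero richness")
    gamma = presence.any(axis=1).sum()
    return float(gamma / alpha.mean() - 1.0)


def bray_curtis(x) -> DistanceMatrix:
    """Bray-Curtis dissimilarity d(a,b) = sum|a_i - b_i| / sum(a_i + b_i)."""
    mat, ids = _sample_matrix(x)
    d = squareform(pdist(mat, metric="braycurtis"))
    return DistanceMatrix(ids, d, "bray_curtis")


def jaccard_binary(x) -> DistanceMatrix:
    """Binary Jaccard dissimilarity 1 - |A & B| / |A | B| on presence sets."""
    mat, ids = _sample_matrix(x)
    d = squareform(pdist(mat > 0, metric="jaccard"))
    return DistanceMatrix(ids, d, "jaccard_binary")


def rv_coefficient(x, y) -> float:
    """RV coefficient between two sample-matched matrices.

    Columns are centred; RV = tr(XX'YY') / sqrt(tr((XX')^2) tr((YY')^2)),
    i.e. total co-inertia over the geometric mean of the two total inertias.
    0 means no shared structure, values near 1 strong co-structure.
    """
    X, ids_x = _sample_matrix(x)
    Y, ids_y = _sample_matrix(y)
    if X.shape[0] != Y.shape[0]:
        raise ValueError("matrices must share the sample axis")
    if isinstance(x, (CountTable, AbundanceTable)) and isinstance(y, (CountTable, AbundanceTable)):
        if ids_x != ids_y:
            raise ValueError("sample ids do not match")
    X = X - X.mean(axis=0, keepdims=True)
    Y = Y - Y.mean(axis=0, keepdims=True)
    Sx = X @ X.T
    Sy = Y @ Y.T
    den = np.sqrt((Sx * Sx).sum() * (Sy * Sy).sum())
    if den == 0:
        raise ValueError("zero matrix has no RV coefficient")
    return float((Sx * Sy).sum() / den)


@dataclass
class PermanovaResult:
    statistic: float  # pseudo-F of the grouping factor
    p_value: float
    df_between: int
    df_resid: int
    ss_between: float
    ss_resid: float
    n_permutations: int
    permuted_f: np.ndarray = field(repr=False, default=None)


def _factor_dummies(values) -> np.ndarray:
    codes, _ = pd.factorize(np.asarray(values))
    levels = codes.max() + 1
    if levels < 2:
        return np.empty((len(codes), 0))
    out = np.zeros((len(codes), levels - 1))
    for j in range(1, levels):
        out[codes == j, j - 1] = 1.0
    return out


def _hat(X: np.ndarray) -> tuple[np.ndarray, int]:
    q, r = np.linalg.qr(X)
    diag = np.abs(np.diag(r))
    rank = int((diag > 1e-10 * max(diag.max(), 1.0)).sum())
    q = q[:, :rank]
    return q @ q.T, rank


def permanova(d: DistanceMatrix, groups, covariates=None, n_perm=999, seed=None) -> PermanovaResult:
    """Permutational MANOVA of ``groups`` on a dissimilarity matrix.

    Covariate factors are fitted first (sequential sums of squares); the
    pseudo-F of the grouping factor is referenced against ``n_perm`` random
    permutations of the sample labels with the design held fixed, giving
    p = (1 + #{F_perm >= F_obs}) / (1 + n_perm).
    """
    groups = np.asarray(groups)
    n = d.n_samples
    if len(groups) != n:
        raise ValueError("groups length does not match distance matrix")
    if len(np.unique(groups)) < 2:
        raise ValueError("PERMANOVA needs >= 2 groups")

    A = -0.5 * d.values**2
    J = np.eye(n) - np.ones((n, n)) / n
    G = J @ A @ J  # Gower-centred inner-product matrix

    cols = [np.ones((n, 1))]
    if covariates is not None:
        if isinstance(covariates, (pd.DataFrame, dict)):
            cov_iter = (covariates[c] for c in covariates)
        else:
            cov = np.asarray(covariates)
            cov_iter = (cov,) if cov.ndim == 1 else (cov[:, j] for j in range(cov.shape[1]))
        for c in cov_iter:
            cols.append(_factor_dummies(c))
    X_cov = np.hstack(cols)
    X_full = np.hstack([X_cov, _factor_dummies(groups)])
    H_cov, rank_cov = _hat(X_cov)
    H_full, rank_full = _hat(X_full)
    df_between = rank_full - rank_cov
    df_resid = n - rank_full
    if df_between < 1 or df_resid < 1:
        raise ValueError("degenerate design: no degrees of freedom")

    Hg = H_full - H_cov
    R = np.eye(n) - H_full
    ss_between = float((Hg * G).sum())  # tr(Hg G)
    ss_resid = float((R * G).sum())
    f_obs = (ss_between / df_between) / (ss_resid / df_resid)

    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(n) for _ in range(n_perm)])
    Gp = G[perms[:, :, None], perms[:, None, :]]
    ssb = np.einsum("ij,bij->b", Hg, Gp)
    ssr = np.einsum("ij,bij->b", R, Gp)
    f_perm = (ssb / df_between) / (ssr / df_resid)
    p = (1.0 + np.sum(f_perm >= f_obs)) / (1.0 + n_perm)
    return PermanovaResult(
        float(f_obs), float(p), df_between, df_resid, ss_between, ss_resid, n_perm, f_perm
    )
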