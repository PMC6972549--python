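"""Sparse partial least squares in regression and discriminant modes.

sPLS seeks, component by component, a sparse X-weight vector and a Y-weight
vector maximising the covariance between the projected data sets. Sparsity is
imposed as a per-component cardinality (``keep_x``): the X-weight is
soft-thresholded so that at most ``keep_x`` entries stay nonzero, then
renormalised (the mixOmics convention). Both modes use regression deflation,
so successive X scores are orthogonal.

The discriminant mode (sPLS-DA) codes the class labels as a one-hot indicator
matrix and predicts with the "max.dist" rule: a sample is assigned to the
class whose predicted indicator value is largest.

Cross-validated tuning reports Q2 per component for regression
(1 - PRESS_h / RSS_{h-1}, with the classical 0.0975 retention threshold) and
the overall/balanced error rate (BER) for classification, over repeated
(stratified) 5-fold splits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, RegressorMixin, TransformerMixin
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import KFold, StratifiedKFold

__all__ = [
    "SparsePLS",
    "SparsePLSDA",
    "spls_fit",
    "splsda_fit",
    "tune_cv",
    "CvReport",
    "auroc",
    "intersect_biomarkers",
    "BiomarkerSet",
]


def _soft_threshold_keep(u: np.ndarray, keep: int) -> np.ndarray:
    """Shrink all but the ``keep`` largest |entries| of u to zero (soft threshold)."""
    p = u.shape[0]
    if keep >= p:
        return u
    absu = np.abs(u)
    lam = np.partition(absu, p - keep - 1)[p - keep - 1]  # largest excluded magnitude
    return np.sign(u) * np.maximum(absu - lam, 0.0)


class SparsePLS(BaseEstimator, RegressorMixin, TransformerMixin):
    """Sparse PLS regression (mixOmics-style keepX cardinality constraint).

    Parameters
    ----------
    n_components : number of latent components.
    keep_x : None (dense), an int applied to every component, or a sequence of
        per-component cardinalities.
    scale : standardise X and Y columns (unit variance, ddof=1) before fitting.

    Fitted attributes: ``x_weights_`` (p x h sparse weight vectors, unit
    norm), ``x_loadings_``, ``y_loadings_``, ``x_scores_``, ``coef_``,
    ``intercept_`` and the centring/scaling vectors.
    """

    def __init__(self, n_components=2, keep_x=None, scale=True, max_iter=500, tol=1e-9):
        self.n_components = n_components
        self.keep_x = keep_x
        self.scale = scale
        self.max_iter = max_iter
        self.tol = tol

    def _keepx_list(self, p):
        if self.keep_x is None:
            return [p] * self.n_components
        if np.isscalar(self.keep_x):
            keep = [int(self.keep_x)] * self.n_components
        else:
            keep = [int(k) for k in self.keep_x]
            if len(keep) != self.n_components:
                raise ValueError("keep_x must have one entry per component")
        if any(k < 1 or k > p for k in keep):
            raise ValueError(f"keep_x entries must be in 1..{p}")
        return keep

    def fit(self, X, Y):
        X = np.asarray(X, dtype=float)
        Y = np.asarray(Y, dtype=float)
        if Y.ndim == 1:
            Y = Y[:, None]
        n, p = X.shape
        if self.n_components > min(n - 1, p):
            raise ValueError("n_components exceeds the rank of X")
        keepx = self._keepx_list(p)

        self.x_mean_ = X.mean(axis=0)
        self.y_mean_ = Y.mean(axis=0)
        if self.scale:
            self.x_std_ = X.std(axis=0, ddof=1)
            self.y_std_ = Y.std(axis=0, ddof=1)
            self.x_std_[self.x_std_ == 0] = 1.0
            self.y_std_[self.y_std_ == 0] = 1.0
        else:
            self.x_std_ = np.ones(p)
            self.y_std_ = np.ones(Y.shape[1])
        Xd = (X - self.x_mean_) / self.x_std_
        Yd = (Y - self.y_mean_) / self.y_std_

        W = np.zeros((p, self.n_components))  # sparse X weights
        C = np.zeros((p, self.n_components))  # X loadings
        Dy = np.zeros((Y.shape[1], self.n_components))  # Y loadings
        V = np.zeros((Y.shape[1], self.n_components))  # Y weights
        T = np.zeros((n, self.n_components))

        for h in range(self.n_components):
            M = Xd.T @ Yd
            if not np.any(M):
                raise ValueError("deflated cross-covariance is zero; reduce n_components")
            # dominant singular pair with sparsity on the left vector
            u, _, vt = np.linalg.svd(M, full_matrices=False)
            uvec, vvec = u[:, 0], vt[0]
            for _ in range(self.max_iter):
                u_new = _soft_threshold_keep(M @ vvec, keepx[h])
                norm = np.linalg.norm(u_new)
                if norm == 0:
                    raise ValueError("all X weights thresholded to zero")
                u_new /= norm
                v_new = M.T @ u_new
                v_new /= np.linalg.norm(v_new)
                if np.linalg.norm(u_new - uvec) < self.tol:
                    uvec, vvec = u_new, v_new
                    break
                uvec, vvec = u_new, v_new
            t = Xd @ uvec
            tt = t @ t
            c = Xd.T @ t / tt
            d = Yd.T @ t / tt
            Xd = Xd - np.outer(t, c)
            Yd = Yd - np.outer(t, d)  # regression deflation for both modes
            W[:, h], C[:, h], Dy[:, h], V[:, h], T[:, h] = uvec, c, d, vvec, t

        self.x_weights_, self.x_loadings_, self.y_loadings_ = W, C, Dy
        self.y_weights_, self.x_scores_ = V, T
        # B = W (C'W)^{-1} D' on the standardised scale
        R = W @ np.linalg.pinv(C.T @ W)
        B = R @ Dy.T
        self.coef_ = (B / self.x_std_[:, None]) * self.y_std_[None, :]
        self.intercept_ = self.y_mean_ - self.x_mean_ @ self.coef_
        self.n_features_in_ = p
        return self

    def transform(self, X):
        Xd = (np.asarray(X, dtype=float) - self.x_mean_) / self.x_std_
        T = np.zeros((Xd.shape[0], self.n_components))
        for h in range(self.n_components):
            t = Xd @ self.x_weights_[:, h]
            Xd = Xd - np.outer(t, self.x_loadings_[:, h])
            T[:, h] = t
        return T

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        Y = X @ self.coef_ + self.intercept_
        return Y[:, 0] if Y.shape[1] == 1 else Y

    @property
    def selected_features_(self):
        return np.flatnonzero(np.any(self.x_weights_ != 0, axis=1))

    def selection_table(self, feature_ids=None) -> pd.DataFrame:
        """Selected features with the component of first selection and its weight."""
        W = self.x_weights_
        rows = []
        for j in self.selected_features_:
            comp = int(np.flatnonzero(W[j] != 0)[0])
            rows.append(
                {
                    "feature": feature_ids[j] if feature_ids is not None else j,
                    "component": comp + 1,
                    "weight": W[j, comp],
                    "max_abs_weight": np.abs(W[j]).max(),
                }
            )
        return pd.DataFrame(rows)


class SparsePLSDA(BaseEstimator, ClassifierMixin):
    """Sparse PLS discriminant analysis: one-hot Y, max.dist class prediction."""

    def __init__(self, n_components=2, keep_x=None, scale=True, max_iter=500, tol=1e-9):
        self.n_components = n_components
        self.keep_x = keep_x
        self.scale = scale
        self.max_iter = max_iter
        self.tol = tol

    def fit(self, X, y):
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if len(self.classes_) < 2:
            raise ValueError("need >= 2 classes")
        Y = (y[:, None] == self.classes_[None, :]).astype(float)
        self.pls_ = SparsePLS(
            self.n_components, self.keep_x, self.scale, self.max_iter, self.tol
        ).fit(X, Y)
        return self

    def decision_function(self, X):
        scores = self.pls_.predict(X)
        return scores if scores.ndim == 2 else scores[:, None]

    def predict(self, X):
        return self.classes_[np.argmax(self.decision_function(X), axis=1)]

    def transform(self, X):
        return self.pls_.transform(X)

    @property
    def x_weights_(self):
        return self.pls_.x_weights_

    @property
    def selected_features_(self):
        return self.pls_.selected_features_

    def selection_table(self, feature_ids=None):
        return self.pls_.selection_table(feature_ids)


def spls_fit(X, Y, ncomp=2, keepx=None, **kwargs) -> SparsePLS:
    """Functional wrapper over :class:`SparsePLS`."""
    return SparsePLS(n_components=ncomp, keep_x=keepx, **kwargs).fit(X, Y)


def splsda_fit(X, labels, ncomp=2, keepx=None, **kwargs) -> SparsePLSDA:
    """Functional wrapper over :class:`SparsePLSDA`."""
    return SparsePLSDA(n_components=ncomp, keep_x=keepx, **kwargs).fit(X, labels)


# ---------------------------------------------------------------------------
# cross-validated tuning
# ---------------------------------------------------------------------------

@dataclass
class CvReport:
    mode: str
    folds: int
    repeats: int
    seed: int
    q2: np.ndarray | None = None  # per component (regression)
    n_components_optimal: int | None = None
    error_rate: float | None = None
    ber: float | None = None
    chosen_keepx: tuple | None = None
    grid: pd.DataFrame | None = field(repr=False, default=None)


Q2_RETENTION_THRESHOLD = 0.0975  # classical PLS component-retention rule


def _ber(y_true, y_pred, classes):
    per_class = [np.mean(y_pred[y_true == c] != c) for c in classes if np.any(y_true == c)]
    return float(np.mean(per_class))


def tune_cv(
    X,
    y,
    mode="da",
    ncomp=2,
    keepx=None,
    keepx_grid=None,
    folds=5,
    repeats=500,
    seed=0,
) -> CvReport:
    """Repeated cross-validation for sPLS tuning.

    ``mode="regression"``: computes Q2_h = 1 - PRESS_h / RSS_{h-1} per
    component (PRESS from out-of-fold predictions of the h-component model,
    RSS from the full fit with h-1 components, RSS_0 = total sum of squares);
    the optimal number of components is the largest h whose Q2 stays at or
    above the 0.0975 retention threshold up to h. If ``keepx_grid`` is given,
    the cardinality maximising first-component Q2 is chosen first.

    ``mode="da"``: stratified folds; reports overall misclassification error
    and the balanced error rate (mean of per-class error rates), choosing the
    grid entry with minimal BER (ties -> fewer features).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    rng = np.random.default_rng(seed)

    if mode == "regression":
        yv = y.astype(float).ravel()

        def press_curve(kx):
            press = np.zeros(ncomp)
            for _ in range(repeats):
                kf = KFold(folds, shuffle=True, random_state=int(rng.integers(2**31)))
                for tr, te in kf.split(X):
                    model = SparsePLS(ncomp, kx).fit(X[tr], yv[tr])
                    Xd = (X[te] - model.x_mean_) / model.x_std_
                    T = np.zeros((len(te), ncomp))
                    for h in range(ncomp):
                        t = Xd @ model.x_weights_[:, h]
                        Xd = Xd - np.outer(t, model.x_loadings_[:, h])
                        T[:, h] = t
                    for h in range(ncomp):
                        pred = (
                            model.y_mean_
                            + T[:, : h + 1] @ model.y_loadings_[0, : h + 1] * model.y_std_[0]
                        )
                        press[h] += ((yv[te] - pred) ** 2).sum()
            return press / repeats

        def rss_curve(kx):
            model = SparsePLS(ncomp, kx).fit(X, yv)
            T = model.x_scores_
            rss = np.zeros(ncomp + 1)
            rss[0] = ((yv - yv.mean()) ** 2).sum()
            for h in range(1, ncomp + 1):
                pred = model.y_mean_ + T[:, :h] @ model.y_loadings_[0, :h] * model.y_std_[0]
                rss[h] = ((yv - pred) ** 2).sum()
            return rss

        candidates = keepx_grid if keepx_grid is not None else [keepx]
        best = None
        for kx in candidates:
            press = press_curve(kx)
            rss = rss_curve(kx)
            q2 = 1.0 - press / rss[:-1]
            if best is None or q2[0] > best[1][0]:
                best = (kx, q2)
        kx, q2 = best
        retained = 0
        for h in range(ncomp):
            if q2[h] >= Q2_RETENTION_THRESHOLD:
                retained = h + 1
            else:
                break
        return CvReport(
            "regression", folds, repeats, seed,
            q2=q2, n_components_optimal=max(retained, 1),
            chosen_keepx=tuple(np.atleast_1d(kx)) if kx is not None else None,
        )

    if mode != "da":
        raise ValueError("mode must be 'regression' or 'da'")

    classes = np.unique(y)
    candidates = keepx_grid if keepx_grid is not None else [keepx]
    rows = []
    for kx in candidates:
        errs, bers = [], []
        for _ in range(repeats):
            skf = StratifiedKFold(folds, shuffle=True, random_state=int(rng.integers(2**31)))
            for tr, te in skf.split(X, y):
                if len(np.unique(y[tr])) < len(classes):
                    raise ValueError("a fold lost an entire class; reduce folds")
                model = SparsePLSDA(ncomp, kx).fit(X[tr], y[tr])
                pred = model.predict(X[te])
                errs.append(np.mean(pred != y[te]))
                bers.append(_ber(y[te], pred, classes))
        n_feat = int(np.sum(np.atleast_1d(kx))) if kx is not None else X.shape[1] * ncomp
        rows.append({"keepx": kx, "error_rate": np.mean(errs), "ber": np.mean(bers), "n": n_feat})
    grid = pd.DataFrame(rows)
    best = grid.sort_values(["ber", "n"], kind="stable").iloc[0]
    return CvReport(
        "da", folds, repeats, seed,
        error_rate=float(best["error_rate"]), ber=float(best["ber"]),
        chosen_keepx=tuple(np.atleast_1d(best["keepx"])) if best["keepx"] is not None else None,
        grid=grid,
    )


def auroc(model: SparsePLSDA, X, labels) -> dict:
    """One-vs-rest AUC per class from the model's predicted indicator scores.

    Computed with the rank (Mann-Whitney) formulation, midranks for ties.
    When scores come from the training data this is a resubstitution AUC.
    """
    labels = np.asarray(labels)
    scores = model.decision_function(X)
    return {
        c: float(roc_auc_score((labels == c).astype(int), scores[:, j]))
        for j, c in enumerate(model.classes_)
    }


# ---------------------------------------------------------------------------
# biomarker intersection
# ---------------------------------------------------------------------------

@dataclass
class BiomarkerSet:
    table: pd.DataFrame  # feature_id, source, weight_da, weight_reg, component

    @property
    def common(self) -> list:
        return list(self.table.loc[self.table["source"] == "common", "feature_id"])

    def __len__(self):
        return len(self.common)


def _selection_weights(model, feature_ids):
    tab = model.selection_table(feature_ids)
    if tab.empty:
        return {}
    return dict(zip(tab["feature"], tab["max_abs_weight"]))


def intersect_biomarkers(sel_da, sel_reg, feature_ids=None) -> BiomarkerSet:
    """Intersection of discriminant- and regression-selected feature sets.

    Accepts fitted models or ``{feature: weight}`` mappings. The joint table
    tags every feature ``common``, ``da_only`` or ``reg_only`` and orders by
    descending maximal |weight|.
    """
    if not isinstance(sel_da, dict):
        sel_da = _selection_weights(sel_da, feature_ids)
    if not isinstance(sel_reg, dict):
        sel_reg = _selection_weights(sel_reg, feature_ids)
    feats = sorted(set(sel_da) | set(sel_reg))
    rows = []
    for f in feats:
        in_da, in_reg = f in sel_da, f in sel_reg
        source = "common" if in_da and in_reg else ("da_only" if in_da else "reg_only")
        w = max(abs(sel_da.get(f, 0.0)), abs(sel_reg.get(f, 0.0)))
        rows.append(
            {
                "feature_id": f,
                "source": source,
                "weight_da": sel_da.get(f, np.nan),
                "weight_reg": sel_reg.get(f, np.nan),
                "max_abs_weight": w,
            }
        )
    tab = pd.DataFrame(rows)
    if not tab.empty:
        tab = tab.sort_values(
            ["source", "max_abs_weight"], ascending=[True, False], kind="stable"
        ).reset_index(drop=True)
    return BiomarkerSet(tab)
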