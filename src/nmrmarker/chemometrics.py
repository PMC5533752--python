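"""From-scratch NIPALS chemometrics: scaling, PCA, PLS-DA, OPLS-DA.

The estimators follow the scikit-learn protocol (``fit``, ``transform`` /
``predict``, trailing-underscore fitted attributes) but the algorithms are
implemented here: power-iteration (NIPALS) PCA, NIPALS PLS with X- and
Y-deflation, and OPLS with orthogonal-component filtering of the
class-uncorrelated variation.  Model validation follows discriminant-
analysis practice in metabolomics: stratified 7-fold cross-validated Q²
and a label-permutation test of the observed Q².

Sign conventions are deterministic everywhere (the largest-magnitude
loading element is made positive) so that results are reproducible across
runs and platforms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin, clone

__all__ = [
    "SpectralScaler",
    "NipalsPCA",
    "PLSDA",
    "OPLSDA",
    "ValidationReport",
    "stratified_folds",
    "cross_validate",
    "permutation_test",
    "fit_scaling",
    "apply_scaling",
    "fit_pca",
    "fit_pls",
    "fit_opls",
    "vip",
    "correlation_loadings",
    "loading_plot_data",
]


def _sign_fix(weight: np.ndarray, *aligned: np.ndarray):
    """Flip sign so the largest-|.| element of ``weight`` is positive."""
    i = int(np.argmax(np.abs(weight)))
    if weight[i] < 0:
        return (-weight, *(-(a) for a in aligned))
    return (weight, *aligned)


def _as_2d(X) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be a 2-D array")
    if not np.all(np.isfinite(X)):
        raise ValueError("X contains non-finite values")
    return X


# ---------------------------------------------------------------------------
# Scaling
# ---------------------------------------------------------------------------

class SpectralScaler(BaseEstimator, TransformerMixin):
    """Column scaling for bucket matrices.

    mode
        ``center`` (mean centring only), ``pareto`` (centre then divide by
        the square root of the sample SD) or ``unit_variance``.  Columns
        with zero sample SD carry no information for ``pareto`` /
        ``unit_variance`` scaling; they are dropped and recorded in
        ``dropped_columns_``.
    """

    MODES = ("center", "pareto", "unit_variance")

    def __init__(self, mode: str = "pareto"):
        self.mode = mode

    def fit(self, X, y=None):
        if self.mode not in self.MODES:
            raise ValueError(f"mode must be one of {self.MODES}")
        X = _as_2d(X)
        if X.shape[0] < 2:
            raise ValueError("scaling requires at least 2 rows")
        self.center_ = X.mean(axis=0)
        sd = X.std(axis=0, ddof=1)
        zero = sd <= 0
        if self.mode == "center":
            scale = np.ones_like(sd)
            zero = np.zeros_like(zero)
        elif self.mode == "pareto":
            scale = np.sqrt(sd)
        else:
            scale = sd.copy()
        self.dropped_columns_ = np.where(zero)[0]
        self.kept_columns_ = np.where(~zero)[0]
        self.scale_ = scale[~zero]
        self.center_kept_ = self.center_[~zero]
        return self

    def transform(self, X):
        X = _as_2d(X)
        return (X[:, self.kept_columns_] - self.center_kept_) / self.scale_


def fit_scaling(matrix, mode: str) -> SpectralScaler:
    return SpectralScaler(mode=mode).fit(matrix)


def apply_scaling(matrix, model: SpectralScaler) -> np.ndarray:
    return model.transform(matrix)


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

class NipalsPCA(BaseEstimator, TransformerMixin):
    """Principal component analysis by NIPALS power iteration.

    Components maximize successively explained variance; loadings are
    orthonormal.  If the matrix rank is lower than ``n_components`` the
    model is truncated with a warning.
    """

    def __init__(self, n_components: int = 2, center: bool = True,
                 tol: float = 1e-14, max_iter: int = 10000):
        self.n_components = n_components
        self.center = center
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X, y=None):
        X = _as_2d(X)
        self.mean_ = X.mean(axis=0) if self.center else np.zeros(X.shape[1])
        Xd = X - self.mean_
        total_ssq = float(np.sum(Xd**2))
        scores, loadings, ssqs = [], [], []
        for _ in range(self.n_components):
            res = float(np.sum(Xd**2))
            if total_ssq == 0 or res < 1e-12 * max(total_ssq, 1.0):
                warnings.warn(
                    "requested more components than the matrix rank; truncating",
                    stacklevel=2,
                )
                break
            t = Xd[:, int(np.argmax(np.sum(Xd**2, axis=0)))].copy()
            for _ in range(self.max_iter):
                p = Xd.T @ t / (t @ t)
                p /= np.linalg.norm(p)
                t_new = Xd @ p
                if np.linalg.norm(t_new - t) <= self.tol * max(np.linalg.norm(t_new), 1e-30):
                    t = t_new
                    break
                t = t_new
            p, t = _sign_fix(p, t)
            scores.append(t)
            loadings.append(p)
            ssqs.append(float(t @ t))
            Xd = Xd - np.outer(t, p)
        self.n_components_ = len(scores)
        self.scores_ = np.column_stack(scores) if scores else np.empty((X.shape[0], 0))
        self.loadings_ = np.column_stack(loadings) if loadings else np.empty((X.shape[1], 0))
        self.explained_variance_ratio_ = (
            np.array(ssqs) / total_ssq if total_ssq > 0 else np.array(ssqs)
        )
        return self

    def transform(self, X):
        X = _as_2d(X)
        return (X - self.mean_) @ self.loadings_


def fit_pca(matrix, n_components: int) -> NipalsPCA:
    return NipalsPCA(n_components=n_components).fit(matrix)


# ---------------------------------------------------------------------------
# PLS
# ---------------------------------------------------------------------------

class PLSDA(BaseEstimator, TransformerMixin):
    """NIPALS partial least squares with X- and Y-deflation.

    ``Y`` is a one-hot group matrix for multi-group scores plots or a
    +/-1 vector for a pairwise comparison.
    """

    def __init__(self, n_components: int = 2, tol: float = 1e-12, max_iter: int = 1000):
        self.n_components = n_components
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X, Y):
        X = _as_2d(X)
        Y = np.asarray(Y, dtype=float)
        if Y.ndim == 1:
            Y = Y[:, None]
        if np.allclose(Y, Y[0]):
            raise ValueError("Y is constant")
        self.x_mean_ = X.mean(axis=0)
        self.y_mean_ = Y.mean(axis=0)
        Xd = X - self.x_mean_
        Yd = Y - self.y_mean_
        W, T, P, Q = [], [], [], []
        for _ in range(self.n_components):
            u = Yd[:, int(np.argmax(np.sum(Yd**2, axis=0)))].copy()
            if np.sum(u**2) < 1e-30 or np.sum(Xd**2) < 1e-30:
                warnings.warn("rank exhausted; truncating components", stacklevel=2)
                break
            t = None
            for _ in range(self.max_iter):
                w = Xd.T @ u / (u @ u)
                nw = np.linalg.norm(w)
                if nw == 0:
                    break
                w /= nw
                t_new = Xd @ w
                q = Yd.T @ t_new / (t_new @ t_new)
                u = Yd @ q / (q @ q)
                if t is not None and np.linalg.norm(t_new - t) <= self.tol * max(
                    np.linalg.norm(t_new), 1e-30
                ):
                    t = t_new
                    break
                t = t_new
            if t is None:
                break
            p = Xd.T @ t / (t @ t)
            w, t, p, q = _sign_fix(w, t, p, q)
            W.append(w); T.append(t); P.append(p); Q.append(q)
            Xd = Xd - np.outer(t, p)
            Yd = Yd - np.outer(t, q)
        self.n_components_ = len(T)
        self.x_weights_ = np.column_stack(W)
        self.x_scores_ = np.column_stack(T)
        self.x_loadings_ = np.column_stack(P)
        self.y_loadings_ = np.column_stack(Q)
        return self

    def transform(self, X):
        X = _as_2d(X)
        Xd = X - self.x_mean_
        T = []
        for a in range(self.n_components_):
            t = Xd @ self.x_weights_[:, a]
            T.append(t)
            Xd = Xd - np.outer(t, self.x_loadings_[:, a])
        return np.column_stack(T)


def fit_pls(X, Y, n_components: int = 2) -> PLSDA:
    return PLSDA(n_components=n_components).fit(X, Y)


# ---------------------------------------------------------------------------
# OPLS
# ---------------------------------------------------------------------------

def _opls_core(X: np.ndarray, yc: np.ndarray, n_orth: int) -> dict:
    """One predictive + ``n_orth`` orthogonal components on centred data."""
    Xd = X.copy()
    W_o, T_o, P_o = [], [], []
    for _ in range(n_orth):
        w = Xd.T @ yc
        nw = np.linalg.norm(w)
        if nw < 1e-30:
            break
        w /= nw
        t = Xd @ w
        p = Xd.T @ t / (t @ t)
        w_o = p - (w @ p) * w
        n_wo = np.linalg.norm(w_o)
        if n_wo < 1e-12 * max(np.linalg.norm(p), 1e-30):
            break  # no orthogonal variation left
        w_o /= n_wo
        t_o = Xd @ w_o
        p_o = Xd.T @ t_o / (t_o @ t_o)
        w_o, t_o, p_o = _sign_fix(w_o, t_o, p_o)
        W_o.append(w_o); T_o.append(t_o); P_o.append(p_o)
        Xd = Xd - np.outer(t_o, p_o)
    w = Xd.T @ yc
    nw = np.linalg.norm(w)
    if nw < 1e-30:
        raise ValueError("y has no covariance with X")
    w /= nw
    t = Xd @ w
    p = Xd.T @ t / (t @ t)
    w, t, p = _sign_fix(w, t, p)
    b = float(t @ yc / (t @ t))
    return {
        "w": w, "t": t, "p": p, "b": b,
        "W_o": W_o, "T_o": T_o, "P_o": P_o, "X_filtered": Xd,
    }


class OPLSDA(BaseEstimator):
    """Orthogonal PLS discriminant analysis for a two-class +/-1 response.

    One predictive component plus ``n_orth`` orthogonal (class-
    uncorrelated) components.  With ``n_orth="auto"`` orthogonal
    components are added while the stratified ``cv_folds``-fold Q²
    improves by more than ``q2_tol``, up to ``max_orth`` — the heuristic
    family used by commercial chemometrics software.

    Fitted attributes include the predictive weight/loading/score vectors
    (``w_pred_``, ``p_pred_``, ``t_pred_``), the orthogonal component
    matrices, the diagnostics ``r2x_``, ``r2y_``, ``q2_``, the VIP vector
    (predictive component, so sum(VIP²) equals the variable count) and the
    correlation loadings ``r_loadings_`` used to colour-encode markers.
    """

    def __init__(self, n_orth="auto", max_orth: int = 5, cv_folds: int = 7,
                 q2_tol: float = 0.01, random_state: int = 0, compute_q2: bool = True):
        self.n_orth = n_orth
        self.max_orth = max_orth
        self.cv_folds = cv_folds
        self.q2_tol = q2_tol
        self.random_state = random_state
        self.compute_q2 = compute_q2

    # -- internal ----------------------------------------------------------
    def _validate_y(self, y) -> np.ndarray:
        y = np.asarray(y, dtype=float).ravel()
        classes = np.unique(y)
        if len(classes) < 2:
            raise ValueError("y contains a single class")
        if not np.all(np.isin(y, (-1.0, 1.0))):
            raise ValueError("y must be coded -1/+1")
        return y

    def fit(self, X, y):
        X = _as_2d(X)
        y = self._validate_y(y)
        self.y_coding_ = y.copy()
        self.y_mean_ = float(y.mean())
        yc = y - self.y_mean_

        if self.n_orth == "auto":
            n_orth = 0
            q2_prev = _cv_q2(X, y, n_orth, self.cv_folds, self.random_state)
            while n_orth < self.max_orth:
                q2_next = _cv_q2(X, y, n_orth + 1, self.cv_folds, self.random_state)
                if q2_next - q2_prev > self.q2_tol:
                    n_orth += 1
                    q2_prev = q2_next
                else:
                    break
        else:
            n_orth = int(self.n_orth)

        core = _opls_core(X, yc, n_orth)
        self.w_pred_ = core["w"]
        self.t_pred_ = core["t"]
        self.p_pred_ = core["p"]
        self.b_ = core["b"]
        self.W_orth_ = np.column_stack(core["W_o"]) if core["W_o"] else np.empty((X.shape[1], 0))
        self.T_orth_ = np.column_stack(core["T_o"]) if core["T_o"] else np.empty((X.shape[0], 0))
        self.P_orth_ = np.column_stack(core["P_o"]) if core["P_o"] else np.empty((X.shape[1], 0))
        self.n_orth_ = self.T_orth_.shape[1]

        resid = core["X_filtered"] - np.outer(self.t_pred_, self.p_pred_)
        ssx = float(np.sum(X**2))
        self.r2x_ = 1.0 - float(np.sum(resid**2)) / ssx if ssx > 0 else 0.0
        ssy = float(np.sum(yc**2))
        self.r2y_ = 1.0 - float(np.sum((yc - self.b_ * self.t_pred_) ** 2)) / ssy
        K = X.shape[1]
        self.vip_ = np.sqrt(K) * np.abs(self.w_pred_) / np.linalg.norm(self.w_pred_)
        self.r_loadings_ = correlation_loadings(self, X)
        if self.compute_q2:
            self.q2_ = cross_validate(
                X, y, model=OPLSDA(n_orth=self.n_orth_, random_state=self.random_state),
                folds=self.cv_folds, seed=self.random_state,
            ).q2
        else:
            self.q2_ = np.nan
        return self

    def _filter(self, X: np.ndarray) -> np.ndarray:
        Xd = X.copy()
        for a in range(self.n_orth_):
            t_o = Xd @ self.W_orth_[:, a]
            Xd = Xd - np.outer(t_o, self.P_orth_[:, a])
        return Xd

    def transform(self, X):
        """Predictive score followed by the orthogonal scores."""
        X = _as_2d(X)
        Xd = X.copy()
        T_o = []
        for a in range(self.n_orth_):
            t_o = Xd @ self.W_orth_[:, a]
            T_o.append(t_o)
            Xd = Xd - np.outer(t_o, self.P_orth_[:, a])
        t = Xd @ self.w_pred_
        return np.column_stack([t] + T_o)

    def predict(self, X):
        X = _as_2d(X)
        t = self._filter(X) @ self.w_pred_
        return self.y_mean_ + self.b_ * t


def fit_opls(X, y, max_orth: int = 5, **kwargs) -> OPLSDA:
    return OPLSDA(max_orth=max_orth, **kwargs).fit(X, y)


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

@dataclass
class ValidationReport:
    fold_assignment: np.ndarray
    q2: float
    r2y: float
    seed: int
    permutation_q2: np.ndarray | None = None
    permutation_r2y: np.ndarray | None = None
    p_perm: float | None = None


def stratified_folds(y, n_folds: int, seed: int = 0) -> np.ndarray:
    """Class-stratified fold labels: per class, a seeded shuffle then a
    round-robin assignment with a counter running across classes (so an
    8 + 8 design over 7 folds gives sizes {3, 3, 2, 2, 2, 2, 2})."""
    if n_folds < 2:
        raise ValueError("need at least 2 folds")
    y = np.asarray(y)
    if len(y) < n_folds:
        raise ValueError("more folds than samples")
    rng = np.random.default_rng(seed)
    fold = np.empty(len(y), dtype=int)
    counter = 0
    for cls in sorted(np.unique(y).tolist()):
        idx = np.where(y == cls)[0]
        idx = idx[rng.permutation(len(idx))]
        for i in idx:
            fold[i] = counter % n_folds
            counter += 1
    return fold


def cross_validate(X, y, model=None, folds: int = 7, seed: int = 0) -> ValidationReport:
    """Stratified k-fold cross-validated Q² (plus full-fit R²Y).

    Q² = 1 - PRESS/TSS accumulated over folds, with each test residual sum
    of squares referenced to the training-fold mean of y.
    """
    X = _as_2d(X)
    y = np.asarray(y, dtype=float).ravel()
    if model is None:
        model = OPLSDA(n_orth=0)
    fold = stratified_folds(y, folds, seed)

    def _quiet_clone(m):
        c = clone(m)
        if "compute_q2" in c.get_params():
            c.set_params(compute_q2=False)
        return c

    press = tss = 0.0
    for f in range(folds):
        test = fold == f
        train = ~test
        if not np.any(test):
            continue
        m = _quiet_clone(model).fit(X[train], y[train])
        y_hat = m.predict(X[test])
        press += float(np.sum((y[test] - y_hat) ** 2))
        tss += float(np.sum((y[test] - y[train].mean()) ** 2))
    q2 = 1.0 - press / tss
    full = _quiet_clone(model).fit(X, y)
    r2y = float(full.r2y_) if hasattr(full, "r2y_") else np.nan
    return ValidationReport(fold_assignment=fold, q2=q2, r2y=r2y, seed=seed)


def _cv_q2(X, y, n_orth: int, folds: int, seed: int) -> float:
    return cross_validate(
        X, y, model=OPLSDA(n_orth=n_orth, random_state=seed), folds=folds, seed=seed
    ).q2


def draw_label_permutation(rng: np.random.Generator, y: np.ndarray) -> np.ndarray:
    """Random permutation of the label vector, excluding draws that
    reproduce the observed labelling (so the observed model is never
    re-counted among the permutations)."""
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("cannot permute a single-class label vector")
    while True:
        y_p = y[rng.permutation(len(y))]
        if not np.array_equal(y_p, y):
            return y_p


def permutation_test(X, y, n_perm: int = 200, seed: int = 0, model=None,
                     folds: int = 7) -> ValidationReport:
    """Label-permutation test of the cross-validated Q².

    y is permuted ``n_perm`` times (permutations reproducing the observed
    label vector are redrawn, so the observed Q² is never counted twice)
    and the model + Q² recomputed; p = (1 + #{Q²_perm >= Q²_obs}) /
    (n_perm + 1).
    """
    if n_perm < 20:
        warnings.warn("fewer than 20 permutations gives a very coarse p-value",
                      stacklevel=2)
    X = _as_2d(X)
    y = np.asarray(y, dtype=float).ravel()
    if model is None:
        model = OPLSDA(n_orth=0)
    obs = cross_validate(X, y, model=model, folds=folds, seed=seed)
    rng = np.random.default_rng(seed)
    q2s = np.empty(n_perm)
    r2s = np.empty(n_perm)
    for i in range(n_perm):
        y_p = draw_label_permutation(rng, y)
        rep = cross_validate(X, y_p, model=model, folds=folds, seed=seed)
        q2s[i] = rep.q2
        r2s[i] = rep.r2y
    p_perm = (1.0 + float(np.sum(q2s >= obs.q2))) / (n_perm + 1.0)
    return ValidationReport(
        fold_assignment=obs.fold_assignment, q2=obs.q2, r2y=obs.r2y, seed=seed,
        permutation_q2=q2s, permutation_r2y=r2s, p_perm=p_perm,
    )


# ---------------------------------------------------------------------------
# Derived per-variable quantities
# ---------------------------------------------------------------------------

def vip(model: OPLSDA) -> np.ndarray:
    """Variable importance in projection for the predictive component:
    VIP_j = sqrt(K) |w_j| / ||w||, so sum(VIP²) = K."""
    w = model.w_pred_
    return np.sqrt(len(w)) * np.abs(w) / np.linalg.norm(w)


def correlation_loadings(model, X) -> np.ndarray:
    """Pearson correlation of each (scaled) variable with the predictive
    score vector; zero-variance columns get r = 0 by convention."""
    X = _as_2d(X)
    t = model.t_pred_ - model.t_pred_.mean()
    Xc = X - X.mean(axis=0)
    col_norm = np.linalg.norm(Xc, axis=0)
    t_norm = np.linalg.norm(t)
    r = np.zeros(X.shape[1])
    ok = (col_norm > 0) & (t_norm > 0)
    r[ok] = (Xc[:, ok].T @ t) / (col_norm[ok] * t_norm)
    return np.clip(r, -1.0, 1.0)


def loading_plot_data(model: OPLSDA, bucket_edges, scaler: SpectralScaler | None = None):
    """Covariance-form loading plot table: ppm, back-scaled predictive
    loading, |r| colour value (one row per bucket)."""
    import pandas as pd

    p = model.p_pred_
    if scaler is not None:
        p = p * scaler.scale_
    edges = np.asarray(bucket_edges, dtype=float)
    if len(edges) != len(p):
        raise ValueError("bucket edges do not match the number of model variables")
    return pd.DataFrame(
        {"ppm": edges, "loading": p, "abs_r": np.abs(model.r_loadings_)}
    )
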