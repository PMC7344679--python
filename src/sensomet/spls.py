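"""Sparse partial least squares regression (sPLS), its discriminant
variant (sPLS-DA), VIP coefficients, and repeated cross-validated grid
search over (components, keepX).

Model
-----
Predictors X (samples x features) and responses Y are column-centered and
unit-variance scaled. For each latent component the dominant singular
pair (u, v) of the current cross-covariance matrix ``X_d' Y_d`` is found
by alternating power iterations; at every step the X-weight u is
soft-thresholded so that exactly ``keepX`` entries stay nonzero, then
renormalized (variable selection by an L1 penalty with a per-component
cardinality budget). Scores are t = X_d u; both X_d and Y_d are deflated
by regression on t (regression mode), so a new component models what the
previous ones left unexplained. With ``keepX = p`` no entry is
thresholded away and the procedure is ordinary NIPALS PLS regression.

Variable importance in projection (VIP) for feature j over A components:

    VIP_j = sqrt( p * sum_a SSY_a * w_aj^2 / sum_a SSY_a )

with unit-norm weights w_a and SSY_a = |q_a|^2 t_a't_a the Y sum of
squares explained by component a. The weights' unit norm makes
mean(VIP^2) = 1 exactly, so VIP > 1 marks above-average importance.

Hyperparameters are chosen by repeated k-fold cross-validation over a
(components, keepX) grid: held-out misclassification rate (sPLS-DA,
minimized) or held-out Q^2 (sPLS, maximized).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold, StratifiedKFold

logger = logging.getLogger(__name__)

DEFAULT_KEEPX_GRID = (50, 100, 200, 300, 500, 1000)
DEFAULT_COMP_GRID_SPLS = tuple(range(1, 13))
DEFAULT_COMP_GRID_SPLSDA = (1, 2, 3)


class SPLSError(ValueError):
    pass


# ---------------------------------------------------------------------------

def soft_threshold_keep(u: np.ndarray, keep: int) -> np.ndarray:
    """Soft-threshold ``u`` so exactly ``keep`` entries are nonzero.

    The threshold is the (keep+1)-th largest absolute value; surviving
    entries are shrunk toward zero by it. Ties at the boundary are broken
    by feature order (lowest index kept), falling back to hard selection
    when shrinkage would annihilate a tied survivor.
    """
    p = u.shape[0]
    if keep >= p:
        return u.copy()
    if keep < 1:
        raise SPLSError("keepX must be >= 1")
    order = np.argsort(-np.abs(u), kind="stable")  # ties -> lowest index first
    thr = np.abs(u[order[keep]])
    out = np.zeros_like(u)
    top = order[:keep]
    shrunk = np.abs(u[top]) - thr
    if np.any(shrunk <= 0):  # boundary tie: keep magnitudes, no shrinkage
        out[top] = u[top]
    else:
        out[top] = np.sign(u[top]) * shrunk
    return out


def _center_scale(M: np.ndarray, what: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mean = M.mean(axis=0)
    std = M.std(axis=0, ddof=1)
    if np.any(~(std > 0)):
        bad = np.flatnonzero(~(std > 0)).tolist()
        raise SPLSError(f"zero-variance column(s) in {what}: {bad}")
    return (M - mean) / std, mean, std


def _impute_median(X: np.ndarray) -> np.ndarray:
    """Replace residual missing values with the per-feature median."""
    if not np.isnan(X).any():
        return X
    logger.info("imputing %d residual missing values with per-feature medians",
                int(np.isnan(X).sum()))
    med = np.nanmedian(X, axis=0)
    out = X.copy()
    idx = np.where(np.isnan(out))
    out[idx] = med[idx[1]]
    return out


@dataclass
class SPLSModel:
    """A fitted sparse PLS model (regression mode)."""

    x_weights: np.ndarray      # p x A, unit-norm sparse columns
    x_scores: np.ndarray       # n x A
    x_loadings: np.ndarray     # p x A
    y_loadings: np.ndarray     # q x A
    keepX: int
    n_components: int
    selected_features: list[list[int]] = field(default_factory=list)
    vip: np.ndarray | None = None
    x_mean: np.ndarray | None = None
    x_std: np.ndarray | None = None
    y_mean: np.ndarray | None = None
    y_std: np.ndarray | None = None
    classes_: np.ndarray | None = None  # set for sPLS-DA
    feature_ids: list[str] | None = None
    mode: str = "regression"

    @property
    def coef_(self) -> np.ndarray:
        """Regression coefficients in the scaled space, p x q."""
        W, P, Q = self.x_weights, self.x_loadings, self.y_loadings
        return W @ np.linalg.solve(P.T @ W, Q.T)

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Predict responses on the original Y scale."""
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[np.newaxis, :]
        Xs = (X - self.x_mean) / self.x_std
        return Xs @ self.coef_ * self.y_std + self.y_mean

    def predict_classes(self, X: np.ndarray) -> np.ndarray:
        """sPLS-DA class prediction: largest predicted indicator value."""
        if self.classes_ is None:
            raise SPLSError("not a discriminant model")
        scores = self.predict(X)
        return self.classes_[np.argmax(scores, axis=1)]


def fit_spls(
    X: np.ndarray,
    Y: np.ndarray,
    n_components: int,
    keepX: int,
    tol: float = 1e-12,
    max_iter: int = 500,
    feature_ids: list[str] | None = None,
) -> SPLSModel:
    """Fit a sparse PLS regression of Y on X.

    X may contain residual missing values; they are imputed with the
    per-feature median before fitting (and this is logged). Y must be
    finite.
    """
    X = _impute_median(np.asarray(X, dtype=float))
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, np.newaxis]
    n, p = X.shape
    if Y.shape[0] != n:
        raise SPLSError(f"X has {n} samples but Y has {Y.shape[0]}")
    if n < 2:
        raise SPLSError("need at least 2 samples")
    if not np.all(np.isfinite(Y)):
        raise SPLSError("Y contains non-finite values")
    if keepX > p:
        raise SPLSError(f"keepX={keepX} exceeds n_features={p}")
    if n_components > min(n - 1, p):
        raise SPLSError(
            f"n_components={n_components} exceeds the data rank bound "
            f"min(n_samples-1, n_features)={min(n - 1, p)}"
        )

    Xs, xm, xs = _center_scale(X, "X")
    Ys, ym, ys = _center_scale(Y, "Y")
    Xd, Yd = Xs.copy(), Ys.copy()
    q = Ys.shape[1]

    W = np.zeros((p, n_components))
    T = np.zeros((n, n_components))
    P = np.zeros((p, n_components))
    Q = np.zeros((q, n_components))
    selected: list[list[int]] = []

    for a in range(n_components):
        M = Xd.T @ Yd  # p x q cross-covariance
        # initialize v from the dominant right singular vector of M
        if q == 1:
            v = np.ones(1)
        else:
            _, _, vt = np.linalg.svd(M, full_matrices=False)
            v = vt[0]
        u = None
        for _ in range(max_iter):
            u = M @ v
            nu = np.linalg.norm(u)
            if nu == 0:
                raise SPLSError(f"rank exhausted at component {a + 1}")
            u = soft_threshold_keep(u, keepX)
            u /= np.linalg.norm(u)
            if q == 1:
                break
            v_new = M.T @ u
            v_new /= np.linalg.norm(v_new)
            if np.linalg.norm(v_new - v) < tol:
                v = v_new
                break
            v = v_new
        t = Xd @ u
        tt = float(t @ t)
        if tt == 0:
            raise SPLSError(f"zero-variance score at component {a + 1}")
        pvec = Xd.T @ t / tt
        qvec = Yd.T @ t / tt
        Xd = Xd - np.outer(t, pvec)
        Yd = Yd - np.outer(t, qvec)
        W[:, a], T[:, a], P[:, a], Q[:, a] = u, t, pvec, qvec
        selected.append(np.flatnonzero(u).tolist())

    model = SPLSModel(
        x_weights=W, x_scores=T, x_loadings=P, y_loadings=Q,
        keepX=keepX, n_components=n_components, selected_features=selected,
        x_mean=xm, x_std=xs, y_mean=ym, y_std=ys, feature_ids=feature_ids,
    )
    model.vip = compute_vip(model)
    return model


def fit_splsda(
    X: np.ndarray,
    classes,
    n_components: int,
    keepX: int,
    **kwargs,
) -> SPLSModel:
    """Sparse PLS-DA: one-hot encode the class labels and fit
    :func:`fit_spls`; prediction takes the class with the largest
    predicted indicator value."""
    y = np.asarray(classes)
    labels, counts = np.unique(y, return_counts=True)
    if len(labels) < 2:
        raise SPLSError("need at least 2 classes")
    if np.any(counts < 2):
        bad = labels[counts < 2].tolist()
        raise SPLSError(f"class(es) with fewer than 2 samples: {bad}")
    indicator = (y[:, np.newaxis] == labels[np.newaxis, :]).astype(float)
    model = fit_spls(X, indicator, n_components, keepX, **kwargs)
    model.classes_ = labels
    return model


def compute_vip(model: SPLSModel) -> np.ndarray:
    """VIP coefficient per feature (see module docstring); also stored on
    the model."""
    W, T, Q = model.x_weights, model.x_scores, model.y_loadings
    if W.size == 0:
        raise SPLSError("model not fitted")
    p = W.shape[0]
    wnorm = np.linalg.norm(W, axis=0)
    Wn = W / wnorm
    ssy = np.einsum("ia,ia->a", T, T) * np.einsum("ja,ja->a", Q, Q)
    vip = np.sqrt(p * (Wn**2 @ ssy) / ssy.sum())
    model.vip = vip
    return vip


# -- cross-validated grid search --------------------------------------------

@dataclass
class CVResult:
    """Grid of mean CV criterion values and the selected (components,
    keepX) pair."""

    grid: pd.DataFrame  # columns n_components, keepX, criterion
    criterion_kind: str  # "classification_error" | "q2"
    best_pair: tuple[int, int]
    n_repeats: int
    k_folds: int
    seed: int

    def criterion_at(self, n_components: int, keepX: int) -> float:
        g = self.grid
        row = g[(g["n_components"] == n_components) & (g["keepX"] == keepX)]
        return float(row["criterion"].iloc[0])


def _q2(y_true: np.ndarray, y_pred: np.ndarray, y_train_mean: np.ndarray) -> tuple[float, float]:
    press = float(np.sum((y_true - y_pred) ** 2))
    tss = float(np.sum((y_true - y_train_mean) ** 2))
    return press, tss


def grid_search(
    X: np.ndarray,
    Y_or_classes,
    kind: str,
    comp_grid=None,
    keepX_grid=None,
    n_repeats: int = 100,
    k: int = 5,
    seed: int = 0,
) -> CVResult:
    """Repeated k-fold cross-validation over the (components, keepX) grid.

    ``kind`` is ``"spls"`` (quantitative Y; criterion = held-out Q^2,
    maximized) or ``"splsda"`` (class labels; criterion = held-out
    misclassification rate, minimized; folds stratified by class).
    keepX values exceeding the number of features are clamped with a
    warning. Deterministic for a fixed seed. Ties on the criterion go to
    the smaller component count, then the smaller keepX.
    """
    if kind not in ("spls", "splsda"):
        raise SPLSError(f"unknown kind {kind!r}")
    X = _impute_median(np.asarray(X, dtype=float))
    n, p = X.shape
    if comp_grid is None:
        comp_grid = DEFAULT_COMP_GRID_SPLSDA if kind == "splsda" else DEFAULT_COMP_GRID_SPLS
    if keepX_grid is None:
        keepX_grid = DEFAULT_KEEPX_GRID
    comp_grid = sorted(set(int(c) for c in comp_grid))
    clamped = sorted(set(min(int(kx), p) for kx in keepX_grid))
    if clamped != sorted(set(int(kx) for kx in keepX_grid)):
        warnings.warn(
            f"keepX values above n_features={p} clamped", UserWarning, stacklevel=2
        )
    keepX_grid = clamped
    if not comp_grid or not keepX_grid:
        raise SPLSError("empty hyperparameter grid")

    if kind == "splsda":
        y = np.asarray(Y_or_classes)
        _, counts = np.unique(y, return_counts=True)
        if k > counts.min():
            raise SPLSError(
                f"k={k} folds exceed the smallest class size {counts.min()}"
            )
    else:
        y = np.asarray(Y_or_classes, dtype=float)
        if y.ndim == 1:
            y = y[:, np.newaxis]

    rng = np.random.default_rng(seed)
    fold_states = rng.integers(0, 2**31 - 1, size=n_repeats)

    acc = {(c, kx): [] for c in comp_grid for kx in keepX_grid}
    for state in fold_states:
        if kind == "splsda":
            splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=int(state))
            split_iter = splitter.split(X, y)
        else:
            splitter = KFold(n_splits=k, shuffle=True, random_state=int(state))
            split_iter = splitter.split(X)
        folds = list(split_iter)
        for c in comp_grid:
            for kx in keepX_grid:
                errs = 0
                total = 0
                press = 0.0
                tss = 0.0
                ok = True
                for train, test in folds:
                    try:
                        if kind == "splsda":
                            m = fit_splsda(X[train], y[train], c, kx)
                            pred = m.predict_classes(X[test])
                            errs += int(np.sum(pred != y[test]))
                            total += len(test)
                        else:
                            m = fit_spls(X[train], y[train], c, kx)
                            pr, ts = _q2(y[test], m.predict(X[test]), y[train].mean(axis=0))
                            press += pr
                            tss += ts
                    except SPLSError:
                        ok = False
                        break
                if not ok:
                    acc[(c, kx)].append(np.nan)
                elif kind == "splsda":
                    acc[(c, kx)].append(errs / total)
                else:
                    acc[(c, kx)].append(1.0 - press / tss)

    rows = [
        (c, kx, float(np.nanmean(acc[(c, kx)])) if not np.all(np.isnan(acc[(c, kx)])) else np.nan)
        for c in comp_grid for kx in keepX_grid
    ]
    grid = pd.DataFrame(rows, columns=["n_components", "keepX", "criterion"])
    valid = grid.dropna(subset=["criterion"])
    if valid.empty:
        raise SPLSError("every grid point failed during cross-validation")
    best = valid.sort_values(
        by=["criterion", "n_components", "keepX"],
        ascending=[kind == "splsda", True, True],  # min error / max q2
        kind="stable",
    ).iloc[0]
    return CVResult(
        grid=grid,
        criterion_kind="classification_error" if kind == "splsda" else "q2",
        best_pair=(int(best["n_components"]), int(best["keepX"])),
        n_repeats=n_repeats,
        k_folds=k,
        seed=seed,
    )


def model_summary(model: SPLSModel, cv: CVResult | None = None) -> dict:
    """JSON-serializable summary of a fitted model (weights, selection,
    VIP, CV grid)."""
    out = {
        "n_components": model.n_components,
        "keepX": model.keepX,
        "selected_features": [
            [model.feature_ids[i] for i in comp] if model.feature_ids else comp
            for comp in model.selected_features
        ],
        "vip": model.vip.tolist() if model.vip is not None else None,
        "feature_ids": model.feature_ids,
        "classes": model.classes_.tolist() if model.classes_ is not None else None,
    }
    if cv is not None:
        out["cv"] = {
            "criterion_kind": cv.criterion_kind,
            "best_pair": list(cv.best_pair),
            "n_repeats": cv.n_repeats,
            "k_folds": cv.k_folds,
            "seed": cv.seed,
            "grid": cv.grid.to_dict(orient="records"),
        }
    return out
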