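"""Principal component analysis by NIPALS, tolerant of missing values.

Features (variables) are mean-centered and scaled to unit variance using
observed entries only. Components are extracted one at a time by the
NIPALS alternating regressions, in which each regression simply skips
missing cells — no imputation is performed. With complete data this is
exactly the PCA given by a singular value decomposition of the scaled
matrix (up to component sign), which the test suite checks against.

Determinism: each component's score vector is initialized from the column
of largest observed variance of the current residual matrix, and the sign
convention makes the largest-magnitude loading of every component
positive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .tables import FeatureTable


class PCAError(ValueError):
    pass


@dataclass
class PCAResult:
    """Scores (samples x components), unit-norm loadings (features x
    components) and the fraction of total scaled variance explained per
    component."""

    scores: np.ndarray
    loadings: np.ndarray
    r2_per_component: np.ndarray
    n_components: int
    sample_ids: list[str]
    feature_ids: list[str]
    scaling: str = "unit_variance"
    centering: bool = True
    mean_: np.ndarray | None = None
    std_: np.ndarray | None = None


def _standardize(X: np.ndarray, feature_ids) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mean = np.nanmean(X, axis=0)
    std = np.nanstd(X, axis=0, ddof=1)
    zero_var = ~(std > 0)
    if np.any(zero_var):
        bad = [feature_ids[i] for i in np.flatnonzero(zero_var)]
        raise PCAError(f"zero-variance feature(s), cannot unit-scale: {bad}")
    return (X - mean) / std, mean, std


def fit_pca(
    table: FeatureTable | np.ndarray,
    n_components: int = 5,
    tol: float = 1e-12,
    max_iter: int = 5000,
) -> PCAResult:
    """Fit a unit-variance-scaled PCA with ``n_components`` components.

    Accepts a processed :class:`FeatureTable` (features x samples; samples
    become observations) or a plain samples x features array with NaN for
    missing entries.
    """
    if isinstance(table, FeatureTable):
        X = table.intensities.to_numpy(dtype=float).T
        sample_ids = [str(s) for s in table.sample_ids]
        feature_ids = [str(f) for f in table.feature_ids]
    else:
        X = np.asarray(table, dtype=float)
        sample_ids = [str(i) for i in range(X.shape[0])]
        feature_ids = [str(j) for j in range(X.shape[1])]

    n, p = X.shape
    if n_components < 1:
        raise PCAError("n_components must be >= 1")
    if n_components > min(n - 1, p):
        raise PCAError(
            f"n_components={n_components} exceeds min(n_samples-1, n_features)="
            f"{min(n - 1, p)}"
        )
    obs = ~np.isnan(X)
    if np.any(obs.sum(axis=0) < 2):
        bad = [feature_ids[j] for j in np.flatnonzero(obs.sum(axis=0) < 2)]
        raise PCAError(f"feature(s) with fewer than 2 observed values: {bad}")

    Xs, mean, std = _standardize(X, feature_ids)
    R = np.where(obs, Xs, 0.0)  # residual matrix, missing cells held at 0
    total_ss = float(np.sum(R**2))

    scores = np.zeros((n, n_components))
    loadings = np.zeros((p, n_components))
    r2 = np.zeros(n_components)
    prev_ss = total_ss

    for a in range(n_components):
        # init from the column with the largest observed variance
        with np.errstate(invalid="ignore"):
            col_var = np.array([
                np.var(R[obs[:, j], j], ddof=0) if obs[:, j].sum() > 1 else 0.0
                for j in range(p)
            ])
        t = R[:, int(np.argmax(col_var))].copy()
        if not np.any(t):
            raise PCAError(f"residual matrix vanished before component {a + 1}")
        for _ in range(max_iter):
            # loadings: per-feature regression of residuals on t over observed cells
            tw = np.where(obs, t[:, None], 0.0)
            denom = np.sum(tw**2, axis=0)
            if np.any(denom == 0):
                raise PCAError("degenerate regression in NIPALS (empty feature support)")
            pvec = R.T @ t / denom
            pvec /= np.linalg.norm(pvec)
            # scores: per-sample regression on the loading over observed cells
            pw = np.where(obs, pvec[None, :], 0.0)
            denom_s = np.sum(pw**2, axis=1)
            if np.any(denom_s == 0):
                raise PCAError("sample with no observed values in NIPALS")
            t_new = R @ pvec / denom_s
            delta = np.linalg.norm(t_new - t) / max(np.linalg.norm(t_new), 1e-300)
            t = t_new
            if delta < tol:
                break
        # sign convention: largest-magnitude loading positive
        j = int(np.argmax(np.abs(pvec)))
        if pvec[j] < 0:
            pvec, t = -pvec, -t
        scores[:, a] = t
        loadings[:, a] = pvec
        R = R - np.where(obs, np.outer(t, pvec), 0.0)
        ss = float(np.sum(R**2))
        r2[a] = (prev_ss - ss) / total_ss
        prev_ss = ss

    return PCAResult(
        scores=scores,
        loadings=loadings,
        r2_per_component=r2,
        n_components=n_components,
        sample_ids=sample_ids,
        feature_ids=feature_ids,
        mean_=mean,
        std_=std,
    )
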