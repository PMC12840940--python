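"""Z-score standardization, OLS-learned fusion weights, and PLSR modelling.

The fusion scheme is mid-level: each feature block (spectral, visual) is
standardized with training-set statistics, an ordinary-least-squares fit of
the response on the standardized features learns per-feature weights (their
absolute values — a sign flip on a standardized feature is absorbed by the
downstream PLSR), the re-weighted blocks are concatenated spectral-first,
and a partial least squares regression with a cross-validated number of
latent variables maps the fused matrix to soluble solid content.

Everything stateful is fitted on the training partition only and replayed
on test data; the no-leakage contract is load-bearing and tested.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin, TransformerMixin
from sklearn.cross_decomposition import PLSRegression
from sklearn.model_selection import KFold

__all__ = [
    "train_test_split_ids",
    "ColumnStandardizer",
    "zscore_fit",
    "zscore_apply",
    "FusionSpec",
    "learn_fusion_weights",
    "fuse",
    "plsr_fit",
    "plsr_predict",
    "select_n_latent",
    "CVPLSRegression",
    "FusedPLSRegressor",
    "EvalReport",
    "evaluate",
]


def train_test_split_ids(sample_ids, ratio: float = 0.7, seed: int = 0):
    """Seeded 7:3-style shuffle split; train size = round(ratio * n)."""
    ids = list(sample_ids)
    if not 0 < ratio < 1:
        raise ValueError("ratio must be in (0, 1)")
    if len(ids) < 2:
        raise ValueError("need at least 2 samples to split")
    n_train = round(ratio * len(ids))
    if n_train == 0 or n_train == len(ids):
        raise ValueError("split produces an empty partition")
    perm = np.random.default_rng(seed).permutation(len(ids))
    train = [ids[i] for i in sorted(perm[:n_train])]
    test = [ids[i] for i in sorted(perm[n_train:])]
    return train, test


class ColumnStandardizer(TransformerMixin, BaseEstimator):
    """Per-feature z-score with training statistics (sample SD, ddof=1)."""

    def fit(self, X, y=None):
        X = np.asarray(X, float)
        if X.ndim != 2 or X.shape[0] < 2:
            raise ValueError("fit requires a matrix with at least 2 rows")
        self.mean_ = X.mean(axis=0)
        self.sd_ = X.std(axis=0, ddof=1)
        zero = np.nonzero(self.sd_ == 0)[0]
        if zero.size:
            raise ValueError(f"degenerate feature: column {zero[0]} has zero variance")
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        X = np.asarray(X, float)
        if X.ndim != 2 or X.shape[1] != self.n_features_in_:
            raise ValueError("feature width does not match the fitted standardizer")
        return (X - self.mean_) / self.sd_


def zscore_fit(X_train) -> ColumnStandardizer:
    return ColumnStandardizer().fit(X_train)


def zscore_apply(standardizer: ColumnStandardizer, X) -> np.ndarray:
    return standardizer.transform(X)


# ------------------------------------------------------------------------- PLSR


def plsr_fit(X, y, n_latent: int) -> PLSRegression:
    """Deflation-based single-response PLSR on centered (unscaled) X."""
    X = np.asarray(X, float)
    y = np.asarray(y, float).ravel()
    if y.std() == 0:
        raise ValueError("response has zero variance")
    cap = min(X.shape[0] - 1, X.shape[1])
    if not 1 <= n_latent <= cap:
        raise ValueError(f"n_latent must be in [1, {cap}]")
    return PLSRegression(n_components=n_latent, scale=False).fit(X, y)


def plsr_predict(model: PLSRegression, X) -> np.ndarray:
    return model.predict(np.asarray(X, float)).ravel()


def select_n_latent(
    X, y, max_latent: int = 25, k_folds: int = 5, seed: int = 42
) -> tuple[int, np.ndarray]:
    """Cross-validated latent-variable count: argmin of mean held-out RMSE.

    Seeded shuffled k-fold; candidates 1..min(max_latent, feasibility);
    ties resolve to the smallest count.  Returns (count, RMSECV trace).
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float).ravel()
    if max_latent < 1 or k_folds < 2:
        raise ValueError("max_latent must be >= 1 and k_folds >= 2")
    n = X.shape[0]
    if n < k_folds:
        raise ValueError("fewer samples than folds")
    cv = KFold(k_folds, shuffle=True, random_state=seed % 2**31)
    folds = list(cv.split(X))
    cap = min(max_latent, X.shape[1], min(tr.size for tr, _ in folds) - 1)
    trace = np.empty(cap)
    for k in range(1, cap + 1):
        errs = []
        for tr, te in folds:
            model = PLSRegression(n_components=k, scale=False).fit(X[tr], y[tr])
            errs.append(np.sqrt(np.mean((y[te] - model.predict(X[te]).ravel()) ** 2)))
        trace[k - 1] = np.mean(errs)
    return int(np.argmin(trace)) + 1, trace


class CVPLSRegression(RegressorMixin, BaseEstimator):
    """PLSR with the latent-variable count chosen by seeded k-fold CV.

    Defaults mirror the modelling protocol: 5 folds, CV seed 42, at most 25
    latent variables.  Set ``n_latent`` to skip selection.
    """

    def __init__(self, max_latent: int = 25, cv_folds: int = 5, cv_seed: int = 42,
                 n_latent: int | None = None):
        self.max_latent = max_latent
        self.cv_folds = cv_folds
        self.cv_seed = cv_seed
        self.n_latent = n_latent

    def fit(self, X, y):
        X = np.asarray(X, float)
        y = np.asarray(y, float).ravel()
        if self.n_latent is not None:
            self.n_components_ = self.n_latent
            self.rmsecv_trace_ = np.array([])
        else:
            self.n_components_, self.rmsecv_trace_ = select_n_latent(
                X, y, self.max_latent, self.cv_folds, self.cv_seed
            )
        self.pls_ = plsr_fit(X, y, self.n_components_)
        self.coef_ = self.pls_.coef_.ravel()
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        return plsr_predict(self.pls_, X)


# ------------------------------------------------------------------------ fusion


@dataclass
class FusionSpec:
    """Learned linear fusion weights for the spectral and visual blocks."""

    spectral_weights: np.ndarray
    visual_weights: np.ndarray
    mode: str = "per_feature"

    def __post_init__(self):
        self.spectral_weights = np.asarray(self.spectral_weights, float)
        self.visual_weights = np.asarray(self.visual_weights, float)
        if self.mode not in ("per_feature", "per_block"):
            raise ValueError("mode must be 'per_feature' or 'per_block'")
        if not (np.any(self.spectral_weights != 0) or np.any(self.visual_weights != 0)):
            raise ValueError("at least one fusion weight must be nonzero")


def _ols(A: np.ndarray, y: np.ndarray) -> np.ndarray:
    coef, _, rank, _ = np.linalg.lstsq(A, y, rcond=None)
    if rank < A.shape[1]:
        warnings.warn("rank-deficient fusion design; using minimum-norm least squares")
    return coef


def _oof_pls_predictions(Z: np.ndarray, y: np.ndarray, n_latent: int, folds) -> np.ndarray:
    """Out-of-fold PLS predictions (stacking-style, no in-sample optimism)."""
    out = np.empty_like(y)
    for tr, te in folds:
        k = max(1, min(n_latent, tr.size - 1, Z.shape[1]))
        model = PLSRegression(n_components=k, scale=False).fit(Z[tr], y[tr])
        out[te] = model.predict(Z[te]).ravel()
    return out


def learn_fusion_weights(Z_spec, Z_vis, y_train, mode: str = "per_block",
                         cv_folds: int = 5, cv_seed: int = 42) -> FusionSpec:
    """OLS-learned fusion weights on standardized blocks.

    per_block (default): OLS of y on the two within-block PLSR prediction
    vectors; the two absolute scalars are broadcast across their blocks.
    The block predictions are out-of-fold (seeded k-fold), so the weights
    reflect each block's generalizing — not in-sample — accuracy; weights
    learned from in-sample predictions collapse onto whichever block has
    more capacity to overfit.

    per_feature: absolute per-feature coefficients of a single OLS of y on
    [Z_spec | Z_vis].  With strongly collinear spectral features the OLS
    coefficients are high-variance, which makes this mode fragile; it is
    kept for completeness.
    """
    Z_spec = np.atleast_2d(np.asarray(Z_spec, float))
    Z_vis = np.atleast_2d(np.asarray(Z_vis, float))
    y = np.asarray(y_train, float).ravel()
    if mode == "per_feature":
        A = np.column_stack([np.ones(y.size), Z_spec, Z_vis])
        coef = _ols(A, y)[1:]
        w = np.abs(coef)
        return FusionSpec(w[: Z_spec.shape[1]], w[Z_spec.shape[1] :], mode)
    if mode == "per_block":
        folds = list(
            KFold(cv_folds, shuffle=True, random_state=cv_seed % 2**31).split(Z_spec)
        )
        preds = []
        for Z in (Z_spec, Z_vis):
            k, _ = select_n_latent(Z, y, min(10, Z.shape[1]), cv_folds, cv_seed)
            preds.append(_oof_pls_predictions(Z, y, k, folds))
        A = np.column_stack([np.ones(y.size), preds[0], preds[1]])
        c = np.abs(_ols(A, y)[1:])
        return FusionSpec(np.full(Z_spec.shape[1], c[0]), np.full(Z_vis.shape[1], c[1]), mode)
    raise ValueError("mode must be 'per_feature' or 'per_block'")


def fuse(Z_spec, Z_vis, spec: FusionSpec) -> np.ndarray:
    """Column-wise re-weighted blocks concatenated spectral-first."""
    Z_spec = np.atleast_2d(np.asarray(Z_spec, float))
    Z_vis = np.atleast_2d(np.asarray(Z_vis, float))
    if Z_spec.shape[1] != spec.spectral_weights.size or Z_vis.shape[1] != spec.visual_weights.size:
        raise ValueError("block widths do not match the fusion spec")
    return np.hstack([Z_spec * spec.spectral_weights, Z_vis * spec.visual_weights])


class FusedPLSRegressor(RegressorMixin, BaseEstimator):
    """The full fusion model: block z-scoring, OLS weighting, fused PLSR.

    ``X`` is the horizontal concatenation [spectral features | visual
    features]; ``n_spectral`` marks the block boundary.  All statistics are
    learned in ``fit`` and replayed in ``predict``.
    """

    def __init__(self, n_spectral: int, fusion_mode: str = "per_block",
                 max_latent: int = 25, cv_folds: int = 5, cv_seed: int = 42):
        self.n_spectral = n_spectral
        self.fusion_mode = fusion_mode
        self.max_latent = max_latent
        self.cv_folds = cv_folds
        self.cv_seed = cv_seed

    def _blocks(self, X):
        X = np.asarray(X, float)
        if X.shape[1] <= self.n_spectral:
            raise ValueError("X must contain both a spectral and a visual block")
        return X[:, : self.n_spectral], X[:, self.n_spectral :]

    def fit(self, X, y):
        Xs, Xv = self._blocks(X)
        y = np.asarray(y, float).ravel()
        self.spec_standardizer_ = zscore_fit(Xs)
        self.vis_standardizer_ = zscore_fit(Xv)
        Zs, Zv = self.spec_standardizer_.transform(Xs), self.vis_standardizer_.transform(Xv)
        self.fusion_spec_ = learn_fusion_weights(Zs, Zv, y, self.fusion_mode,
                                                 self.cv_folds, self.cv_seed)
        fused = fuse(Zs, Zv, self.fusion_spec_)
        self.pls_ = CVPLSRegression(self.max_latent, self.cv_folds, self.cv_seed).fit(fused, y)
        self.n_components_ = self.pls_.n_components_
        self.n_features_in_ = X.shape[1] if hasattr(X, "shape") else Xs.shape[1] + Xv.shape[1]
        return self

    def predict(self, X):
        Xs, Xv = self._blocks(X)
        fused = fuse(
            self.spec_standardizer_.transform(Xs),
            self.vis_standardizer_.transform(Xv),
            self.fusion_spec_,
        )
        return self.pls_.predict(fused)


# --------------------------------------------------------------------- metrics


@dataclass
class EvalReport:
    """R^2/RMSE on both partitions plus the test-set RPD."""

    r2_train: float
    rmse_train: float
    r2_test: float
    rmse_test: float
    rpd: float

    def as_dict(self) -> dict[str, float]:
        return {
            "R2c": self.r2_train,
            "RMSEC": self.rmse_train,
            "R2v": self.r2_test,
            "RMSEV": self.rmse_test,
            "RPD": self.rpd,
        }


def evaluate(y_true, y_pred) -> dict[str, float]:
    """R^2 = 1 - SSE/SST, RMSE, and RPD = sd(y_true, ddof=1) / RMSE."""
    y_true = np.asarray(y_true, float).ravel()
    y_pred = np.asarray(y_pred, float).ravel()
    if y_true.size != y_pred.size or y_true.size < 2:
        raise ValueError("need equal-length vectors with at least 2 values")
    sst = np.sum((y_true - y_true.mean()) ** 2)
    if sst == 0:
        raise ValueError("zero variance in y_true: R^2 and RPD undefined")
    sse = np.sum((y_true - y_pred) ** 2)
    rmse = float(np.sqrt(np.mean((y_true - y_pred) ** 2)))
    rpd = float(np.inf) if rmse == 0 else float(np.std(y_true, ddof=1) / rmse)
    return {"r2": float(1 - sse / sst), "rmse": rmse, "rpd": rpd}


def eval_report(y_train, pred_train, y_test, pred_test) -> EvalReport:
    tr = evaluate(y_train, pred_train)
    te = evaluate(y_test, pred_test)
    return EvalReport(tr["r2"], tr["rmse"], te["r2"], te["rmse"], te["rpd"])
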