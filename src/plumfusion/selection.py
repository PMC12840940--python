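"""Wavelength selection: CARS, SPA and UVE.

All three algorithms pick an informative subset of wavelengths for a PLSR
model of a single response.  They are implemented as scikit-learn selector
estimators (``fit`` / ``transform`` / ``get_support``) plus functional
wrappers returning a :class:`SelectionResult`.  Each is deterministic given
(X, y, config, seed).

CARS — competitive adaptive reweighted sampling: Monte-Carlo runs combining
an enforced exponentially decaying retention schedule with resampling of
variables in proportion to their absolute PLS regression coefficients;
the retained set with minimal cross-validated RMSE wins.

SPA — successive projections algorithm: forward chains that repeatedly add
the column with the largest norm in the orthogonal complement of the span
of the already-selected columns (minimizing collinearity), scored by
held-out least-squares RMSE over all (start, length) chains.

UVE — uninformative variable elimination: real variables must beat appended
artificial noise variables on a coefficient-stability score c_j =
mean(b_j)/sd(b_j) across leave-one-out PLS fits.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.cross_decomposition import PLSRegression
from sklearn.feature_selection import SelectorMixin
from sklearn.model_selection import KFold

__all__ = [
    "SelectionResult",
    "CARSConfig",
    "CARSSelector",
    "SPASelector",
    "UVESelector",
    "cars_select",
    "spa_select",
    "uve_select",
]


@dataclass
class SelectionResult:
    """Outcome of one wavelength-selection run."""

    method: str
    selected_indices: np.ndarray
    rmsecv_trace: np.ndarray = field(default_factory=lambda: np.array([]))
    retained_counts: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    threshold: float | None = None
    seed: int = 0

    def save(self, wavelengths: np.ndarray, weights: np.ndarray, csv_path, diag_path) -> None:
        """Serialize as (index, wavelength_nm, weight) CSV + key=value diagnostics."""
        idx = np.asarray(self.selected_indices, int)
        pd.DataFrame(
            {
                "index": idx,
                "wavelength_nm": np.asarray(wavelengths)[idx],
                "weight": np.asarray(weights)[: idx.size] if len(weights) else np.ones(idx.size),
            }
        ).to_csv(csv_path, index=False)
        lines = [
            f"method = {self.method}",
            f"n_selected = {idx.size}",
            f"seed = {self.seed}",
            f"threshold = {self.threshold}",
            "rmsecv_trace = " + ",".join(f"{v:.6g}" for v in self.rmsecv_trace),
            "retained_counts = " + ",".join(str(int(c)) for c in self.retained_counts),
        ]
        with open(diag_path, "w") as fh:
            fh.write("\n".join(lines) + "\n")


def _pls_coef(X: np.ndarray, y: np.ndarray, n_components: int) -> np.ndarray:
    """Single-response PLS regression coefficient vector (centered, unscaled)."""
    model = PLSRegression(n_components=n_components, scale=False)
    model.fit(X, y)
    return model.coef_.ravel()


def _rmsecv(X: np.ndarray, y: np.ndarray, n_components: int, cv: KFold) -> float:
    """k-fold cross-validated RMSE of a PLSR with a fixed component count.

    A fixed, small count keeps the run-scoring criterion from chasing
    fold-noise; the final model on the winning subset re-selects its own
    latent-variable count.
    """
    sq = 0.0
    n_total = 0
    for tr, te in cv.split(X):
        k = max(1, min(n_components, X.shape[1], tr.size - 1))
        model = PLSRegression(n_components=k, scale=False)
        model.fit(X[tr], y[tr])
        pred = model.predict(X[te]).ravel()
        sq += np.sum((y[te] - pred) ** 2)
        n_total += te.size
    return float(np.sqrt(sq / n_total))


def _validate_xy(X, y):
    X = np.asarray(X, float)
    y = np.asarray(y, float).ravel()
    if X.ndim != 2 or X.shape[0] != y.size:
        raise ValueError("X must be (n_samples, n_features) with matching y")
    return X, y


# ----------------------------------------------------------------------- CARS


@dataclass
class CARSConfig:
    """Monte-Carlo settings for CARS; defaults follow the original algorithm's
    conventions (50 runs, 80% calibration subsets, 5-fold RMSECV)."""

    n_runs: int = 50
    calibration_fraction: float = 0.8
    cv_folds: int = 5
    max_latent_variables: int = 5
    seed: int = 0

    def validate(self) -> None:
        if self.n_runs < 2:
            raise ValueError("n_runs must be >= 2")
        if not 0 < self.calibration_fraction < 1:
            raise ValueError("calibration_fraction must be in (0, 1)")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")


def edf_schedule(p: int, n_runs: int) -> np.ndarray:
    """Enforced exponential retention counts ceil(r_i * p), i = 1..N.

    The decay ratio r_i = a * exp(-k*i) is pinned by the boundary conditions
    r_1 = 1 (all variables survive the first run) and r_N = 2/p (two
    variables survive the last).
    """
    if p < 2:
        raise ValueError("need at least 2 variables")
    k = math.log(p / 2.0) / (n_runs - 1)
    a = math.exp(k)
    i = np.arange(1, n_runs + 1)
    # epsilon guard: the boundary values r_1*p = p and r_N*p = 2 must not
    # round up through floating-point error
    counts = np.ceil(a * np.exp(-k * i) * p - 1e-9).astype(int)
    return np.clip(counts, 2, p)


class CARSSelector(SelectorMixin, BaseEstimator):
    """Competitive adaptive reweighted sampling wavelength selector.

    Each Monte-Carlo run fits PLSR on a random calibration subset of the
    currently retained variables, weights variables by normalized absolute
    regression coefficients, applies the enforced exponential reduction,
    resamples variables proportionally to weight (with replacement,
    de-duplicated), and scores the retained set by k-fold RMSECV.  The run
    with minimal RMSECV wins; ties prefer fewer variables, then the earlier
    run.
    """

    def __init__(
        self,
        n_runs: int = 50,
        calibration_fraction: float = 0.8,
        cv_folds: int = 5,
        max_latent_variables: int = 5,
        seed: int = 0,
    ):
        self.n_runs = n_runs
        self.calibration_fraction = calibration_fraction
        self.cv_folds = cv_folds
        self.max_latent_variables = max_latent_variables
        self.seed = seed

    def fit(self, X, y):
        cfg = CARSConfig(
            self.n_runs, self.calibration_fraction, self.cv_folds,
            self.max_latent_variables, self.seed,
        )
        cfg.validate()
        X, y = _validate_xy(X, y)
        n, p = X.shape
        if p < 2:
            raise ValueError("CARS requires at least 2 variables")
        if n < cfg.cv_folds:
            raise ValueError("fewer samples than cv_folds")
        if np.all(X.std(axis=0) == 0):
            raise ValueError("degenerate input: all variables constant")

        rng = np.random.default_rng(self.seed)
        cv = KFold(cfg.cv_folds, shuffle=True, random_state=self.seed % 2**31)
        schedule = edf_schedule(p, cfg.n_runs)
        n_cal = max(2, round(cfg.calibration_fraction * n))

        retained = np.arange(p)
        runs: list[np.ndarray] = []
        rmse = np.empty(cfg.n_runs)
        counts = np.empty(cfg.n_runs, dtype=int)
        for i in range(cfg.n_runs):
            cal = rng.choice(n, size=n_cal, replace=False)
            k = min(cfg.max_latent_variables, retained.size, n_cal - 1)
            b = _pls_coef(X[np.ix_(cal, retained)], y[cal], max(1, k))
            absb = np.abs(b)
            w = absb / absb.sum() if absb.sum() > 0 else np.full(retained.size, 1.0 / retained.size)
            n_keep = min(schedule[i], retained.size)
            top = retained[np.argsort(-w, kind="stable")[:n_keep]]
            pos = {v: j for j, v in enumerate(retained)}
            w_top = np.array([w[pos[v]] for v in top])
            probs = w_top / w_top.sum() if w_top.sum() > 0 else np.full(top.size, 1.0 / top.size)
            # draw ceil(r_i * p) times (against the original p) so early runs
            # keep diversity; de-duplication shrinks the set further
            sampled = rng.choice(top, size=schedule[i], replace=True, p=probs)
            retained = np.unique(sampled)
            if retained.size < 1:  # pragma: no cover - unique of nonempty is nonempty
                retained = top[:1]
            k_cv = min(cfg.max_latent_variables, retained.size)
            rmse[i] = _rmsecv(X[:, retained], y, k_cv, cv)
            counts[i] = retained.size
            runs.append(retained.copy())

        order = sorted(range(cfg.n_runs), key=lambda i: (rmse[i], counts[i], i))
        best = order[0]
        self.n_features_in_ = p
        self.support_ = np.zeros(p, dtype=bool)
        self.support_[runs[best]] = True
        self.rmsecv_trace_ = rmse
        self.retained_counts_ = counts
        self.best_run_ = best
        self.schedule_ = schedule
        return self

    def _get_support_mask(self):
        return self.support_


def cars_select(X, y, cfg: CARSConfig | None = None) -> SelectionResult:
    cfg = cfg or CARSConfig()
    sel = CARSSelector(
        cfg.n_runs, cfg.calibration_fraction, cfg.cv_folds,
        cfg.max_latent_variables, cfg.seed,
    ).fit(X, y)
    return SelectionResult(
        method="CARS",
        selected_indices=np.nonzero(sel.support_)[0],
        rmsecv_trace=sel.rmsecv_trace_,
        retained_counts=sel.retained_counts_,
        seed=cfg.seed,
    )


# ------------------------------------------------------------------------ SPA


class SPASelector(SelectorMixin, BaseEstimator):
    """Successive projections algorithm selector.

    For every candidate starting column a chain is grown by repeatedly
    appending the column with the largest projection norm onto the
    orthogonal complement of the selected columns' span.  Every
    (start, length) chain with length in [min_vars, max_vars] is scored by
    the RMSE of an ordinary least-squares fit on a seeded held-out
    validation split; ties prefer shorter chains, then lower start index.
    """

    def __init__(
        self,
        min_vars: int = 5,
        max_vars: int = 25,
        validation_fraction: float = 0.2,
        seed: int = 0,
    ):
        self.min_vars = min_vars
        self.max_vars = max_vars
        self.validation_fraction = validation_fraction
        self.seed = seed

    @staticmethod
    def _chain(X: np.ndarray, start: int, length: int) -> list[int]:
        """Gram-Schmidt forward chain of column indices starting at ``start``."""
        R = X.copy()
        chain = [start]
        for _ in range(length - 1):
            q = R[:, chain[-1]]
            nq = np.linalg.norm(q)
            if nq == 0:
                break
            q = q / nq
            R = R - np.outer(q, q @ R)
            norms = np.linalg.norm(R, axis=0)
            norms[chain] = -1.0
            nxt = int(np.argmax(norms))
            if norms[nxt] <= 1e-10:
                break
            chain.append(nxt)
        return chain

    def fit(self, X, y):
        X, y = _validate_xy(X, y)
        n, p = X.shape
        if not 1 <= self.min_vars <= self.max_vars:
            raise ValueError("need 1 <= min_vars <= max_vars")
        rng = np.random.default_rng(self.seed)
        perm = rng.permutation(n)
        n_val = max(1, round(self.validation_fraction * n))
        val, tr = perm[:n_val], perm[n_val:]
        if self.max_vars > min(tr.size - 1, p):
            raise ValueError("max_vars exceeds the rank-feasible limit")

        best = None  # (rmse, length, start, chain)
        for start in range(p):
            chain = self._chain(X, start, self.max_vars)
            for L in range(self.min_vars, min(self.max_vars, len(chain)) + 1):
                cols = chain[:L]
                A = np.column_stack([np.ones(tr.size), X[np.ix_(tr, cols)]])
                coef, *_ = np.linalg.lstsq(A, y[tr], rcond=None)
                Av = np.column_stack([np.ones(val.size), X[np.ix_(val, cols)]])
                rmse = float(np.sqrt(np.mean((y[val] - Av @ coef) ** 2)))
                key = (rmse, L, start)
                if best is None or key < best[:3]:
                    best = (rmse, L, start, cols)

        self.n_features_in_ = p
        self.support_ = np.zeros(p, dtype=bool)
        self.support_[best[3]] = True
        self.chain_ = np.array(best[3])
        self.rmse_ = best[0]
        return self

    def _get_support_mask(self):
        return self.support_


def spa_select(
    X, y, min_vars: int = 5, max_vars: int = 25,
    validation_fraction: float = 0.2, seed: int = 0,
) -> SelectionResult:
    sel = SPASelector(min_vars, max_vars, validation_fraction, seed).fit(X, y)
    return SelectionResult(
        method="SPA",
        selected_indices=sel.chain_.copy(),
        rmsecv_trace=np.array([sel.rmse_]),
        retained_counts=np.array([sel.chain_.size]),
        seed=seed,
    )


# ------------------------------------------------------------------------ UVE


class UVESelector(SelectorMixin, BaseEstimator):
    """Uninformative variable elimination against artificial noise variables.

    Appends p uniform noise columns (scaled by ``noise_scale`` so they never
    perturb the fit), collects per-variable PLS coefficients over
    leave-one-out folds, scores each variable by the stability ratio
    c_j = mean(b_j)/sd(b_j), and retains real variables whose |c_j| exceeds
    the ``percentile_cutoff``-th percentile of |c| among the noise columns.
    """

    def __init__(
        self,
        n_latent: int = 10,
        noise_scale: float = 1e-10,
        percentile_cutoff: float = 99.0,
        seed: int = 0,
    ):
        self.n_latent = n_latent
        self.noise_scale = noise_scale
        self.percentile_cutoff = percentile_cutoff
        self.seed = seed

    def fit(self, X, y):
        X, y = _validate_xy(X, y)
        n, p = X.shape
        if n < 5:
            raise ValueError("UVE requires at least 5 samples")
        rng = np.random.default_rng(self.seed)
        noise = rng.uniform(0.0, 1.0, size=(n, p)) * self.noise_scale
        aug = np.hstack([X, noise])

        coefs = np.empty((n, 2 * p))
        for i in range(n):
            idx = np.delete(np.arange(n), i)
            k = min(self.n_latent, idx.size - 1, 2 * p)
            coefs[i] = _pls_coef(aug[idx], y[idx], max(1, k))

        mean = coefs.mean(axis=0)
        sd = coefs.std(axis=0, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            c = np.where(sd > 0, mean / np.where(sd > 0, sd, 1.0), 0.0)
        if np.any(sd == 0):
            warnings.warn("zero coefficient spread for some variables; reliability set to 0")
        threshold = float(np.percentile(np.abs(c[p:]), self.percentile_cutoff))

        self.n_features_in_ = p
        self.reliability_ = c[:p]
        self.threshold_ = threshold
        self.support_ = np.abs(c[:p]) > threshold
        return self

    def _get_support_mask(self):
        return self.support_


def uve_select(
    X, y, n_latent: int = 10, noise_scale: float = 1e-10,
    percentile_cutoff: float = 99.0, seed: int = 0,
) -> SelectionResult:
    sel = UVESelector(n_latent, noise_scale, percentile_cutoff, seed).fit(X, y)
    return SelectionResult(
        method="UVE",
        selected_indices=np.nonzero(sel.support_)[0],
        retained_counts=np.array([int(sel.support_.sum())]),
        threshold=sel.threshold_,
        seed=seed,
    )


SELECTOR_REGISTRY = {
    "CARS": CARSSelector,
    "SPA": SPASelector,
    "UVE": UVESelector,
}
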