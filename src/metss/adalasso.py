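"""Adaptive LASSO estimation for metabolomic severity scores.

The estimator is a two-stage penalized linear regression:

1. A ridge regression (L2) fit, with the penalty chosen by K-fold
   cross-validation, supplies per-feature penalty factors
   ``w_j = 1 / |beta_ridge_j|`` (capped for near-zero coefficients).
2. An L1 (LASSO) problem with those penalty factors is solved by cyclic
   coordinate descent over a descending grid of penalties ``lambda``;
   K-fold cross-validation selects the ``lambda`` with the lowest mean
   out-of-fold squared error, and a final fit at that ``lambda`` on the
   full data yields the score weights.

Both stages support positive per-observation weights, which enter all
inner products, standardizations and error terms.  Multiplying every
observation weight by the same positive constant leaves the solution
path unchanged (weights are normalized to mean one internally).

Objective conventions
---------------------
Ridge minimizes ``sum_i w_i (y_i - b0 - x_i'b)^2 + lam * sum_j b_j^2``
(intercept unpenalized).  The LASSO stage minimizes::

    (1 / 2n) sum_i w_i (y_i - b0 - x_i'b)^2 + lam * sum_j pf_j |b_j|

on internally standardized columns (weighted mean 0, weighted SD 1);
coefficients are returned on the input scale.  ``lambda_max``, the
smallest penalty at which every penalized coefficient is zero, anchors a
log-spaced path.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from numba import njit

__all__ = [
    "ridge_fit",
    "ridge_cv",
    "penalty_weights",
    "lambda_grid",
    "lasso_cd",
    "cv_adalasso",
    "kkt_check",
    "AdaptiveLasso",
    "AdaLassoFit",
    "ConvergenceError",
]

DEFAULT_CAP = 1e6
DEFAULT_RIDGE_GRID = tuple(np.logspace(-2.0, 4.0, 13))
# relative inflation of lambda_max so the KKT comparison at the path anchor
# is robust to last-ulp rounding and coefficients there are exactly zero
_LAMBDA_MAX_PAD = 1e-9


class ConvergenceError(RuntimeError):
    """Coordinate descent failed to reach the KKT tolerance.

    Carries the maximum KKT violation observed at termination.
    """

    def __init__(self, message: str, max_violation: float):
        super().__init__(message)
        self.max_violation = float(max_violation)


# ---------------------------------------------------------------------------
# weighted standardization helpers


def _norm_weights(n: int, obs_weights) -> np.ndarray:
    if obs_weights is None:
        return np.ones(n)
    w = np.asarray(obs_weights, dtype=float)
    if w.shape != (n,):
        raise ValueError(f"obs_weights must have shape ({n},)")
    if np.any(w <= 0) or not np.all(np.isfinite(w)):
        raise ValueError("observation weights must be positive and finite")
    return w / w.mean()


def _standardize(X: np.ndarray, w: np.ndarray):
    """Weighted column standardization; constant columns get SD 1 (stay zero)."""
    n = X.shape[0]
    mean = (w[:, None] * X).sum(axis=0) / n
    Xc = X - mean
    sd = np.sqrt((w[:, None] * Xc**2).sum(axis=0) / n)
    const = sd <= 0
    sd = np.where(const, 1.0, sd)
    return Xc / sd, mean, sd


def _center_y(y: np.ndarray, w: np.ndarray):
    ybar = float((w * y).sum() / y.shape[0])
    return y - ybar, ybar


# ---------------------------------------------------------------------------
# ridge


def ridge_fit(X, y, lam_ridge, obs_weights=None, standardize=True):
    """Weighted ridge regression, closed form via SVD.

    Minimizes ``sum_i w_i (y_i - b0 - x_i'b)^2 + lam_ridge * ||b||^2`` with an
    unpenalized intercept.  Stable for p > n whenever ``lam_ridge > 0``.

    Returns ``(coef, intercept)`` on the input scale.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if n < 2:
        raise ValueError("ridge_fit needs at least 2 observations")
    if lam_ridge < 0:
        raise ValueError("lam_ridge must be >= 0")
    w = _norm_weights(n, obs_weights)
    if standardize:
        Xs, mean, sd = _standardize(X, w)
    else:
        mean = (w[:, None] * X).sum(axis=0) / n
        Xs, sd = X - mean, np.ones(p)
    yc, ybar = _center_y(y, w)
    sw = np.sqrt(w)
    U, d, Vt = np.linalg.svd(sw[:, None] * Xs, full_matrices=False)
    if lam_ridge == 0 and (d.size == 0 or d.min() <= 1e-10 * max(d.max(), 1.0)):
        raise np.linalg.LinAlgError(
            "lam_ridge=0 with a rank-deficient design has no unique solution"
        )
    shrink = d / (d**2 + lam_ridge)
    beta_s = Vt.T @ (shrink * (U.T @ (sw * yc)))
    coef = beta_s / sd
    intercept = ybar - float(coef @ mean)
    return coef, intercept


def ridge_cv(X, y, grid=None, folds=10, seed=0, obs_weights=None, standardize=True):
    """Choose the ridge penalty by K-fold CV (minimum mean out-of-fold MSE).

    A single SVD per training fold serves the whole grid.  Deterministic
    given ``seed``.  Returns the chosen penalty.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    grid = np.asarray(DEFAULT_RIDGE_GRID if grid is None else grid, dtype=float)
    if grid.size == 0:
        raise ValueError("ridge penalty grid must be nonempty")
    if folds < 2 or n < folds:
        raise ValueError("need 2 <= folds <= n")
    w = _norm_weights(n, obs_weights)
    assign = _fold_assignments(n, folds, seed)
    sse = np.zeros(grid.size)
    wsum = np.zeros(grid.size)
    for f in range(folds):
        te = assign == f
        tr = ~te
        wtr = w[tr] / w[tr].mean()
        if standardize:
            Xs, mean, sd = _standardize(X[tr], wtr)
        else:
            mean = (wtr[:, None] * X[tr]).sum(axis=0) / tr.sum()
            Xs, sd = X[tr] - mean, np.ones(p)
        yc, ybar = _center_y(y[tr], wtr)
        sw = np.sqrt(wtr)
        U, d, Vt = np.linalg.svd(sw[:, None] * Xs, full_matrices=False)
        uty = U.T @ (sw * yc)
        Xte = (X[te] - mean) / sd
        for i, lam in enumerate(grid):
            beta = Vt.T @ ((d / (d**2 + lam)) * uty)
            resid = y[te] - (ybar + Xte @ beta)
            sse[i] += float(w[te] @ resid**2)
            wsum[i] += float(w[te].sum())
    return float(grid[int(np.argmin(sse / wsum))])


def penalty_weights(ridge_beta, cap=DEFAULT_CAP):
    """Adaptive penalty factors ``w_j = min(1/|beta_j|, cap)``."""
    b = np.abs(np.asarray(ridge_beta, dtype=float))
    if not np.all(np.isfinite(b)):
        raise ValueError("ridge coefficients must be finite")
    with np.errstate(divide="ignore"):
        w = np.where(b > 0, 1.0 / b, np.inf)
    return np.minimum(w, cap)


# ---------------------------------------------------------------------------
# lambda path


def lambda_grid(X, y, penalty_factors=None, obs_weights=None, n_lambda=100,
                ratio=1e-4, standardize=True):
    """Descending log-spaced penalty grid anchored at ``lambda_max``.

    ``lambda_max = max_j |<x_j, y - ybar>_w| / (n * pf_j)`` over features with
    a finite positive penalty factor; at that penalty all penalized
    coefficients are zero (KKT).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    pf = np.ones(p) if penalty_factors is None else np.asarray(penalty_factors, float)
    if np.any(pf < 0):
        raise ValueError("penalty factors must be >= 0")
    w = _norm_weights(n, obs_weights)
    if standardize:
        Xs, _, _ = _standardize(X, w)
    else:
        Xs = X - (w[:, None] * X).sum(axis=0) / n
    yc, _ = _center_y(y, w)
    g = np.abs(Xs.T @ (w * yc)) / n
    ok = np.isfinite(pf) & (pf > 0)
    if not ok.any():
        raise ValueError("no finite positive penalty factor; lambda_max undefined")
    lam_max = float(np.max(g[ok] / pf[ok])) * (1.0 + _LAMBDA_MAX_PAD)
    if lam_max <= 0:
        lam_max = 1e-3  # y orthogonal to every penalized column
    return np.geomspace(lam_max, lam_max * ratio, int(n_lambda))


# ---------------------------------------------------------------------------
# coordinate descent kernels


@njit(cache=True)
def _cd_kernel(Xs, resid, w, colvar, lam, pf, beta, tol, max_sweeps):  # pragma: no cover
    """Cyclic coordinate descent with active-set refinement between sweeps.

    ``colvar[j]`` is the weighted mean square of column j (1 for standardized
    columns); ``resid`` holds y - Xs @ beta (centered) and is updated in
    place along with ``beta``.  Returns sweeps used, or -1 if the budget is
    exhausted.
    """
    n, p = Xs.shape
    sweeps = 0
    while sweeps < max_sweeps:
        sweeps += 1
        max_delta = 0.0
        for j in range(p):
            vj = colvar[j]
            if vj <= 0.0:
                continue
            bj = beta[j]
            g = vj * bj
            for i in range(n):
                g += w[i] * Xs[i, j] * resid[i] / n
            t = lam * pf[j]
            if g > t:
                nb = (g - t) / vj
            elif g < -t:
                nb = (g + t) / vj
            else:
                nb = 0.0
            d = nb - bj
            if d != 0.0:
                beta[j] = nb
                for i in range(n):
                    resid[i] -= Xs[i, j] * d
                ad = abs(d)
                if ad > max_delta:
                    max_delta = ad
        if max_delta < tol:
            return sweeps
        # active-set refinement until stable, then another full sweep
        inner = 0
        while inner < 1000:
            inner += 1
            max_delta = 0.0
            for j in range(p):
                bj = beta[j]
                if bj == 0.0:
                    continue
                vj = colvar[j]
                g = vj * bj
                for i in range(n):
                    g += w[i] * Xs[i, j] * resid[i] / n
                t = lam * pf[j]
                if g > t:
                    nb = (g - t) / vj
                elif g < -t:
                    nb = (g + t) / vj
                else:
                    nb = 0.0
                d = nb - bj
                if d != 0.0:
                    beta[j] = nb
                    for i in range(n):
                        resid[i] -= Xs[i, j] * d
                    ad = abs(d)
                    if ad > max_delta:
                        max_delta = ad
            if max_delta < tol:
                break
    return -1


@njit(cache=True)
def _cd_path_kernel(Xs, yc, w, lams, pf, tol, max_sweeps,
                    rsq_stop, fdev_min):  # pragma: no cover
    """Warm-started path fit with deviance-based early stopping.

    Stops (cleanly) once the in-sample R^2 exceeds ``rsq_stop`` or its
    per-step improvement falls below ``fdev_min`` — the remaining, denser
    end of the path is the overfitting region cross-validation never
    selects.  Returns (betas, n_fitted, ok); ok=False means the sweep
    budget was exhausted at path position n_fitted.
    """
    n, p = Xs.shape
    colvar = np.ones(p)
    betas = np.zeros((lams.shape[0], p))
    beta = np.zeros(p)
    resid = yc.copy()
    tss = 0.0
    for i in range(n):
        tss += w[i] * yc[i] * yc[i]
    if tss <= 0.0:
        tss = 1.0
    prev_rsq = 0.0
    for k in range(lams.shape[0]):
        status = _cd_kernel(Xs, resid, w, colvar, lams[k], pf, beta, tol, max_sweeps)
        if status < 0:
            return betas, k, False
        betas[k] = beta
        rss = 0.0
        for i in range(n):
            rss += w[i] * resid[i] * resid[i]
        rsq = 1.0 - rss / tss
        # stop when the fit saturates or its fractional improvement stalls
        if rsq > rsq_stop or (k > 0 and rsq > 0.0
                              and rsq - prev_rsq < fdev_min * rsq):
            return betas, k + 1, True
        prev_rsq = rsq
    return betas, lams.shape[0], True


def _kkt_violation_std(Xs, resid, w, lam, pf, beta):
    n = Xs.shape[0]
    g = Xs.T @ (w * resid) / n
    viol = np.zeros_like(beta)
    nz = beta != 0
    viol[nz] = np.abs(g[nz] - lam * pf[nz] * np.sign(beta[nz]))
    viol[~nz] = np.maximum(0.0, np.abs(g[~nz]) - lam * pf[~nz])
    return float(viol.max(initial=0.0))


def lasso_cd(X, y, lam, penalty_factors=None, obs_weights=None, tol=1e-8,
             max_iter=100_000, standardize=True, kkt_tol=None):
    """Weighted LASSO with per-feature penalty factors by coordinate descent.

    Soft-thresholds each coordinate at ``lam * pf_j``; converged when the
    largest coefficient update in a full sweep is below ``tol`` and the KKT
    residual is below ``kkt_tol`` (default ``max(1e-6, 100 * tol)``, i.e.
    1e-6 at the default ``tol``).  Returns ``(coef, intercept)`` on the
    input scale.

    Raises
    ------
    ConvergenceError
        if the sweep budget is exhausted; carries the max KKT violation.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if lam < 0:
        raise ValueError("lam must be >= 0")
    if kkt_tol is None:
        kkt_tol = max(1e-6, 100.0 * tol)
    pf = np.ones(p) if penalty_factors is None else np.asarray(penalty_factors, float)
    w = _norm_weights(n, obs_weights)
    if standardize:
        Xs, mean, sd = _standardize(X, w)
        colvar = np.ones(p)
    else:
        mean = (w[:, None] * X).sum(axis=0) / n
        Xs, sd = X - mean, np.ones(p)
        colvar = (w[:, None] * Xs**2).sum(axis=0) / n
    yc, ybar = _center_y(y, w)
    beta = np.zeros(p)
    resid = yc.copy()
    max_sweeps = max(int(max_iter), 1)
    Xs = np.ascontiguousarray(Xs)
    for _ in range(5):
        status = _cd_kernel(Xs, resid, w, colvar, float(lam), pf, beta, tol, max_sweeps)
        viol = _kkt_violation_std(Xs, resid, w, float(lam), pf, beta)
        if status >= 0 and viol <= kkt_tol:
            break
    else:
        raise ConvergenceError(
            f"coordinate descent did not converge (max KKT violation {viol:.3e})",
            viol,
        )
    coef = beta / sd
    intercept = ybar - float(coef @ mean)
    return coef, intercept


def kkt_check(fit, X, y):
    """Maximum KKT residual of a fit at its chosen penalty (standardized scale).

    For zero coefficients the residual is ``max(0, |g_j| - lam*pf_j)``; for
    active ones ``|g_j - lam*pf_j*sign(b_j)|``, with ``g`` the weighted
    gradient of the smooth part.  Test harness for converged fits.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = X.shape[0]
    w = _norm_weights(n, getattr(fit, "obs_weights", None))
    Xs, mean, sd = _standardize(X, w)
    yc, ybar = _center_y(y, w)
    beta = np.asarray(fit.coef) * sd  # back to standardized scale
    resid = yc - Xs @ beta
    return _kkt_violation_std(Xs, resid, w, fit.lambda_min,
                              np.asarray(fit.penalty_factors), beta)


# ---------------------------------------------------------------------------
# cross-validated procedure


def _fold_assignments(n, folds, seed):
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    assign = np.empty(n, dtype=np.int64)
    for f, chunk in enumerate(np.array_split(perm, folds)):
        assign[chunk] = f
    return assign


@dataclass
class AdaLassoFit:
    """Results of a cross-validated (adaptive) LASSO fit.

    Holds the full penalty path, the CV curve, and the coefficients at the
    CV-chosen penalty (the severity-score weights).
    """

    feature_names: list
    lambdas: np.ndarray
    coef_path: np.ndarray          # (n_lambda, p), input scale
    intercept_path: np.ndarray
    cv_mse_mean: np.ndarray
    cv_mse_se: np.ndarray
    lambda_min: float
    coef: np.ndarray               # at lambda_min, input scale
    intercept: float
    penalty_factors: np.ndarray
    ridge_lambda: float | None
    seed: int
    folds: int
    obs_weights: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    @property
    def selected(self) -> dict:
        """Nonzero coefficients at the chosen penalty, by feature name."""
        nz = np.flatnonzero(self.coef)
        return {self.feature_names[j]: float(self.coef[j]) for j in nz}

    @property
    def n_selected(self) -> int:
        return int(np.count_nonzero(self.coef))

    def predict(self, X) -> np.ndarray:
        return self.intercept + np.asarray(X, dtype=float) @ self.coef

    def summary(self) -> str:
        lines = [
            "Cross-validated adaptive LASSO fit",
            "==================================",
            f"features: {len(self.feature_names)}   folds: {self.folds}   seed: {self.seed}",
            f"ridge penalty: {self.ridge_lambda}",
            f"lambda_min: {self.lambda_min:.6g}  "
            f"(CV MSE {self.cv_mse_mean[np.argmin(self.cv_mse_mean)]:.6g})",
            f"selected features: {self.n_selected}",
            "",
            f"{'feature':<40s}{'coefficient':>14s}",
        ]
        for name, b in sorted(self.selected.items(), key=lambda kv: -abs(kv[1])):
            lines.append(f"{name:<40s}{b:>14.5f}")
        return "\n".join(lines)

    def to_json(self, path=None):
        obj = {
            "feature_names": list(self.feature_names),
            "lambdas": self.lambdas.tolist(),
            "coef_path": self.coef_path.tolist(),
            "intercept_path": self.intercept_path.tolist(),
            "cv_mse_mean": self.cv_mse_mean.tolist(),
            "cv_mse_se": self.cv_mse_se.tolist(),
            "lambda_min": self.lambda_min,
            "coef": self.coef.tolist(),
            "intercept": self.intercept,
            "penalty_factors": self.penalty_factors.tolist(),
            "ridge_lambda": self.ridge_lambda,
            "seed": self.seed,
            "folds": self.folds,
            "meta": self.meta,
        }
        s = json.dumps(obj)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s)
        return s

    @classmethod
    def from_json(cls, source):
        if isinstance(source, str) and source.lstrip().startswith("{"):
            obj = json.loads(source)
        else:
            with open(source) as fh:
                obj = json.load(fh)
        return cls(
            feature_names=obj["feature_names"],
            lambdas=np.asarray(obj["lambdas"]),
            coef_path=np.asarray(obj["coef_path"]),
            intercept_path=np.asarray(obj["intercept_path"]),
            cv_mse_mean=np.asarray(obj["cv_mse_mean"]),
            cv_mse_se=np.asarray(obj["cv_mse_se"]),
            lambda_min=obj["lambda_min"],
            coef=np.asarray(obj["coef"]),
            intercept=obj["intercept"],
            penalty_factors=np.asarray(obj["penalty_factors"]),
            ridge_lambda=obj["ridge_lambda"],
            seed=obj["seed"],
            folds=obj["folds"],
            meta=obj.get("meta", {}),
        )

    def cv_curve_tsv(self, path):
        import pandas as pd

        pd.DataFrame(
            {"lambda": self.lambdas, "cv_mse_mean": self.cv_mse_mean,
             "cv_mse_se": self.cv_mse_se}
        ).to_csv(path, sep="\t", index=False)


class AdaptiveLasso:
    """Adaptive (or plain) LASSO model for a continuous outcome.

    Parameters
    ----------
    y : array (n,)
        Outcome (e.g. FEV1 in liters).
    X : array (n, p)
        Design matrix; typically log metabolite abundances plus 0/1
        present/absent indicators.
    feature_names : sequence of str, optional
    obs_weights : array (n,), optional
        Positive per-observation weights (scale-invariant).
    adaptive : bool
        If True (default), ridge-derived penalty factors; if False, all
        penalty factors are 1 (plain LASSO).
    """

    def __init__(self, y, X, feature_names=None, obs_weights=None, adaptive=True,
                 ridge_grid=None, cap=DEFAULT_CAP, standardize=True):
        self.y = np.asarray(y, dtype=float)
        self.X = np.asarray(X, dtype=float)
        if self.X.ndim != 2 or self.X.shape[0] != self.y.shape[0]:
            raise ValueError("X must be (n, p) with n matching y")
        n, p = self.X.shape
        if feature_names is None:
            feature_names = [f"x{j}" for j in range(p)]
        if len(feature_names) != p:
            raise ValueError("feature_names length must match X columns")
        self.feature_names = list(feature_names)
        self.obs_weights = None if obs_weights is None else np.asarray(obs_weights, float)
        self.adaptive = bool(adaptive)
        self.ridge_grid = ridge_grid
        self.cap = cap
        self.standardize = standardize

    @classmethod
    def from_dataframe(cls, df, outcome, features=None, **kwargs):
        feats = [c for c in df.columns if c != outcome] if features is None else list(features)
        return cls(df[outcome].to_numpy(float), df[feats].to_numpy(float),
                   feature_names=feats, **kwargs)

    def fit(self, lam, penalty_factors=None, tol=1e-8, max_iter=100_000):
        """Single-penalty fit; returns (coef, intercept)."""
        return lasso_cd(self.X, self.y, lam, penalty_factors=penalty_factors,
                        obs_weights=self.obs_weights, tol=tol, max_iter=max_iter,
                        standardize=self.standardize)

    def fit_cv(self, folds=10, seed=0, n_lambda=100, lambda_ratio=1e-4,
               tol=1e-8, max_iter=100_000) -> AdaLassoFit:
        return cv_adalasso(
            self.X, self.y, folds=folds, seed=seed, obs_weights=self.obs_weights,
            feature_names=self.feature_names, adaptive=self.adaptive,
            ridge_grid=self.ridge_grid, cap=self.cap, n_lambda=n_lambda,
            lambda_ratio=lambda_ratio, tol=tol, max_iter=max_iter,
        )


def _path_fit(X, y, w, lams, pf, tol, max_sweeps, rsq_stop=2.0, fdev_min=0.0):
    """Standardize, run the path kernel, return input-scale paths.

    ``rsq_stop``/``fdev_min`` enable deviance-based early stopping (used for
    the cross-validation fold fits); the defaults disable it.  Returns the
    number of path positions actually fitted.
    """
    n, p = X.shape
    Xs, mean, sd = _standardize(X, w)
    yc, ybar = _center_y(y, w)
    betas_std, nfit, ok = _cd_path_kernel(
        np.ascontiguousarray(Xs), yc, w, np.asarray(lams, float), pf,
        tol, max_sweeps, rsq_stop, fdev_min,
    )
    if not ok:
        raise ConvergenceError(
            f"path fit exhausted its sweep budget at lambda index {nfit}",
            float("nan"))
    coefs = betas_std[:nfit] / sd
    intercepts = ybar - coefs @ mean
    return coefs, intercepts, nfit


def cv_adalasso(X, y, folds=10, seed=0, obs_weights=None, feature_names=None,
                adaptive=True, ridge_grid=None, cap=DEFAULT_CAP, n_lambda=100,
                lambda_ratio=1e-4, tol=1e-8, cv_tol=1e-4,
                max_iter=100_000) -> AdaLassoFit:
    """Full cross-validated adaptive LASSO procedure.

    ridge CV -> ridge fit -> penalty factors -> lambda path -> per-fold path
    fits -> mean out-of-fold MSE per lambda -> lambda at the minimum mean MSE
    ("lambda-min" rule) -> final fit on all data.  Deterministic given seed.

    Fold fits use the looser ``cv_tol`` and stop early once the in-sample fit
    saturates (the dense end of the path that CV never selects); penalties
    not reached by every fold get a NaN CV entry and are excluded from the
    minimum.  The final fit runs at the strict ``tol`` from ``lambda_max``
    down to the chosen penalty and is KKT-verified, so ``coef_path`` covers
    ``lambdas[:k_min + 1]`` while the CV curves span the full grid.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if folds < 2 or n < folds:
        raise ValueError("need 2 <= folds <= n")
    if np.ptp(y) == 0:
        raise ValueError("outcome is constant; nothing to fit")
    w = _norm_weights(n, obs_weights)
    if feature_names is None:
        feature_names = [f"x{j}" for j in range(p)]

    ridge_lambda = None
    if adaptive:
        ridge_lambda = ridge_cv(X, y, grid=ridge_grid, folds=folds, seed=seed,
                                obs_weights=w)
        ridge_beta_std = _ridge_std_coef(X, y, ridge_lambda, w)
        pf = penalty_weights(ridge_beta_std, cap=cap)
    else:
        pf = np.ones(p)

    lams = lambda_grid(X, y, penalty_factors=pf, obs_weights=w,
                       n_lambda=n_lambda, ratio=lambda_ratio)
    assign = _fold_assignments(n, folds, seed)
    max_sweeps = max(int(max_iter), 1)

    fold_mse = np.full((folds, len(lams)), np.nan)
    for f in range(folds):
        te = assign == f
        tr = ~te
        wtr = w[tr] / w[tr].mean()
        coefs, intercepts, nfit = _path_fit(X[tr], y[tr], wtr, lams, pf,
                                            cv_tol, max_sweeps,
                                            rsq_stop=0.99, fdev_min=1e-5)
        pred = intercepts[:, None] + coefs @ X[te].T  # (nfit, n_te)
        err = (y[te][None, :] - pred) ** 2
        fold_mse[f, :nfit] = (err * w[te][None, :]).sum(axis=1) / w[te].sum()
    complete = ~np.isnan(fold_mse).any(axis=0)
    cv_mean = np.where(complete, fold_mse.mean(axis=0), np.nan)
    cv_se = np.where(complete, fold_mse.std(axis=0, ddof=1) / np.sqrt(folds),
                     np.nan)
    k_min = int(np.nanargmin(cv_mean))

    coefs, intercepts, _ = _path_fit(X, y, w, lams[:k_min + 1], pf, tol,
                                     max_sweeps)
    fit = AdaLassoFit(
        feature_names=list(feature_names),
        lambdas=np.asarray(lams),
        coef_path=coefs,
        intercept_path=intercepts,
        cv_mse_mean=cv_mean,
        cv_mse_se=cv_se,
        lambda_min=float(lams[k_min]),
        coef=coefs[k_min].copy(),
        intercept=float(intercepts[k_min]),
        penalty_factors=pf,
        ridge_lambda=ridge_lambda,
        seed=int(seed),
        folds=int(folds),
        obs_weights=None if obs_weights is None else np.asarray(obs_weights, float),
        meta={"adaptive": adaptive, "n": int(n), "p": int(p)},
    )
    viol = kkt_check(fit, X, y)
    if viol > 1e-6:
        raise ConvergenceError(
            f"final fit failed KKT verification (violation {viol:.3e})", viol)
    return fit


def _ridge_std_coef(X, y, lam, w):
    """Ridge coefficients on the standardized scale (for penalty factors).

    Penalty factors compare feature importance, so they are taken from the
    standardized-coefficient magnitudes rather than the raw-scale ones.
    """
    n, p = X.shape
    Xs, _, _ = _standardize(X, w)
    yc, _ = _center_y(y, w)
    sw = np.sqrt(w)
    U, d, Vt = np.linalg.svd(sw[:, None] * Xs, full_matrices=False)
    return Vt.T @ ((d / (d**2 + lam)) * (U.T @ (sw * yc)))
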