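"""Metabolomic severity score (metSS) construction and evaluation.

The metSS is the linear predictor of the cross-validated adaptive LASSO
fit: intercept plus the selected metabolite features weighted by their
coefficients.  Built on a training cohort, it is applied unchanged to a
validation cohort whose design was constructed with the training recipe.

Evaluation follows the three-model comparison: ordinary least squares of
the outcome on (a) clinical covariates only, (b) the metSS only, and
(c) metSS plus covariates, summarized by Wherry-adjusted R^2 (in %) and
MSE (= RSS/n, outcome units squared), with a partial F-test comparing
the combined model against covariates only.

Sensitivity analyses: cohort swap (exchange training and validation
roles) and extreme-quintile observation weighting (bottom/top outcome
quintiles up-weighted by a factor, default 5) to penalize errors on the
extremes of the outcome distribution.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .adalasso import AdaLassoFit

__all__ = [
    "MetSS", "build_metss", "apply_metss", "wherry_adj_r2", "eval_models",
    "ModelEval", "extreme_quintile_weights", "predicted_vs_observed",
    "expand_covariates",
]


@dataclass
class MetSS:
    """A severity score: named feature weights plus intercept."""

    features: list
    weights: np.ndarray
    intercept: float
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        if np.any(self.weights == 0):
            raise ValueError("score weights must all be nonzero")
        if len(self.features) != self.weights.shape[0]:
            raise ValueError("features and weights must align")

    def apply(self, design: pd.DataFrame) -> pd.Series:
        return apply_metss(self, design)

    def summary(self) -> str:
        lines = [
            "Metabolomic severity score",
            "==========================",
            f"features: {len(self.features)}   intercept: {self.intercept:.5f}",
            "",
            f"{'feature':<40s}{'weight':>12s}",
        ]
        order = np.argsort(-np.abs(self.weights))
        for j in order:
            lines.append(f"{self.features[j]:<40s}{self.weights[j]:>12.5f}")
        return "\n".join(lines)

    def to_json(self, path=None):
        s = json.dumps({"features": list(self.features),
                        "weights": self.weights.tolist(),
                        "intercept": self.intercept,
                        "provenance": self.provenance})
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
        return cls(features=obj["features"], weights=np.asarray(obj["weights"]),
                   intercept=obj["intercept"], provenance=obj.get("provenance", {}))


def build_metss(fit: AdaLassoFit) -> MetSS:
    """Extract the score from a cross-validated fit (nonzero coefficients)."""
    selected = fit.selected
    if not selected:
        raise ValueError("empty score: the fit selected no features")
    names = list(selected)
    return MetSS(features=names,
                 weights=np.array([selected[m] for m in names]),
                 intercept=float(fit.intercept),
                 provenance={"seed": fit.seed, "lambda_min": fit.lambda_min,
                             "ridge_lambda": fit.ridge_lambda})


def apply_metss(score: MetSS, design: pd.DataFrame) -> pd.Series:
    """Per-sample score: intercept + sum_j w_j * design_ij."""
    missing = [f for f in score.features if f not in design.columns]
    if missing:
        raise KeyError(f"design lacks score features: {missing}")
    vals = design[score.features].to_numpy(float) @ score.weights + score.intercept
    return pd.Series(vals, index=design.index, name="metss")


# ---------------------------------------------------------------------------


def wherry_adj_r2(r2, n, p, variant="n_minus_p_minus_1"):
    """Wherry-shrunken adjusted R^2 (as a fraction).

    Default: ``1 - (1 - R^2)(n - 1)/(n - p - 1)``, the adjustment reported
    by mainstream regression output.  ``variant="n_minus_p"`` uses an
    (n - p) denominator, a variant found in parts of the literature.
    """
    if n <= p + 1:
        raise ValueError("adjusted R^2 undefined for n <= p + 1")
    denom = (n - p - 1) if variant == "n_minus_p_minus_1" else (n - p)
    return 1.0 - (1.0 - r2) * (n - 1) / denom


def expand_covariates(clin: pd.DataFrame, covariates) -> pd.DataFrame:
    """Covariate design matrix: numeric columns as-is, categoricals dummied."""
    cols = []
    for c in covariates:
        s = clin[c]
        if pd.api.types.is_numeric_dtype(s):
            cols.append(s.astype(float).rename(c))
        else:
            d = pd.get_dummies(s.astype(str), prefix=c, drop_first=True)
            cols.extend(d[col].astype(float) for col in d.columns)
    return pd.concat(cols, axis=1)


def _drop_aliased(X: pd.DataFrame) -> pd.DataFrame:
    """Drop columns until the (constant-augmented) design has full rank."""
    Xa = X.copy()
    while Xa.shape[1] > 0:
        M = np.column_stack([np.ones(len(Xa)), Xa.to_numpy(float)])
        rank = np.linalg.matrix_rank(M)
        if rank == M.shape[1]:
            return Xa
        # find first column whose removal does not lower the rank
        for c in Xa.columns:
            M2 = np.column_stack([np.ones(len(Xa)),
                                  Xa.drop(columns=[c]).to_numpy(float)])
            if np.linalg.matrix_rank(M2) == rank:
                warnings.warn(f"dropping aliased covariate column {c!r}")
                Xa = Xa.drop(columns=[c])
                break
        else:  # pragma: no cover
            break
    return Xa


@dataclass
class ModelEval:
    """Three-model comparison: covariates only / metSS only / combined.

    ``models`` maps model name to a dict with adj_r2_pct, mse, r2, n and
    n_predictors; the partial F-test compares combined vs covariates-only.
    """

    models: dict
    f_stat: float
    f_pvalue: float
    n: int
    wherry_variant: str = "n_minus_p_minus_1"

    def summary(self) -> str:
        lines = [
            "Linear-model evaluation (Wherry-adjusted R^2, MSE)",
            "==================================================",
            f"{'model':<24s}{'adj R2 (%)':>12s}{'MSE':>12s}{'predictors':>12s}",
        ]
        for name, m in self.models.items():
            lines.append(f"{name:<24s}{m['adj_r2_pct']:>12.1f}"
                         f"{m['mse']:>12.4f}{m['n_predictors']:>12d}")
        lines.append(f"partial F (combined vs covariates): "
                     f"F = {self.f_stat:.2f}, p = {self.f_pvalue:.3g}")
        return "\n".join(lines)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.models).T

    def to_tsv(self, path):
        self.to_frame().to_csv(path, sep="\t", index_label="model")


def _ols_stats(y, X: pd.DataFrame | None, wherry_variant):
    n = len(y)
    if X is None or X.shape[1] == 0:
        exog = np.ones((n, 1))
        p = 0
    else:
        X = _drop_aliased(X)
        exog = sm.add_constant(X.to_numpy(float), has_constant="add")
        p = X.shape[1]
    res = sm.OLS(np.asarray(y, float), exog).fit()
    rss = float(res.ssr)
    return res, {
        "r2": float(res.rsquared),
        "adj_r2_pct": 100.0 * wherry_adj_r2(res.rsquared, n, p,
                                            variant=wherry_variant),
        "mse": rss / n,
        "n": n,
        "n_predictors": p,
    }


def eval_models(y, metss_scores, covariates: pd.DataFrame,
                wherry_variant="n_minus_p_minus_1") -> ModelEval:
    """OLS evaluation of covariates-only, metSS-only and combined models.

    ``covariates`` must already be expanded to numeric columns (see
    :func:`expand_covariates`).  Complete cases only; MSE = RSS/n; the
    combined model is compared with covariates-only by partial F-test.
    """
    y = np.asarray(y, dtype=float)
    s = np.asarray(metss_scores, dtype=float)
    if covariates is not None and len(covariates) != len(y):
        raise ValueError("covariates must align with y")
    score_col = pd.DataFrame({"metss": s},
                             index=covariates.index if covariates is not None
                             else None)
    combined = (pd.concat([covariates, score_col], axis=1)
                if covariates is not None else score_col)

    res_cov, m_cov = _ols_stats(y, covariates, wherry_variant)
    _, m_met = _ols_stats(y, score_col, wherry_variant)
    res_full, m_full = _ols_stats(y, combined, wherry_variant)

    q = m_full["n_predictors"] - m_cov["n_predictors"]
    df_resid = len(y) - m_full["n_predictors"] - 1
    rss_red, rss_full = res_cov.ssr, res_full.ssr
    f = ((rss_red - rss_full) / q) / (rss_full / df_resid)
    pval = float(stats.f.sf(f, q, df_resid))
    return ModelEval(
        models={"covariates_only": m_cov, "metss_only": m_met,
                "metss_plus_covariates": m_full},
        f_stat=float(f), f_pvalue=pval, n=len(y),
        wherry_variant=wherry_variant,
    )


# ---------------------------------------------------------------------------


def extreme_quintile_weights(y_train, factor=5.0) -> np.ndarray:
    """Weight the bottom and top outcome quintiles by ``factor``.

    Quintile membership uses ordinal ranks so that exactly ceil(n/5)
    samples fall in each tail even under ties.
    """
    y = np.asarray(y_train, dtype=float)
    n = y.shape[0]
    if n < 5:
        raise ValueError("need at least 5 samples for quintiles")
    if np.ptp(y) == 0:
        raise ValueError("constant outcome: quintiles undefined")
    k = int(np.ceil(n / 5))
    ranks = stats.rankdata(y, method="ordinal")  # 1..n
    w = np.ones(n)
    w[(ranks <= k) | (ranks > n - k)] = float(factor)
    return w


def predicted_vs_observed(y, scores):
    """Slope and intercept of observed ~ predicted simple regression.

    A slope below 1 is the shrinkage signature: the largest observed
    outcomes are under-predicted and the smallest over-predicted.
    """
    y = np.asarray(y, dtype=float)
    s = np.asarray(scores, dtype=float)
    if y.shape[0] < 3:
        raise ValueError("need at least 3 samples")
    if np.ptp(s) == 0:
        raise ValueError("zero-variance scores")
    slope, intercept = np.polyfit(s, y, 1)
    return float(slope), float(intercept)
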