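"""Multivariate DTI -> histology regression with cross-validation.

Each histological parameter y_kj (animal k, region j) is modelled as

    y_kj = b' x_kj + c + e_kj,     x_kj = (FA, RD, MD, CP, CS),

pooling all animals and regions into one ordinary-least-squares fit.  AD
and CL are excluded by construction: AD = 3 MD - 2 RD and CL = 1 - CP - CS
make the design singular, and requesting them raises an error that names
the dependency.  Predictive value is assessed by leave-one-animal-out and
leave-one-region-out cross-validation, reporting the Pearson correlation R
between pooled held-out predictions and truths and the cross-validated
coefficient of determination

    Q^2 = 1 - mean((y - yhat)^2) / mean((y - ybar)^2),

where ybar is the mean of the true values over all rows.  Q^2 <= 0 means
the model predicts held-out data no better than the mean.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import _bca_bounds

__all__ = [
    "PREDICTORS", "SingularDesignError", "RegressionResult", "CvResult",
    "LoroResult", "fit_multivariate", "pearson_univariate", "univariate_table",
    "loao_cv", "loro_cv", "adjusted_r2", "f_statistic", "q_squared",
]

#: predictor set of the pooled regression
PREDICTORS = ("FA", "RD", "MD", "CP", "CS")

#: exact linear dependencies among the scalar DTI metrics
_KNOWN_DEPENDENCIES = [
    ({"AD", "MD", "RD"}, "AD = 3*MD - 2*RD"),
    ({"CL", "CP", "CS"}, "CL = 1 - CP - CS (with the intercept)"),
]


class SingularDesignError(ValueError):
    """Raised when the regression design matrix is rank deficient."""


def adjusted_r2(r2: float, n: int, p: int) -> float:
    """Closed-form adjusted R^2 = 1 - (1 - R^2)(n - 1)/(n - p - 1)."""
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)


def f_statistic(r2: float, n: int, p: int) -> float:
    """Overall regression F = (R^2/p) / ((1 - R^2)/(n - p - 1))."""
    if r2 >= 1.0:
        return float("inf")
    return (r2 / p) / ((1.0 - r2) / (n - p - 1))


def q_squared(y_true, y_pred) -> float:
    """Cross-validated coefficient of determination of pooled predictions."""
    y = np.asarray(y_true, float)
    yhat = np.asarray(y_pred, float)
    denom = np.mean((y - y.mean()) ** 2)
    if denom == 0:
        raise ValueError("response has zero variance")
    return float(1.0 - np.mean((y - yhat) ** 2) / denom)


@dataclass
class RegressionResult:
    b: np.ndarray            # coefficients in predictor order
    c: float                 # intercept
    R2: float
    R2_adj: float
    F: float
    R2_ci: tuple[float, float] | None
    n: int
    predictors: tuple[str, ...]
    response: str

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, float) @ self.b + self.c


@dataclass
class CvResult:
    R_cv: float
    Q2: float
    per_fold_predictions: pd.DataFrame  # columns: fold, y_true, y_pred


@dataclass
class LoroResult:
    per_region: dict[str, float]   # held-out Pearson R per region fold
    pooled_R: float                # R over concatenated held-out predictions
    per_fold_predictions: pd.DataFrame


def _design(table: pd.DataFrame, response: str, predictors) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    cols = list(predictors) + [response]
    used = table.dropna(subset=cols)
    X = used[list(predictors)].to_numpy(float)
    y = used[response].to_numpy(float)
    return X, y, used


def _check_rank(X: np.ndarray, predictors) -> None:
    design = np.column_stack([np.ones(len(X)), X])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        names = set(predictors)
        for dep_set, msg in _KNOWN_DEPENDENCIES:
            if dep_set <= names:
                raise SingularDesignError(
                    f"rank-deficient design: {msg}; drop one of {sorted(dep_set)}")
        raise SingularDesignError(
            f"rank-deficient design (rank {rank} < {design.shape[1]})")


def _ols(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float, float]:
    """Least squares fit; returns (b, c, R^2)."""
    design = np.column_stack([np.ones(len(X)), X])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    ss_res = float(resid @ resid)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    return coef[1:], float(coef[0]), r2


def fit_multivariate(table: pd.DataFrame, response: str,
                     predictors=PREDICTORS, *, animal_col: str = "animal_id",
                     ci: bool = True, n_boot: int = 2000, alpha: float = 0.05,
                     seed: int | None = None) -> RegressionResult:
    """Pooled OLS of one histological response on the DTI predictors.

    The 95% CI for R^2 is an accelerated bootstrap resampling whole
    animals as blocks (rows within an animal are not independent).
    """
    X, y, used = _design(table, response, predictors)
    n, p = X.shape
    if n <= p + 1:
        raise ValueError(f"need more than {p + 1} rows, got {n}")
    _check_rank(X, predictors)
    b, c, r2 = _ols(X, y)

    r2_ci = None
    if ci:
        rng = np.random.default_rng(seed)
        animals = used[animal_col].to_numpy()
        uniq = np.unique(animals)
        idx_by_animal = {a: np.flatnonzero(animals == a) for a in uniq}

        def r2_of(selected_animals) -> float:
            idx = np.concatenate([idx_by_animal[a] for a in selected_animals])
            try:
                return _ols(X[idx], y[idx])[2]
            except np.linalg.LinAlgError:  # pragma: no cover
                return np.nan

        boot = np.array([
            r2_of(rng.choice(uniq, size=len(uniq), replace=True))
            for _ in range(n_boot)
        ])
        jack = np.array([r2_of(np.delete(uniq, i)) for i in range(len(uniq))])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            r2_ci = _bca_bounds(r2, boot, jack, alpha)

    return RegressionResult(
        b=b, c=c, R2=r2, R2_adj=adjusted_r2(r2, n, p),
        F=f_statistic(r2, n, p), R2_ci=r2_ci, n=n,
        predictors=tuple(predictors), response=response,
    )


def pearson_univariate(table: pd.DataFrame, response: str, predictor: str,
                       alpha: float = 0.05):
    """Pearson R between one DTI predictor and one response, with 95% CI.

    Returns ``(R, (ci_low, ci_high), R^2, p)``; family-wise q-values are
    assigned by :func:`univariate_table`.
    """
    _, _, used = _design(table, response, (predictor,))
    x = used[predictor].to_numpy(float)
    y = used[response].to_numpy(float)
    if len(x) < 3:
        raise ValueError("need at least 3 rows")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in correlation input")
    res = sps.pearsonr(x, y)
    ci = res.confidence_interval(confidence_level=1 - alpha)
    return float(res.statistic), (float(ci.low), float(ci.high)), \
        float(res.statistic) ** 2, float(res.pvalue)


def univariate_table(table: pd.DataFrame, responses, predictors=PREDICTORS) -> pd.DataFrame:
    """Univariate correlation grid with BH-FDR across the whole family."""
    from .stats import bh_fdr

    rows = []
    for resp in responses:
        for pred in predictors:
            r, (lo, hi), r2, p = pearson_univariate(table, resp, pred)
            rows.append(dict(response=resp, predictor=pred, R=r,
                             ci_low=lo, ci_high=hi, R2=r2, p=p))
    out = pd.DataFrame(rows)
    out["q"] = bh_fdr(out["p"].to_numpy())
    return out


def _cv(table: pd.DataFrame, response: str, predictors, fold_col: str) -> pd.DataFrame:
    X, y, used = _design(table, response, predictors)
    folds = used[fold_col].to_numpy()
    preds = np.full(len(y), np.nan)
    for f in pd.unique(folds):
        train = folds != f
        test = ~train
        if train.sum() <= len(predictors) + 1:
            raise ValueError(f"fold {f!r}: too few training rows")
        try:
            _check_rank(X[train], predictors)
        except SingularDesignError as err:
            raise SingularDesignError(f"training fold {f!r}: {err}") from err
        b, c, _ = _ols(X[train], y[train])
        preds[test] = X[test] @ b + c
    return pd.DataFrame({"fold": folds, "y_true": y, "y_pred": preds})


def loao_cv(table: pd.DataFrame, response: str, predictors=PREDICTORS,
            *, animal_col: str = "animal_id") -> CvResult:
    """Leave-one-animal-out CV: all of an animal's regions are held out together."""
    if table[animal_col].nunique() < 3:
        raise ValueError("need at least 3 animals")
    folds = _cv(table, response, predictors, animal_col)
    r_cv = float(np.corrcoef(folds["y_pred"], folds["y_true"])[0, 1])
    return CvResult(R_cv=r_cv, Q2=q_squared(folds["y_true"], folds["y_pred"]),
                    per_fold_predictions=folds)


def loro_cv(table: pd.DataFrame, response: str, predictors=PREDICTORS,
            *, region_col: str = "region") -> LoroResult:
    """Leave-one-region-out CV: per-region held-out R plus the pooled R."""
    if table[region_col].nunique() < 2:
        raise ValueError("need at least 2 regions")
    folds = _cv(table, response, predictors, region_col)
    per_region = {}
    for region, sub in folds.groupby("fold", sort=False):
        per_region[region] = float(np.corrcoef(sub["y_pred"], sub["y_true"])[0, 1])
    pooled = float(np.corrcoef(folds["y_pred"], folds["y_true"])[0, 1])
    return LoroResult(per_region=per_region, pooled_R=pooled,
                      per_fold_predictions=folds)
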