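"""Ordinary least squares for the descriptor models and Pearson correlation
matrices for the multi-target binding-score analysis.

The headline fit statistic throughout the package is the squared Pearson
correlation between observed and predicted values (reported per split
group), with RMSE on the original response scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps


def pearson_r2(observed: np.ndarray, predicted: np.ndarray) -> float:
    """Squared Pearson correlation of two vectors."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    so = obs - obs.mean()
    sp_ = pred - pred.mean()
    denom = np.sqrt((so**2).sum() * (sp_**2).sum())
    if denom == 0:
        raise ValueError("zero-variance vector in correlation")
    return float(((so * sp_).sum() / denom) ** 2)


@dataclass
class RegressionModel:
    """OLS fit of one response on named predictors, with per-group stats."""

    response: str
    predictors: list[str]
    coefficients: np.ndarray  # [intercept, b_1, ..., b_p]
    std_errors: np.ndarray
    t_values: np.ndarray
    p_values: np.ndarray
    stats: dict[str, dict[str, float]] = field(default_factory=dict)
    residuals: pd.Series | None = None  # fitting-group residuals, by id
    train_ids: list[str] = field(default_factory=list)
    rmse_train: float = 0.0

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        M = np.column_stack(
            [np.ones(len(X))] + [X[c].to_numpy(dtype=float) for c in self.predictors]
        )
        return M @ self.coefficients

    def significant_predictors(self, alpha: float = 0.05) -> list[str]:
        """Predictors whose two-sided coefficient t-test rejects at alpha.

        This artifact's convention for "significant contribution"; the
        intercept is not reported.
        """
        return [
            name
            for name, p in zip(self.predictors, self.p_values[1:])
            if p < alpha
        ]


def _design(X: pd.DataFrame, predictors: list[str]) -> np.ndarray:
    return np.column_stack(
        [np.ones(len(X))] + [X[c].to_numpy(dtype=float) for c in predictors]
    )


def fit_ols(
    X: pd.DataFrame,
    y: pd.Series,
    fit_ids: list[str] | None = None,
    predictors: list[str] | None = None,
    response_name: str | None = None,
) -> RegressionModel:
    """Fit y on X (with intercept) over ``fit_ids``; stats on all groups.

    Raises on rank deficiency, naming the collinear columns.  Rows of X not
    in ``fit_ids`` are scored as the held-out group.
    """
    predictors = list(predictors) if predictors is not None else list(X.columns)
    if X[predictors].isna().to_numpy().any():
        bad = [c for c in predictors if X[c].isna().any()]
        raise ValueError(f"missing values in predictor column(s) {bad}")
    fit_ids = list(fit_ids) if fit_ids is not None else list(X.index)
    Xf = X.loc[fit_ids]
    yf = y.loc[fit_ids].to_numpy(dtype=float)
    n, p = len(fit_ids), len(predictors)
    if n <= p + 1:
        raise ValueError(f"need more than {p + 1} fitting rows, got {n}")

    M = _design(Xf, predictors)
    # rank check via QR: near-zero diagonal of R names the collinear columns
    _, R = np.linalg.qr(M)
    diag = np.abs(np.diag(R))
    tol = max(M.shape) * np.finfo(float).eps * diag.max()
    if (diag <= tol).any():
        names = ["intercept"] + predictors
        bad = [names[i] for i in np.flatnonzero(diag <= tol)]
        raise np.linalg.LinAlgError(f"rank-deficient design; collinear: {bad}")

    coef, *_ = np.linalg.lstsq(M, yf, rcond=None)
    resid = yf - M @ coef
    dof = n - (p + 1)
    sigma2 = float(resid @ resid) / dof if dof > 0 else np.nan
    cov = sigma2 * np.linalg.inv(M.T @ M)
    se = np.sqrt(np.diag(cov))
    tvals = coef / se
    pvals = 2 * sps.t.sf(np.abs(tvals), dof)

    model = RegressionModel(
        response=response_name or (y.name or "response"),
        predictors=predictors,
        coefficients=coef,
        std_errors=se,
        t_values=tvals,
        p_values=pvals,
        residuals=pd.Series(resid, index=fit_ids),
        train_ids=fit_ids,
        rmse_train=float(np.sqrt(np.mean(resid**2))),
    )
    model.stats["train"] = {
        "r2": pearson_r2(yf, M @ coef),
        "rmse": model.rmse_train,
        "n": n,
    }
    held_out = [i for i in X.index if i not in set(fit_ids)]
    if held_out:
        yt = y.loc[held_out].to_numpy(dtype=float)
        pred = model.predict(X.loc[held_out])
        model.stats["test"] = {
            "r2": pearson_r2(yt, pred) if np.ptp(yt) > 0 else np.nan,
            "rmse": float(np.sqrt(np.mean((pred - yt) ** 2))),
            "n": len(held_out),
        }
    return model


def q2_external(
    model: RegressionModel, X_test: pd.DataFrame, y_test: pd.Series
) -> float:
    """Squared Pearson correlation of predictions vs observations (test set)."""
    yt = y_test.to_numpy(dtype=float)
    if len(yt) == 0:
        raise ValueError("empty test group")
    if np.ptp(yt) == 0:
        raise ValueError("constant test response")
    return pearson_r2(yt, model.predict(X_test))


def pearson_matrix(table: pd.DataFrame) -> pd.DataFrame:
    """Symmetric Pearson correlation matrix of the given columns."""
    if len(table) < 3:
        raise ValueError("need at least 3 rows for a correlation matrix")
    values = table.to_numpy(dtype=float)
    sd = values.std(axis=0)
    if (sd == 0).any():
        col = table.columns[int(np.flatnonzero(sd == 0)[0])]
        raise ValueError(f"zero-variance column {col!r}")
    corr = np.corrcoef(values, rowvar=False)
    return pd.DataFrame(corr, index=table.columns, columns=table.columns)
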