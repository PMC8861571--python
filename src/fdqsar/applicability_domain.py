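"""Leverage-based applicability domain and Williams-plot data.

The leverage (hat value) of a compound is the diagonal element of the
projection matrix of the linear model, h_i = x_i (XᵀX)⁻¹ x_iᵀ with an
intercept column — a distance of the compound's descriptors from the
training centroid.  Compounds beyond the warning leverage
h* = 3(k + 1)/n (k descriptors, n training compounds; overridable) are
structurally influential; compounds with standardized residuals beyond
±3σ are response outliers.  Standardized residual = raw residual divided
by the training RMSE (plain convention; an internally studentized variant
is available via ``studentized=True``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .regression_stats import RegressionModel


def warning_leverage(k_descriptors: int, n_train: int) -> float:
    """Warning leverage h* = 3(k + 1)/n."""
    if n_train <= 0:
        raise ValueError("n_train must be positive")
    return 3.0 * (k_descriptors + 1) / n_train


def leverages(X_train: np.ndarray, X_query: np.ndarray | None = None) -> np.ndarray:
    """Hat values for training rows, or generalized leverages for queries.

    ``X_train`` must already contain the intercept column.  With
    ``X_query`` given, returns x (XᵀX)⁻¹ xᵀ per query row.
    """
    X_train = np.asarray(X_train, dtype=float)
    gram = X_train.T @ X_train
    if np.linalg.matrix_rank(gram) < gram.shape[0]:
        raise np.linalg.LinAlgError("singular X'X; design is rank-deficient")
    inv = np.linalg.inv(gram)
    target = X_train if X_query is None else np.asarray(X_query, dtype=float)
    return np.einsum("ij,jk,ik->i", target, inv, target)


@dataclass
class ADReport:
    """Per-compound leverage / residual table with outlier flags."""

    table: pd.DataFrame  # columns: leverage, std_residual, beyond_h_star, beyond_3sigma
    h_star: float
    k_descriptors: int
    n_train: int

    @property
    def influential(self) -> list[str]:
        return list(self.table.index[self.table["beyond_h_star"]])

    @property
    def response_outliers(self) -> list[str]:
        return list(self.table.index[self.table["beyond_3sigma"]])


def williams_data(
    model: RegressionModel,
    X: pd.DataFrame,
    y: pd.Series,
    h_star: float | None = None,
    studentized: bool = False,
) -> ADReport:
    """Williams-plot data (leverage vs standardized residual) for all rows.

    Training rows get hat values; other rows get generalized leverages
    computed against the training design.  The report is sorted by id.
    """
    if model.rmse_train <= 0:
        raise ValueError("zero training RMSE; residuals cannot be standardized")
    preds = model.predictors
    design_all = np.column_stack(
        [np.ones(len(X))] + [X[c].to_numpy(dtype=float) for c in preds]
    )
    train_pos = [X.index.get_loc(i) for i in model.train_ids]
    X_train = design_all[train_pos]
    h = leverages(X_train, design_all)

    resid = y.to_numpy(dtype=float) - model.predict(X)
    if studentized:
        denom = model.rmse_train * np.sqrt(np.clip(1.0 - h, 1e-12, None))
    else:
        denom = model.rmse_train
    std_resid = resid / denom

    k = len(preds)
    n = len(model.train_ids)
    if h_star is None:
        h_star = warning_leverage(k, n)
    table = pd.DataFrame(
        {
            "leverage": h,
            "std_residual": std_resid,
            "beyond_h_star": h > h_star,
            "beyond_3sigma": np.abs(std_resid) > 3.0,
        },
        index=X.index,
    ).sort_index()
    return ADReport(table=table, h_star=float(h_star), k_descriptors=k, n_train=n)
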