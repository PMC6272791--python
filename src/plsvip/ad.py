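"""Leverage applicability domain and Williams-plot data.

The domain of a QSAR model is delimited in descriptor space by the leverage
h_i = x_i'(X'X)⁻¹x_i computed against the autoscaled training matrix of the
final model variables, with control leverage h* = 3k/n (k model variables,
n training compounds).  Compounds are cross-checked on the response axis by
standardized residuals (residual / training RMSE): training rows use their
LOO residuals, test rows their prediction residuals; |standardized
residual| > 3 marks a response outlier.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .pls import PLSFit, predict, rmse as _rmse
from .validation import loo_cv

__all__ = [
    "ADReport",
    "leverages",
    "control_leverage",
    "standardized_residuals",
    "williams_report",
]


@dataclass
class ADReport:
    h_star: float
    rows: pd.DataFrame  # columns: id, set, leverage, std_residual, in_domain, outlier

    @property
    def outliers(self) -> list[str]:
        return [str(i) for i in self.rows.loc[self.rows["outlier"], "id"]]

    @property
    def out_of_domain(self) -> list[str]:
        return [str(i) for i in self.rows.loc[~self.rows["in_domain"], "id"]]

    def summary(self) -> dict:
        by_set = self.rows.groupby("set").size().to_dict()
        return {
            "h_star": self.h_star,
            "n": int(len(self.rows)),
            "counts": {k: int(v) for k, v in by_set.items()},
            "n_outliers": int(self.rows["outlier"].sum()),
            "n_out_of_domain": int((~self.rows["in_domain"]).sum()),
        }


def leverages(X_train_scaled, X_query_scaled) -> np.ndarray:
    """h_i = x_i'(X'X)⁻¹x_i for every query row, X the scaled training matrix.

    Falls back to the Moore–Penrose pseudo-inverse (with a warning) when the
    training Gram matrix is rank deficient.
    """
    Xt = np.asarray(getattr(X_train_scaled, "values", X_train_scaled), dtype=float)
    Xq = np.asarray(getattr(X_query_scaled, "values", X_query_scaled), dtype=float)
    if Xq.ndim == 1:
        Xq = Xq[None, :]
    if Xt.shape[1] != Xq.shape[1]:
        raise ValueError(f"column mismatch: training has {Xt.shape[1]}, query {Xq.shape[1]}")
    G = Xt.T @ Xt
    rank = np.linalg.matrix_rank(G)
    if rank < G.shape[0]:
        warnings.warn(
            f"training Gram matrix rank deficient ({rank}/{G.shape[0]}); using pseudo-inverse",
            RuntimeWarning,
        )
    Ginv = np.linalg.pinv(G, rcond=1e-10)
    return np.einsum("ij,jk,ik->i", Xq, Ginv, Xq)


def control_leverage(k: int, n: int) -> float:
    """Control leverage h* = 3k/n."""
    if k <= 0 or n <= 0:
        raise ValueError("k and n must be positive")
    return 3.0 * k / n


def standardized_residuals(residuals, rmse_train: float) -> np.ndarray:
    """Residuals divided by the training RMSE."""
    if rmse_train <= 0:
        raise ValueError("rmse_train must be positive")
    return np.asarray(residuals, dtype=float).ravel() / rmse_train


def williams_report(
    fit: PLSFit,
    X_train,
    y_train,
    X_test=None,
    y_test=None,
    train_ids=None,
    test_ids=None,
    loo_residuals=None,
) -> ADReport:
    """Assemble the Williams-plot data for training (and optionally test) sets.

    Leverages are computed on the autoscaled final-descriptor matrix with
    the training scaling; h* = 3k/n with k = number of model variables.
    Training rows are standardized on their LOO residuals (computed here at
    the fit's A unless passed in), test rows on their prediction residuals;
    both use the training RMSE as denominator.
    """
    Xtr = np.asarray(getattr(X_train, "values", X_train), dtype=float)
    ytr = np.asarray(y_train, dtype=float).ravel()
    n, k = Xtr.shape
    h_star = control_leverage(k, n)
    Xtr_s = fit.scaling.scale_x(Xtr)
    rmse_train = _rmse(ytr, predict(fit, Xtr))

    if loo_residuals is None:
        cv = loo_cv(Xtr, ytr, fit.A)
        loo_residuals = cv.cv_predictions - ytr
    ids_tr = list(train_ids) if train_ids is not None else (
        list(fit.training_ids) if len(fit.training_ids) == n else [str(i) for i in range(n)]
    )
    frames = [pd.DataFrame({
        "id": ids_tr,
        "set": "train",
        "leverage": leverages(Xtr_s, Xtr_s),
        "std_residual": standardized_residuals(loo_residuals, rmse_train),
    })]
    if X_test is not None:
        Xte = np.asarray(getattr(X_test, "values", X_test), dtype=float)
        yte = np.asarray(y_test, dtype=float).ravel()
        res_te = predict(fit, Xte) - yte
        ids_te = list(test_ids) if test_ids is not None else [f"t{i}" for i in range(len(yte))]
        frames.append(pd.DataFrame({
            "id": ids_te,
            "set": "test",
            "leverage": leverages(Xtr_s, fit.scaling.scale_x(Xte)),
            "std_residual": standardized_residuals(res_te, rmse_train),
        }))
    rows = pd.concat(frames, ignore_index=True)
    rows["in_domain"] = rows["leverage"] <= h_star
    rows["outlier"] = rows["std_residual"].abs() > 3.0
    return ADReport(h_star=h_star, rows=rows)
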