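"""Internal and external validation of a PLS QSAR model.

Internal: leave-one-out and leave-many-out cross-validation (q² = 1 −
PRESS/TSS), and y-randomization (refit on shuffled responses, chance
correlation categorised by the mean r² bands).  External: predictive r_p²
(squared Pearson correlation of observed vs predicted), RMSP, the
Golbraikh–Tropsha through-origin criteria, and the |residual| > 3·RMSE
outlier rule.  Every report keeps its per-compound raw material so each
statistic can be recomputed from it.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .pls import PLSFit, fit_pls_nipals, predict, q_squared, r_squared

__all__ = [
    "CVResult",
    "LMOResult",
    "YRandResult",
    "GTReport",
    "ExternalStats",
    "ValidationReport",
    "loo_cv",
    "lmo_cv",
    "y_randomization",
    "external_validation",
    "golbraikh_tropsha",
    "flag_residual_outliers",
]


@dataclass
class CVResult:
    method: str
    q2: float
    rmsv: float
    cv_predictions: np.ndarray


@dataclass
class LMOResult:
    M: int
    repeats: int
    q2_values: list[float]
    mean_q2: float
    ci95_halfwidth: float
    seed: int | None = None


@dataclass
class YRandResult:
    repeats: int
    r2_values: list[float]
    q2_values: list[float]
    mean_r2: float
    mean_q2: float
    r2_ci95: float
    q2_ci95: float
    category: str
    seed: int | None = None


@dataclass
class GTReport:
    R2: float
    R2o: float
    R2o_prime: float
    k: float
    k_prime: float
    ratio1: float
    ratio2: float
    passes: dict


@dataclass
class ExternalStats:
    n_p: int
    r_p2: float
    rmsp: float
    residuals: np.ndarray


@dataclass
class ValidationReport:
    """Bundle of the full validation battery for one model."""

    A: int
    r2: float
    rmse: float
    loo: CVResult
    lmo: list[LMOResult] = field(default_factory=list)
    yrand: YRandResult | None = None
    external: ExternalStats | None = None
    gt: GTReport | None = None
    seed: int | None = None


def _t_halfwidth(values: np.ndarray) -> float:
    """Student-t 95% CI halfwidth: t(0.975, n−1) · SD/√n."""
    n = len(values)
    if n < 2:
        return 0.0
    return float(sps.t.ppf(0.975, n - 1) * np.std(values, ddof=1) / np.sqrt(n))


def loo_cv(X, y, A: int) -> CVResult:
    """Leave-one-out cross-validation at fixed component count ``A``.

    Every fold is autoscaled on its own n−1 rows before fitting; the held
    out compound is predicted in original units.  Deterministic.
    """
    Xv = np.asarray(getattr(X, "values", X), dtype=float)
    yv = np.asarray(y, dtype=float).ravel()
    n = Xv.shape[0]
    if n < 3:
        raise ValueError("LOO needs at least 3 compounds")
    preds = np.zeros(n)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        try:
            fit = fit_pls_nipals(Xv[mask], yv[mask], A)
        except ValueError as exc:
            raise ValueError(f"LOO fold {i} (compound index {i}) failed: {exc}") from exc
        preds[i] = predict(fit, Xv[i : i + 1])[0]
    q2 = q_squared(yv, preds)
    rmsv = float(np.sqrt(np.mean((preds - yv) ** 2)))
    return CVResult(method="LOO", q2=q2, rmsv=rmsv, cv_predictions=preds)


def _lmo_once(Xv, yv, A, M, rng) -> float:
    n = len(yv)
    order = rng.permutation(n)
    preds = np.zeros(n)
    for start in range(0, n, M):
        group = order[start : start + M]
        mask = np.ones(n, dtype=bool)
        mask[group] = False
        fit = fit_pls_nipals(Xv[mask], yv[mask], A)
        preds[group] = predict(fit, Xv[group])
    return q_squared(yv, preds)


def lmo_cv(X, y, A: int, M: int, repeats: int = 10, seed: int | None = None) -> LMOResult:
    """Leave-many-out cross-validation.

    Per repeat the compounds are randomly partitioned into disjoint groups
    of size ≤ M; each group is predicted from a model trained (and rescaled)
    on the rest, giving one q² per repeat computed over all n out-of-fold
    predictions.  M=1 reduces exactly to LOO for every repeat.
    """
    Xv = np.asarray(getattr(X, "values", X), dtype=float)
    yv = np.asarray(y, dtype=float).ravel()
    n = len(yv)
    if not 1 <= M < n:
        raise ValueError(f"M={M} must satisfy 1 <= M < n={n}")
    rng = np.random.default_rng(seed)
    q2s = [_lmo_once(Xv, yv, A, M, rng) for _ in range(repeats)]
    return LMOResult(
        M=M, repeats=repeats, q2_values=q2s,
        mean_q2=float(np.mean(q2s)), ci95_halfwidth=_t_halfwidth(np.array(q2s)),
        seed=seed,
    )


def _yrand_category(mean_r2: float, mean_q2: float) -> str:
    """Chance-correlation category from the mean r²/q² of shuffled refits."""
    if mean_r2 > 0.4:
        return "recognized"
    if mean_r2 > 0.3:
        return "tolerable"
    if mean_r2 > 0.2:
        return "negligible"
    # r2 <= 0.2: no chance correlation requires q2 small as well
    return "none" if mean_q2 < 0.2 else "negligible"


def y_randomization(
    X, y, A: int, repeats: int = 10, seed: int | None = None
) -> YRandResult:
    """Chance-correlation test: shuffle y, refit at the same A, repeat.

    Records training r² and LOO q² of every shuffled refit; the component
    count stays fixed at the real model's A so only the response pairing is
    randomised.
    """
    Xv = np.asarray(getattr(X, "values", X), dtype=float)
    yv = np.asarray(y, dtype=float).ravel()
    if len(yv) < 5:
        raise ValueError("y-randomization needs at least 5 compounds")
    rng = np.random.default_rng(seed)
    r2s, q2s = [], []
    for _ in range(repeats):
        yp = rng.permutation(yv)
        fit = fit_pls_nipals(Xv, yp, A)
        r2s.append(r_squared(yp, predict(fit, Xv)))
        q2s.append(loo_cv(Xv, yp, A).q2)
    mean_r2, mean_q2 = float(np.mean(r2s)), float(np.mean(q2s))
    return YRandResult(
        repeats=repeats, r2_values=r2s, q2_values=q2s,
        mean_r2=mean_r2, mean_q2=mean_q2,
        r2_ci95=_t_halfwidth(np.array(r2s)), q2_ci95=_t_halfwidth(np.array(q2s)),
        category=_yrand_category(mean_r2, mean_q2), seed=seed,
    )


def external_validation(obs_test, pred_test) -> ExternalStats:
    """Predictive statistics on an external test set.

    r_p² is the squared Pearson correlation between observed and predicted;
    RMSP uses denominator n_p; residuals follow the predicted − observed
    sign convention.
    """
    obs = np.asarray(obs_test, dtype=float).ravel()
    pred = np.asarray(pred_test, dtype=float).ravel()
    if obs.shape != pred.shape or obs.size < 3:
        raise ValueError("need equal-length vectors with at least 3 entries")
    if np.all(obs == obs[0]):
        raise ValueError("observed test values are all equal")
    r = float(np.corrcoef(obs, pred)[0, 1])
    return ExternalStats(
        n_p=obs.size,
        r_p2=r * r,
        rmsp=float(np.sqrt(np.mean((pred - obs) ** 2))),
        residuals=pred - obs,
    )


def golbraikh_tropsha(obs, pred, q2: float | None = None) -> GTReport:
    """Golbraikh–Tropsha external-validation criteria.

    Through-origin slopes: k = Σ(y·ŷ)/Σŷ² (observed regressed on predicted)
    and k′ = Σ(y·ŷ)/Σy² (the converse).  R²o is the through-origin
    determination coefficient of predicted vs observed, R′²o the converse;
    ratios are (R² − R²o)/R².  Pass flags use the published bounds:
    q² > 0.5, R² > 0.6, either ratio < 0.1, either slope in [0.85, 1.15].
    """
    y = np.asarray(obs, dtype=float).ravel()
    yh = np.asarray(pred, dtype=float).ravel()
    if y.shape != yh.shape or y.size < 3:
        raise ValueError("need equal-length vectors with at least 3 entries")
    if np.all(y == 0) or np.all(yh == 0):
        raise ValueError("degenerate all-zero vector")
    syy, shh, syh = float(y @ y), float(yh @ yh), float(y @ yh)
    k = syh / shh
    k_prime = syh / syy
    r = float(np.corrcoef(y, yh)[0, 1])
    R2 = r * r
    # through-origin fits: yh ~ y (slope k') and y ~ yh (slope k)
    R2o = 1.0 - float(np.sum((yh - k_prime * y) ** 2)) / float(np.sum((yh - yh.mean()) ** 2))
    R2o_prime = 1.0 - float(np.sum((y - k * yh) ** 2)) / float(np.sum((y - y.mean()) ** 2))
    ratio1 = (R2 - R2o) / R2
    ratio2 = (R2 - R2o_prime) / R2
    passes = {
        "q2_gt_0.5": (q2 is not None and q2 > 0.5),
        "r2_gt_0.6": R2 > 0.6,
        "ratio_lt_0.1": ratio1 < 0.1 or ratio2 < 0.1,
        "slope_in_0.85_1.15": 0.85 <= k <= 1.15 or 0.85 <= k_prime <= 1.15,
    }
    return GTReport(R2=R2, R2o=R2o, R2o_prime=R2o_prime, k=k, k_prime=k_prime,
                    ratio1=ratio1, ratio2=ratio2, passes=passes)


def flag_residual_outliers(residuals, rmse_train: float, factor: float = 3.0) -> list[int]:
    """Indices whose |residual| exceeds ``factor`` times the training RMSE."""
    if rmse_train <= 0:
        raise ValueError("rmse_train must be positive")
    res = np.asarray(residuals, dtype=float).ravel()
    return [int(i) for i in np.nonzero(np.abs(res) > factor * rmse_train)[0]]
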