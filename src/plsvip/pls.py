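"""NIPALS partial least squares regression (PLS1) with autoscaling and VIP.

The model relates a compound-by-descriptor matrix ``X`` to a single activity
vector ``y`` (here the placental clearance index, CI) through ``A`` latent
components.  Both blocks are autoscaled (mean 0, unit sample SD, ``ddof=1``)
before extraction; coefficients are reported back in original units.  The VIP
(variable importance in projection) statistic aggregates each descriptor's
squared component weights, weighted by how much of the y-variance each
component explains; by construction the mean squared VIP equals 1.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ScalingParams",
    "PLSFit",
    "VIPVector",
    "FitMetrics",
    "autoscale",
    "fit_pls_nipals",
    "predict",
    "predict_per_component",
    "loo_q2_per_component",
    "select_n_components",
    "compute_vip",
    "r_squared",
    "rmse",
    "q_squared",
    "f_statistic",
    "fit_to_json",
    "fit_from_json",
]

VIP_WEIGHT_MODES = ("y_contribution", "eq2_literal", "component_ssy")


@dataclass
class ScalingParams:
    """Column means/SDs of X and mean/SD of y used for autoscaling."""

    x_means: np.ndarray
    x_sds: np.ndarray
    y_mean: float
    y_sd: float

    def scale_x(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.x_means) / self.x_sds

    def scale_y(self, y: np.ndarray) -> np.ndarray:
        return (np.asarray(y, dtype=float) - self.y_mean) / self.y_sd

    def unscale_y(self, ys: np.ndarray) -> np.ndarray:
        return np.asarray(ys, dtype=float) * self.y_sd + self.y_mean


@dataclass
class PLSFit:
    """Fitted PLS1 state.

    ``W`` holds unit-norm weight vectors, ``P`` the x-loadings, ``T`` the
    training scores (mutually orthogonal columns), ``q`` the y-loadings, all
    in autoscaled space.  ``coef``/``intercept`` give the equivalent linear
    model in original units.
    """

    A: int
    W: np.ndarray
    P: np.ndarray
    T: np.ndarray
    q: np.ndarray
    coef: np.ndarray
    intercept: float
    scaling: ScalingParams
    descriptor_names: list[str]
    training_ids: list[str] = field(default_factory=list)
    ys_train: np.ndarray | None = None  # autoscaled training response

    @property
    def fitted_values(self) -> np.ndarray:
        """Training-set predictions in original y units."""
        return self.scaling.unscale_y(self.T @ self.q)


@dataclass
class VIPVector:
    names: list[str]
    vip: np.ndarray

    def top(self, k: int) -> list[tuple[str, float]]:
        order = np.argsort(self.vip)[::-1][:k]
        return [(self.names[i], float(self.vip[i])) for i in order]


@dataclass
class FitMetrics:
    r2: float
    rmse: float
    q2: float
    rmsv: float
    f_stat: float


def _as_matrix(X) -> tuple[np.ndarray, list[str], list[str]]:
    """Accept a DataFrame or ndarray; return (values, row ids, column names)."""
    if hasattr(X, "columns"):  # pandas DataFrame
        return (
            np.asarray(X.values, dtype=float),
            [str(i) for i in X.index],
            [str(c) for c in X.columns],
        )
    X = np.asarray(X, dtype=float)
    return X, [str(i) for i in range(X.shape[0])], [f"x{j}" for j in range(X.shape[1])]


def autoscale(X, y) -> tuple[np.ndarray, np.ndarray, ScalingParams]:
    """Mean-center and scale X columns and y to unit sample SD (ddof=1)."""
    Xv, _, _ = _as_matrix(X)
    yv = np.asarray(y, dtype=float).ravel()
    if Xv.shape[0] < 2:
        raise ValueError("autoscaling requires at least 2 rows")
    x_means = Xv.mean(axis=0)
    x_sds = Xv.std(axis=0, ddof=1)
    if np.any(x_sds <= 0):
        bad = int(np.argmin(x_sds))
        raise ValueError(f"zero-variance column at position {bad}; remove constants first")
    y_mean = float(yv.mean())
    y_sd = float(yv.std(ddof=1))
    if y_sd <= 0:
        raise ValueError("response has zero variance")
    params = ScalingParams(x_means=x_means, x_sds=x_sds, y_mean=y_mean, y_sd=y_sd)
    return params.scale_x(Xv), params.scale_y(yv), params


def _nipals_components(Xs: np.ndarray, ys: np.ndarray, A: int):
    """Extract up to ``A`` NIPALS components; stops early when the residual
    X block (or the covariance with the y residual) collapses.

    Returns (W, P, T, q, achieved) with arrays truncated to the achieved
    component count.
    """
    n, m = Xs.shape
    Xr = Xs.copy()
    yr = ys.copy()
    W = np.zeros((m, A))
    P = np.zeros((m, A))
    T = np.zeros((n, A))
    q = np.zeros(A)
    eps = 1e-12 * max(1.0, float(np.abs(Xs).max()))
    achieved = 0
    for a in range(A):
        w = Xr.T @ yr
        wn = np.linalg.norm(w)
        if wn <= eps:
            break
        w /= wn
        t = Xr @ w
        tt = float(t @ t)
        if tt <= eps**2:
            break
        qa = float(t @ yr) / tt
        p = (Xr.T @ t) / tt
        Xr -= np.outer(t, p)
        yr = yr - qa * t
        W[:, a], P[:, a], T[:, a], q[a] = w, p, t, qa
        achieved = a + 1
    return W[:, :achieved], P[:, :achieved], T[:, :achieved], q[:achieved], achieved


def fit_pls_nipals(X, y, A: int) -> PLSFit:
    """Fit a single-response PLS model with ``A`` components by NIPALS.

    ``X``/``y`` are raw (unscaled); autoscaling is applied internally and the
    parameters stored on the fit.  For one response the NIPALS inner loop
    converges in a single pass (the weight vector is X'y normalised), so the
    algorithm is deterministic; X and y are deflated after each component.

    Raises ``ValueError`` if the residual X block collapses before ``A``
    components, naming the achievable rank.
    """
    Xv, ids, names = _as_matrix(X)
    n, m = Xv.shape
    if not 1 <= A <= min(m, n - 1):
        raise ValueError(f"A={A} outside 1..min(m={m}, n-1={n - 1})")
    Xs, ys, scaling = autoscale(Xv, y)
    W, P, T, q, achieved = _nipals_components(Xs, ys, A)
    if achieved < A:
        raise ValueError(
            f"X residual collapsed after {achieved} components; achievable rank is {achieved}"
        )

    # regression vector in autoscaled space: B = W (P'W)^-1 q
    B = W @ np.linalg.solve(P.T @ W, q)
    coef = B * scaling.y_sd / scaling.x_sds
    intercept = scaling.y_mean - float(scaling.x_means @ coef)
    return PLSFit(
        A=A, W=W, P=P, T=T, q=q, coef=coef, intercept=intercept,
        scaling=scaling, descriptor_names=names, training_ids=ids, ys_train=ys,
    )


def _check_columns(fit: PLSFit, X_new) -> np.ndarray:
    Xv, _, names = _as_matrix(X_new)
    if hasattr(X_new, "columns") and names != fit.descriptor_names:
        raise ValueError("descriptor columns of X_new do not match the fitted model")
    if Xv.shape[1] != len(fit.descriptor_names):
        raise ValueError(
            f"expected {len(fit.descriptor_names)} descriptor columns, got {Xv.shape[1]}"
        )
    return Xv


def predict(fit: PLSFit, X_new) -> np.ndarray:
    """Predict activities for new compounds, in original y units."""
    Xv = _check_columns(fit, X_new)
    return Xv @ fit.coef + fit.intercept


def predict_per_component(fit: PLSFit, X_new) -> np.ndarray:
    """Predictions using 1..A components: array of shape (n_new, A).

    Column ``a-1`` is the prediction of the truncated a-component model;
    column ``A-1`` equals :func:`predict`.  Scores of a new row are obtained
    by the same sequential deflation used in training.
    """
    Xv = _check_columns(fit, X_new)
    Xr = fit.scaling.scale_x(Xv)
    out = np.zeros((Xv.shape[0], fit.A))
    acc = np.zeros(Xv.shape[0])
    for a in range(fit.A):
        t = Xr @ fit.W[:, a]
        acc = acc + fit.q[a] * t
        Xr = Xr - np.outer(t, fit.P[:, a])
        out[:, a] = acc
    return fit.scaling.unscale_y(out)


def loo_q2_per_component(X, y, A_max: int) -> np.ndarray:
    """Leave-one-out q² for component counts 1..A_max (one fold refit each).

    Each fold is rescaled on its own n−1 rows; q² follows the PRESS form
    with the full-set mean as reference.  If some fold's X block collapses
    before A_max components, the result is truncated to the component count
    every fold achieves (predictions beyond a fold's rank are undefined).
    """
    Xv, _, _ = _as_matrix(X)
    yv = np.asarray(y, dtype=float).ravel()
    n = Xv.shape[0]
    if n < 3:
        raise ValueError("LOO needs at least 3 rows")
    A_max = min(A_max, Xv.shape[1], n - 2)
    preds = np.zeros((n, A_max))
    common = A_max
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        Xs, ys, scaling = autoscale(Xv[mask], yv[mask])
        W, P, T, q, achieved = _nipals_components(Xs, ys, A_max)
        common = min(common, achieved)
        if achieved == 0:
            raise ValueError(f"LOO fold {i}: no component extractable")
        xr = scaling.scale_x(Xv[i : i + 1])[0]
        acc = 0.0
        for a in range(achieved):
            t = float(xr @ W[:, a])
            acc += q[a] * t
            xr = xr - t * P[:, a]
            preds[i, a] = acc
        preds[i, achieved:] = acc  # rank exhausted: prediction saturates
    tss = float(np.sum((yv - yv.mean()) ** 2))
    press = np.sum((preds[:, :common] - yv[:, None]) ** 2, axis=0)
    return 1.0 - press / tss


def select_n_components(X, y, A_max: int | None = None) -> int:
    """Pick the component count maximising LOO q²; ties go to the smaller A."""
    Xv, _, _ = _as_matrix(X)
    n, m = Xv.shape
    if A_max is None:
        A_max = min(10, m, n - 1)
    if A_max < 1:
        raise ValueError("A_max must be >= 1")
    q2s = loo_q2_per_component(Xv, y, A_max)
    return int(np.argmax(q2s)) + 1  # argmax returns first (smallest A) on ties


def compute_vip(fit: PLSFit, ys: np.ndarray | None = None,
                weight: str = "y_contribution") -> VIPVector:
    """VIP scores for every descriptor of a fitted model.

    VIP_j = sqrt( m * Σ_a w_ja² s_a / Σ_a s_a ), where s_a weights component
    a by its explained y-variance.  ``weight`` selects how s_a is computed:

    - ``y_contribution`` (default): s_a = max(0, 1 − Σ(y_i − t_ia q_a)²/Σy_i²)
      on the autoscaled response — the share of y-variance the a-th
      component's y-contribution accounts for;
    - ``eq2_literal``: the same form with the raw score t_ia in place of
      t_ia q_a (clamped at 0);
    - ``component_ssy``: the classical q_a²·t_a't_a sum-of-squares weighting.

    Because every W column has unit norm, Σ_j VIP_j² = m under any
    non-negative weighting.
    """
    if weight not in VIP_WEIGHT_MODES:
        raise ValueError(f"weight must be one of {VIP_WEIGHT_MODES}")
    if ys is None:
        ys = fit.ys_train
    if ys is None:
        raise ValueError("autoscaled training response required for VIP")
    ys = np.asarray(ys, dtype=float).ravel()
    tss = float(np.sum((ys - ys.mean()) ** 2))
    s = np.zeros(fit.A)
    for a in range(fit.A):
        if weight == "component_ssy":
            s[a] = fit.q[a] ** 2 * float(fit.T[:, a] @ fit.T[:, a])
        else:
            contrib = fit.T[:, a] * fit.q[a] if weight == "y_contribution" else fit.T[:, a]
            s[a] = max(0.0, 1.0 - float(np.sum((ys - contrib) ** 2)) / tss)
    total = s.sum()
    if total <= 0:
        raise ValueError("all component weights are zero; degenerate fit")
    m = fit.W.shape[0]
    vip = np.sqrt(m * (fit.W**2 @ s) / total)
    return VIPVector(names=list(fit.descriptor_names), vip=vip)


# ---------------------------------------------------------------- metrics

def _check_pair(obs, calc) -> tuple[np.ndarray, np.ndarray]:
    obs = np.asarray(obs, dtype=float).ravel()
    calc = np.asarray(calc, dtype=float).ravel()
    if obs.shape != calc.shape or obs.size < 3:
        raise ValueError("need equal-length vectors with at least 3 entries")
    return obs, calc


def r_squared(obs, calc) -> float:
    """Determination coefficient 1 − RSS/TSS of calculated vs observed."""
    obs, calc = _check_pair(obs, calc)
    tss = float(np.sum((obs - obs.mean()) ** 2))
    if tss <= 0:
        raise ValueError("observed values are all equal; r² undefined")
    return 1.0 - float(np.sum((calc - obs) ** 2)) / tss


def rmse(obs, calc) -> float:
    """Root-mean-square error with denominator n."""
    obs, calc = _check_pair(obs, calc)
    return float(np.sqrt(np.mean((calc - obs) ** 2)))


def q_squared(obs, cvpred) -> float:
    """Cross-validated q² = 1 − PRESS/TSS over out-of-fold predictions."""
    return r_squared(obs, cvpred)


def f_statistic(r2: float, n: int, A: int) -> float:
    """F = (r²/A) / ((1−r²)/(n−A−1)) for a model with A latent variables."""
    if not 0 <= r2 < 1:
        raise ValueError("r2 must lie in [0, 1)")
    if n - A - 1 <= 0:
        raise ValueError("n must exceed A + 1")
    return (r2 / A) / ((1.0 - r2) / (n - A - 1))


# ---------------------------------------------------------------- serialization

def fit_to_json(fit: PLSFit) -> str:
    """Serialise a fitted model to a JSON document (lossless round trip)."""
    doc = {
        "A": fit.A,
        "W": fit.W.tolist(),
        "P": fit.P.tolist(),
        "T": fit.T.tolist(),
        "q": fit.q.tolist(),
        "coef": fit.coef.tolist(),
        "intercept": fit.intercept,
        "scaling": {
            "x_means": fit.scaling.x_means.tolist(),
            "x_sds": fit.scaling.x_sds.tolist(),
            "y_mean": fit.scaling.y_mean,
            "y_sd": fit.scaling.y_sd,
        },
        "descriptor_names": fit.descriptor_names,
        "training_ids": fit.training_ids,
        "ys_train": None if fit.ys_train is None else fit.ys_train.tolist(),
    }
    return json.dumps(doc)


def fit_from_json(doc: str) -> PLSFit:
    d = json.loads(doc)
    sc = d["scaling"]
    return PLSFit(
        A=int(d["A"]),
        W=np.array(d["W"], dtype=float),
        P=np.array(d["P"], dtype=float),
        T=np.array(d["T"], dtype=float),
        q=np.array(d["q"], dtype=float),
        coef=np.array(d["coef"], dtype=float),
        intercept=float(d["intercept"]),
        scaling=ScalingParams(
            x_means=np.array(sc["x_means"], dtype=float),
            x_sds=np.array(sc["x_sds"], dtype=float),
            y_mean=float(sc["y_mean"]),
            y_sd=float(sc["y_sd"]),
        ),
        descriptor_names=list(d["descriptor_names"]),
        training_ids=list(d["training_ids"]),
        ys_train=None if d["ys_train"] is None else np.array(d["ys_train"], dtype=float),
    )
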