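"""Internal and external validation statistics for MLR QSAR models.

Implements the full battery a QSAR practitioner reports for a regression
model: fit statistics, closed-form leave-one-out cross-validation
(PRESS via the hat diagonal, identical to explicit refitting), response
scrambling, the external predictivity family Q2_F1/F2/F3, Lin's concordance
correlation coefficient, the rm-squared metrics, the eigenvalue-based
multivariate correlation index Kxx / delta-K, and the leverage-based
applicability domain (Williams plot data with the h* = 3p'/n warning
leverage).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .models import DescriptorMLR, _as_matrix, _ols_core

__all__ = [
    "q2_loo",
    "loo_predictions",
    "ccc",
    "external_metrics",
    "r2m_metrics",
    "k_correlation",
    "y_scramble",
    "applicability_domain",
    "WilliamsData",
    "ValidationReport",
    "build_validation_report",
]


def loo_predictions(X, y) -> np.ndarray:
    """Leave-one-out predictions from the closed-form hat identity.

    For OLS, deleting observation i changes its prediction by
    e_i h_ii / (1 - h_ii), so the LOO residual is e_i / (1 - h_ii); no
    refitting is needed.
    """
    X, _ = _as_matrix(X)
    y = np.asarray(y, dtype=float).ravel()
    _, resid, hat = _ols_core(X, y)
    if np.any(1.0 - hat <= 1e-12):
        raise ValueError("degenerate leverage (h_ii = 1): LOO undefined")
    return y - resid / (1.0 - hat)


def q2_loo(X, y) -> float:
    """Leave-one-out cross-validated explained variance, 1 - PRESS/TSS."""
    y = np.asarray(y, dtype=float).ravel()
    press = float(np.sum((y - loo_predictions(X, y)) ** 2))
    tss = float(np.sum((y - y.mean()) ** 2))
    return 1.0 - press / tss


def ccc(y_obs, y_pred) -> float:
    """Lin's concordance correlation coefficient (agreement with identity)."""
    x = np.asarray(y_obs, dtype=float).ravel()
    y = np.asarray(y_pred, dtype=float).ravel()
    sxy = np.mean((x - x.mean()) * (y - y.mean()))
    return float(
        2 * sxy / (x.var() + y.var() + (x.mean() - y.mean()) ** 2)
    )


def _rmse(e: np.ndarray) -> float:
    return float(np.sqrt(np.mean(e**2)))


def _r2_pearson(a: np.ndarray, b: np.ndarray) -> float:
    if a.std() == 0 or b.std() == 0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1] ** 2)


def external_metrics(
    model: DescriptorMLR, X_ext, y_ext, y_train
) -> dict[str, float]:
    """External-set predictivity statistics.

    Q2_F1 scales the external residual sum by deviations of the external
    responses from the *training* mean, Q2_F2 from the external mean, and
    Q2_F3 compares per-observation mean squared errors against the training
    variance. Q2_F1 >= Q2_F2 always, since the training-mean denominator can
    only be larger.
    """
    y_ext = np.asarray(y_ext, dtype=float).ravel()
    y_train = np.asarray(y_train, dtype=float).ravel()
    if len(y_ext) == 0:
        raise ValueError("external set is empty")
    y_hat = model.predict(X_ext)
    press = float(np.sum((y_ext - y_hat) ** 2))
    denom_f2 = float(np.sum((y_ext - y_ext.mean()) ** 2))
    out = {
        "RMSE_ext": _rmse(y_ext - y_hat),
        "MAE_ext": float(np.mean(np.abs(y_ext - y_hat))),
        "R2_ext": _r2_pearson(y_ext, y_hat),
        "CCC_ext": ccc(y_ext, y_hat),
        "Q2_F1": 1.0 - press / float(np.sum((y_ext - y_train.mean()) ** 2)),
        "Q2_F2": (1.0 - press / denom_f2) if denom_f2 > 0 else np.nan,
        "Q2_F3": 1.0
        - (press / len(y_ext))
        / (float(np.sum((y_train - y_train.mean()) ** 2)) / len(y_train)),
    }
    return out


def _r2m_directional(y: np.ndarray, x: np.ndarray) -> float:
    """rm2 for one direction: regress y on x with and without intercept."""
    r2 = _r2_pearson(y, x)
    k = float(np.sum(x * y) / np.sum(x**2))  # slope through the origin
    tss = float(np.sum((y - y.mean()) ** 2))
    r0_2 = 1.0 - float(np.sum((y - k * x) ** 2)) / tss
    return r2 * (1.0 - np.sqrt(max(r2 - r0_2, 0.0)))


def r2m_metrics(y_obs, y_pred) -> tuple[float, float]:
    """(average, absolute difference) of the two directional rm2 values."""
    y_obs = np.asarray(y_obs, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    if len(y_obs) < 3:
        raise ValueError("rm2 needs at least 3 points")
    if y_obs.std() == 0 or y_pred.std() == 0:
        raise ValueError("rm2 undefined for zero-variance input")
    a = _r2m_directional(y_obs, y_pred)
    b = _r2m_directional(y_pred, y_obs)
    return (a + b) / 2.0, abs(a - b)


def k_correlation(X, y=None) -> float:
    """Multivariate correlation index from correlation-matrix eigenvalues.

    K = sum_j |lambda_j / sum(lambda) - 1/p| / (2 (p - 1) / p), which is 0
    for mutually orthogonal columns and 1 for complete collinearity. With
    ``y`` given, the response is appended as an extra column (Kxy).
    """
    X, _ = _as_matrix(X)
    if y is not None:
        X = np.column_stack([X, np.asarray(y, dtype=float).ravel()])
    p = X.shape[1]
    if p < 2:
        raise ValueError("K needs at least 2 columns")
    if np.any(X.std(axis=0) == 0):
        raise ValueError("K undefined with a constant column")
    lam = np.linalg.eigvalsh(np.corrcoef(X, rowvar=False))
    lam = np.clip(lam, 0.0, None)
    return float(np.sum(np.abs(lam / lam.sum() - 1.0 / p)) / (2.0 * (p - 1) / p))


def y_scramble(
    X, y, n_iter: int = 500, seed: int = 0
) -> dict[str, float]:
    """Response-permutation (Y-randomization) robustness test.

    Refits the model on ``n_iter`` seeded permutations of y and returns the
    mean R2 and mean Q2_LOO across permutations (with standard errors). For
    a real model both means should stay well below the unscrambled values.
    """
    if n_iter < 2:
        raise ValueError("n_iter must be >= 2")
    X, _ = _as_matrix(X)
    y = np.asarray(y, dtype=float).ravel()
    rng = np.random.default_rng(seed)
    tss = float(np.sum((y - y.mean()) ** 2))
    r2s = np.empty(n_iter)
    q2s = np.empty(n_iter)
    for i in range(n_iter):
        yp = rng.permutation(y)
        _, resid, hat = _ols_core(X, yp)
        r2s[i] = 1.0 - float(np.sum(resid**2)) / tss
        q2s[i] = 1.0 - float(np.sum((resid / (1.0 - hat)) ** 2)) / tss
    return {
        "R2_scr_mean": float(r2s.mean()),
        "R2_scr_se": float(r2s.std(ddof=1) / np.sqrt(n_iter)),
        "Q2_scr_mean": float(q2s.mean()),
        "Q2_scr_se": float(q2s.std(ddof=1) / np.sqrt(n_iter)),
    }


def _plain(value):
    """numpy scalar -> builtin, for JSON export."""
    return value.item() if hasattr(value, "item") else value


@dataclass
class WilliamsData:
    """Per-compound applicability-domain data (Williams plot)."""

    ids: list
    leverage: np.ndarray
    std_residual: np.ndarray
    h_star: float
    outliers: list = field(default_factory=list)  # |std residual| > 2
    out_of_domain: list = field(default_factory=list)  # leverage > h*


def applicability_domain(
    model: DescriptorMLR, X_all, y_all, ids=None
) -> WilliamsData:
    """Leverages and standardized residuals against a fitted model.

    Leverage of a point x is x'^T (X^T X)^-1 x' with x' intercept-augmented
    and X the training design; the warning leverage is h* = 3 p'/n. The
    standardized residual uses the training residual standard deviation s.
    """
    X_all, _ = _as_matrix(X_all)
    y_all = np.asarray(y_all, dtype=float).ravel()
    if ids is None:
        ids = list(range(len(y_all)))
    Xt = np.column_stack([np.ones(model.n_train_), model.X_train_])
    xtx = Xt.T @ Xt
    try:
        xtx_inv = np.linalg.inv(xtx)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError("singular X'X: leverage undefined") from err
    Xa = np.column_stack([np.ones(X_all.shape[0]), X_all])
    lev = np.einsum("ij,jk,ik->i", Xa, xtx_inv, Xa)
    resid = y_all - model.predict(X_all)
    std_resid = resid / model.s_
    p_prime = len(model.coef_) + 1
    h_star = 3.0 * p_prime / model.n_train_
    return WilliamsData(
        ids=list(ids),
        leverage=lev,
        std_residual=std_resid,
        h_star=float(h_star),
        outliers=[i for i, r in zip(ids, std_resid) if abs(r) > 2],
        out_of_domain=[i for i, h in zip(ids, lev) if h > h_star],
    )


@dataclass
class ValidationReport:
    """The full statistic set for one model, training set and test set."""

    stats: dict[str, float]
    williams: WilliamsData

    def to_dict(self) -> dict:
        return {
            "stats": {k: (None if v is None or not np.isfinite(v) else float(v))
                      for k, v in self.stats.items()},
            "williams": {
                "h_star": self.williams.h_star,
                "ids": [_plain(i) for i in self.williams.ids],
                "leverage": [float(v) for v in self.williams.leverage],
                "std_residual": [float(v) for v in self.williams.std_residual],
                "outliers": [_plain(i) for i in self.williams.outliers],
                "out_of_domain": [_plain(i) for i in self.williams.out_of_domain],
            },
        }


def build_validation_report(
    model: DescriptorMLR,
    X_train,
    y_train,
    X_ext,
    y_ext,
    ids_train=None,
    ids_ext=None,
    n_scramble: int = 500,
    seed: int = 0,
) -> ValidationReport:
    """Assemble every reported statistic for a fitted model."""
    X_train_m, _ = _as_matrix(X_train)
    y_train = np.asarray(y_train, dtype=float).ravel()
    y_ext_arr = np.asarray(y_ext, dtype=float).ravel()
    y_loo = loo_predictions(X_train_m, y_train)
    y_fit = model.predict(X_train_m)
    stats: dict[str, float] = {
        "n_train": float(model.n_train_),
        "n_ext": float(len(y_ext_arr)),
        "R2": model.r2_,
        "R2_adj": model.r2_adj_,
        "s": model.s_,
        "F": model.f_,
        "Kxx": k_correlation(X_train_m),
        "Kxy": k_correlation(X_train_m, y_train),
        "RMSE_tr": _rmse(y_train - y_fit),
        "MAE_tr": float(np.mean(np.abs(y_train - y_fit))),
        "CCC_tr": ccc(y_train, y_fit),
        "Q2_LOO": q2_loo(X_train_m, y_train),
        "RMSE_cv": _rmse(y_train - y_loo),
        "MAE_cv": float(np.mean(np.abs(y_train - y_loo))),
        "CCC_cv": ccc(y_train, y_loo),
    }
    stats["delta_K"] = stats["Kxy"] - stats["Kxx"]
    scr = y_scramble(X_train_m, y_train, n_iter=n_scramble, seed=seed)
    stats["R2_Yscr"] = scr["R2_scr_mean"]
    stats["Q2_Yscr"] = scr["Q2_scr_mean"]
    stats.update(external_metrics(model, X_ext, y_ext_arr, y_train))
    r2m_avg, r2m_diff = r2m_metrics(y_train, y_loo)
    stats["r2m_average"] = r2m_avg
    stats["r2m_difference"] = r2m_diff
    ids_all = list(ids_train or range(len(y_train))) + list(
        ids_ext or range(len(y_train), len(y_train) + len(y_ext_arr))
    )
    X_ext_m, _ = _as_matrix(X_ext)
    williams = applicability_domain(
        model,
        np.vstack([X_train_m, X_ext_m]),
        np.concatenate([y_train, y_ext_arr]),
        ids=ids_all,
    )
    return ValidationReport(stats=stats, williams=williams)
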