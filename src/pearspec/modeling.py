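"""Regression models and evaluation metrics for SPAD estimation.

Two model families are supported on the selected sensitive bands:

* ``two_band_ols`` — the classical two-wavelength affine model
  ``y = b0 + b1*x_l1 + b2*x_l2`` fitted by ordinary least squares;
* ``pls`` — partial least squares (PLS1, NIPALS): predictors are projected
  onto components that maximise covariance with SPAD, the coefficient
  vector composed back into an affine predictor. With a single response
  each component's weight vector is closed-form, so no inner iteration is
  needed, and with as many components as the predictor rank PLS reproduces
  the OLS solution exactly.

By default predictors and response are z-standardized on the training
split (coefficients are reported in standardized units, with the constants
stored so predictions are always in SPAD units); ``standardize=False``
fits in raw units.

Model quality is summarised by the coefficient of determination
``R^2 = 1 - SS_res/SS_tot`` and ``RMSE = sqrt(mean((y - yhat)^2))``,
computed separately on the modeling and validation groups.
"""

from __future__ import annotations

import numpy as np

from .datatypes import EvaluationResult, FittedModel, SpectraSet, SplitSpec

__all__ = [
    "split_samples", "fit_two_band", "fit_pls", "r_squared", "rmse",
    "coefficient_of_variation", "spad_summary", "loo_rmse", "select_n_components",
    "evaluate_model",
]

_COLLINEAR_TOL = 1e-10


def _constant_columns(X: np.ndarray) -> np.ndarray:
    """Columns whose variation is at floating-point noise level."""
    scale = np.maximum(np.abs(X).max(axis=0), 1e-30)
    return X.std(axis=0) <= 1e-12 * scale


def split_samples(dataset: SpectraSet | int, spec: SplitSpec) -> SplitSpec:
    """Seeded random modeling/validation assignment without replacement."""
    n = dataset if isinstance(dataset, int) else dataset.n_samples
    if spec.n_train + spec.n_valid != n:
        raise ValueError(
            f"split sizes {spec.n_train}+{spec.n_valid} do not sum to {n} samples"
        )
    rng = np.random.default_rng(spec.seed)
    assignment = np.array(["valid"] * n, dtype=object)
    assignment[rng.permutation(n)[: spec.n_train]] = "train"
    return SplitSpec(spec.n_train, spec.n_valid, spec.seed, assignment)


def _standardize(X: np.ndarray, y: np.ndarray, standardize: bool):
    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    if standardize:
        x_scale = X.std(axis=0, ddof=1)
        x_scale = np.where(_constant_columns(X), 1.0, x_scale)
        y_sd = float(y.std(ddof=1))
        y_scale = y_sd if y_sd > 1e-12 * max(abs(y).max(), 1e-30) else 1.0
    else:
        # center only; folding means into the intercept keeps raw units
        x_scale = np.ones(X.shape[1])
        y_scale = 1.0
    Z = (X - x_mean) / x_scale
    w = (y - y_mean) / y_scale
    return Z, w, x_mean, x_scale, y_mean, y_scale


def fit_two_band(X: np.ndarray, y: np.ndarray, bands_nm,
                 transform_tag: str = "R", standardize: bool = True) -> FittedModel:
    """OLS fit of the two-wavelength affine model on selected band values."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    bands_nm = np.asarray(bands_nm, dtype=float)
    if X.ndim != 2 or X.shape[1] != 2 or bands_nm.size != 2:
        raise ValueError("fit_two_band expects exactly 2 predictor bands")
    if X.shape[0] != y.size or X.shape[0] < 3:
        raise ValueError("need >= 3 aligned training samples")
    flat = np.nonzero(_constant_columns(X))[0]
    if flat.size:
        raise ValueError(
            f"predictor band(s) {bands_nm[flat].tolist()} nm are constant across samples"
        )
    rho = np.corrcoef(X[:, 0], X[:, 1])[0, 1]
    if abs(rho) >= 1.0 - _COLLINEAR_TOL:
        raise ValueError(
            f"bands {bands_nm.tolist()} nm are collinear (|r| = {abs(rho):.2e} from 1); "
            "re-select bands or use PLS"
        )
    Z, w, x_mean, x_scale, y_mean, y_scale = _standardize(X, y, standardize)
    design = np.column_stack([np.ones(Z.shape[0]), Z])
    beta, *_ = np.linalg.lstsq(design, w, rcond=None)
    intercept, coef = float(beta[0]), beta[1:]
    if not standardize:
        # fold the internal centering back so coefficients act on raw values
        intercept, x_mean, y_mean = intercept + y_mean - float(x_mean @ coef), 0.0 * x_mean, 0.0
    return FittedModel(
        transform_tag=transform_tag, bands_nm=bands_nm,
        intercept=intercept, coefficients=coef,
        method="two_band_ols", standardized=standardize,
        x_mean=x_mean, x_scale=x_scale, y_mean=y_mean, y_scale=y_scale,
    )


def fit_pls(X: np.ndarray, y: np.ndarray, n_components: int, bands_nm=None,
            transform_tag: str = "R", standardize: bool = True) -> FittedModel:
    """NIPALS PLS1 regression on the selected band values.

    Centering (and optional scaling) happens internally; the stored
    coefficients act on the standardized predictors with zero intercept,
    and :meth:`FittedModel.predict` restores SPAD units.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or X.shape[0] != y.size:
        raise ValueError("X must be (n_samples, n_bands) aligned with y")
    if bands_nm is None:
        bands_nm = np.arange(X.shape[1], dtype=float)
    bands_nm = np.asarray(bands_nm, dtype=float)
    Z, w, x_mean, x_scale, y_mean, y_scale = _standardize(X, y, standardize)
    rank = np.linalg.matrix_rank(Z)
    if not 1 <= n_components <= rank:
        raise ValueError(
            f"n_components={n_components} outside [1, rank={rank}] of the centered predictors"
        )
    Xd, yd = Z.copy(), w.copy()
    W = np.zeros((Z.shape[1], n_components))
    P = np.zeros((Z.shape[1], n_components))
    q = np.zeros(n_components)
    for a in range(n_components):
        wv = Xd.T @ yd
        norm = np.linalg.norm(wv)
        if norm <= 1e-300:
            raise ValueError(
                f"PLS component {a + 1}: predictor/response covariance vanished "
                "(degenerate deflated data)"
            )
        wv = wv / norm
        t = Xd @ wv
        tt = float(t @ t)
        p = Xd.T @ t / tt
        qa = float(yd @ t) / tt
        Xd = Xd - np.outer(t, p)
        yd = yd - qa * t
        W[:, a], P[:, a], q[a] = wv, p, qa
    coef = W @ np.linalg.solve(P.T @ W, q)
    intercept = 0.0  # predictors are centered, so the standardized intercept vanishes
    if not standardize:
        intercept, x_mean, y_mean = y_mean - float(x_mean @ coef), 0.0 * x_mean, 0.0
    return FittedModel(
        transform_tag=transform_tag, bands_nm=bands_nm,
        intercept=intercept, coefficients=coef,
        method="pls", standardized=standardize, n_components=int(n_components),
        x_mean=x_mean, x_scale=x_scale, y_mean=y_mean, y_scale=y_scale,
    )


def r_squared(measured, predicted) -> float:
    """Coefficient of determination, 1 - SS_res/SS_tot.

    Defined against the measured mean; may be negative on a validation set
    and is rejected when the measured values are constant (zero SS_tot).
    """
    m = np.asarray(measured, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if m.shape != p.shape or m.ndim != 1 or m.size < 2:
        raise ValueError("measured and predicted must be equal-length vectors (n >= 2)")
    ss_tot = float(np.sum((m - m.mean()) ** 2))
    if ss_tot <= 0.0:
        raise ValueError("R^2 undefined: measured values are constant")
    ss_res = float(np.sum((m - p) ** 2))
    return 1.0 - ss_res / ss_tot


def rmse(measured, predicted) -> float:
    """Root mean square error, in the units of the response (SPAD)."""
    m = np.asarray(measured, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if m.shape != p.shape or m.ndim != 1 or m.size < 1:
        raise ValueError("measured and predicted must be equal-length non-empty vectors")
    return float(np.sqrt(np.mean((m - p) ** 2)))


def coefficient_of_variation(mean: float, sd: float) -> float:
    """CV as a percentage, 100 * sd / mean."""
    if mean == 0:
        raise ValueError("CV undefined for zero mean")
    return 100.0 * sd / mean


def spad_summary(dataset: SpectraSet) -> dict:
    """Descriptive statistics of the SPAD labels (SD with ddof=1)."""
    if dataset.spad is None:
        raise ValueError("dataset has no SPAD labels")
    s = dataset.spad
    mean = float(s.mean())
    sd = float(s.std(ddof=1))
    return {
        "n": int(s.size),
        "min": float(s.min()),
        "max": float(s.max()),
        "mean": mean,
        "sd": sd,
        "cv_percent": coefficient_of_variation(mean, sd),
    }


def loo_rmse(X: np.ndarray, y: np.ndarray, n_components: int,
             standardize: bool = True) -> float:
    """Leave-one-out RMSE of a PLS fit with ``n_components`` components."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    preds = np.empty(y.size)
    for i in range(y.size):
        keep = np.ones(y.size, dtype=bool)
        keep[i] = False
        model = fit_pls(X[keep], y[keep], n_components, standardize=standardize)
        preds[i] = model.predict(X[i:i + 1])[0]
    return rmse(y, preds)


def select_n_components(X: np.ndarray, y: np.ndarray, max_components: int | None = None,
                        standardize: bool = True) -> int:
    """Pick the PLS component count minimising leave-one-out RMSE (ties: fewer)."""
    X = np.asarray(X, dtype=float)
    Z = X - X.mean(axis=0)
    rank = int(np.linalg.matrix_rank(Z))
    upper = rank if max_components is None else min(rank, max_components)
    if upper < 1:
        raise ValueError("predictors have rank 0; nothing to fit")
    best_k, best = 1, np.inf
    for k in range(1, upper + 1):
        err = loo_rmse(X, y, k, standardize=standardize)
        if err < best - 1e-12:
            best_k, best = k, err
    return best_k


def evaluate_model(model: FittedModel, X_train, y_train, X_valid, y_valid) -> EvaluationResult:
    """R^2/RMSE of a fitted model on the modeling and validation groups."""
    y_train = np.asarray(y_train, dtype=float)
    y_valid = np.asarray(y_valid, dtype=float)
    pt = model.predict(np.asarray(X_train, dtype=float))
    pv = model.predict(np.asarray(X_valid, dtype=float))
    return EvaluationResult(
        r2_train=r_squared(y_train, pt), rmse_train=rmse(y_train, pt),
        r2_valid=r_squared(y_valid, pv), rmse_valid=rmse(y_valid, pv),
        n_train=int(y_train.size), n_valid=int(y_valid.size),
    )
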