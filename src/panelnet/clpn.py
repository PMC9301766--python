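"""Cross-lagged panel network estimation.

Each wave-2 item is regressed on all wave-1 items plus covariates with an L1
(LASSO) penalty; the p node-wise regressions are assembled into a directed
network whose edge weights are standardized regression coefficients.  The
penalty level is chosen per node by K-fold cross-validation; covariates are
confounder adjustments and enter unpenalized by default.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from ._seeds import seed_sequence
from ._solver import cd_gram, cd_gram_path
from .data_model import CLPNetwork, PanelDataset

__all__ = ["FitConfig", "LassoFit", "LambdaSelection", "fit_lasso", "select_lambda", "fit_clpn"]

_CD_TOL = 1e-12
_CD_MAX_ITER = 100_000


@dataclass
class FitConfig:
    """Settings for node-wise penalized regressions.

    lambda_rule:
        ``cv_1se`` (default) — largest penalty within one standard error of
        the CV-minimal mean squared error; parsimonious, controls false
        positive edges under the null.  ``cv_min`` — MSE-minimizing penalty.
        ``fixed`` — use ``fixed_lambda`` for every node.
    penalize_covariates:
        covariates carry penalty factor 0 when False (default).
    standardize:
        z-score items per wave and continuous covariates, so edge weights are
        standardized coefficients.
    """

    lambda_rule: str = "cv_1se"
    n_folds: int = 10
    fixed_lambda: float = 0.0
    penalize_covariates: bool = False
    standardize: bool = True
    fold_seed: int = 0
    n_lambdas: int = 100
    lambda_min_ratio: float = 1e-3

    def __post_init__(self) -> None:
        if self.lambda_rule not in ("cv_min", "cv_1se", "fixed"):
            raise ValueError(f"unknown lambda_rule {self.lambda_rule!r}")
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if self.fixed_lambda < 0:
            raise ValueError("fixed_lambda must be >= 0")


@dataclass
class LassoFit:
    coef: np.ndarray  # on the standardized-predictor scale; exact zeros
    intercept: float
    lam: float
    penalty_factors: np.ndarray
    n_sweeps: int
    dropped: list[int] = field(default_factory=list)  # zero-variance predictors


@dataclass
class LambdaSelection:
    lam: float
    grid: np.ndarray
    mean_mse: np.ndarray
    se_mse: np.ndarray
    rule: str


def _prepare(y, X, penalty_factors, standardize):
    y = np.asarray(y, dtype=float).ravel()
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError(f"shape mismatch: y {y.shape}, X {X.shape}")
    if np.isnan(y).any() or np.isnan(X).any():
        raise ValueError("missing values are not allowed; impute first")
    n, m = X.shape
    if n <= 2:
        raise ValueError("need n > 2 observations")
    w = np.ones(m) if penalty_factors is None else np.asarray(penalty_factors, float)
    if w.shape != (m,) or (w < 0).any():
        raise ValueError("penalty_factors must be m nonnegative reals")
    centers = X.mean(axis=0)
    Xc = X - centers
    sd = Xc.std(axis=0)
    dropped = np.flatnonzero(sd == 0.0).tolist()
    if dropped:
        warnings.warn(
            f"zero-variance predictor(s) {dropped}: coefficients forced to 0",
            stacklevel=3,
        )
    if standardize:
        scale = np.where(sd > 0, sd, 1.0)
        Xs = Xc / scale
    else:
        Xs = Xc
    # zero out dead columns so the solver pins them at exactly zero
    for j in dropped:
        Xs[:, j] = 0.0
    ybar = float(y.mean())
    return y - ybar, Xs, w, ybar, dropped


def fit_lasso(
    y: np.ndarray,
    X: np.ndarray,
    lam: float,
    penalty_factors: Sequence[float] | None = None,
    standardize: bool = True,
) -> LassoFit:
    """Solve one weighted-LASSO regression at penalty ``lam``.

    The objective is ``(1/2n)||y - b0 - X b||^2 + lam * sum_j w_j |b_j|``,
    solved by cyclic coordinate descent on centered (and, by default,
    unit-variance) predictors.  Coefficients are returned on that
    standardized-predictor scale with exact zeros where the soft threshold
    lands.
    """
    if lam < 0:
        raise ValueError("lam must be >= 0")
    yc, Xs, w, ybar, dropped = _prepare(y, X, penalty_factors, standardize)
    n = yc.shape[0]
    XtX = np.ascontiguousarray(Xs.T @ Xs)
    Xty = np.ascontiguousarray(Xs.T @ yc)
    beta = np.zeros(Xs.shape[1])
    sweeps = cd_gram(XtX, Xty, np.ascontiguousarray(w), float(lam), float(n),
                     beta, _CD_TOL, _CD_MAX_ITER)
    return LassoFit(
        coef=beta,
        intercept=ybar,
        lam=float(lam),
        penalty_factors=w,
        n_sweeps=int(sweeps),
        dropped=dropped,
    )


def _lambda_max(yc: np.ndarray, Xs: np.ndarray, w: np.ndarray) -> float:
    """Smallest penalty at which every penalized coefficient is zero.

    Unpenalized columns stay in the model at any penalty, so the entry
    threshold is computed on the residual after projecting y onto them.
    """
    n = yc.shape[0]
    free = np.flatnonzero(w == 0)
    pen = np.flatnonzero(w > 0)
    r = yc
    if free.size:
        coef, *_ = np.linalg.lstsq(Xs[:, free], yc, rcond=None)
        r = yc - Xs[:, free] @ coef
    if pen.size == 0:
        return 1e-8
    lmax = float(np.max(np.abs(Xs[:, pen].T @ r) / (n * w[pen])))
    return max(lmax, 1e-8)


def select_lambda(
    y: np.ndarray,
    X: np.ndarray,
    penalty_factors: Sequence[float] | None = None,
    config: FitConfig | None = None,
    rng: np.random.Generator | None = None,
) -> LambdaSelection:
    """K-fold cross-validation over a log-spaced penalty grid.

    The grid runs from lambda_max (null penalized model) down to
    ``lambda_min_ratio * lambda_max`` in ``n_lambdas`` points.  ``cv_min``
    returns the MSE-minimizing penalty; ``cv_1se`` the largest penalty whose
    mean CV error is within one standard error of the minimum.
    """
    config = config or FitConfig()
    y = np.asarray(y, dtype=float).ravel()
    X = np.asarray(X, dtype=float)
    n, m = X.shape
    K = config.n_folds
    if n < 2 * K:
        raise ValueError("need n >= 2 * n_folds for cross-validation")
    w = np.ones(m) if penalty_factors is None else np.asarray(penalty_factors, float)

    # grid anchored at the full-sample entry threshold
    yc0, Xs0, _, _, _ = _prepare(y, X, w, config.standardize)
    lmax = _lambda_max(yc0, Xs0, w)
    grid = np.geomspace(lmax, lmax * config.lambda_min_ratio, config.n_lambdas)

    if rng is None:
        rng = np.random.default_rng(config.fold_seed)
    perm = rng.permutation(n)
    folds = np.array_split(perm, K)

    mse = np.empty((K, grid.size))
    for k, val_idx in enumerate(folds):
        tr_idx = np.setdiff1d(perm, val_idx, assume_unique=True)
        ytr, Xtr = y[tr_idx], X[tr_idx]
        yval, Xval = y[val_idx], X[val_idx]
        yc, Xs, wv, ybar, _ = _prepare(ytr, Xtr, w, config.standardize)
        # apply the training standardization to the validation block
        centers = Xtr.mean(axis=0)
        sd = (Xtr - centers).std(axis=0)
        scale = np.where(sd > 0, sd, 1.0) if config.standardize else np.ones(Xtr.shape[1])
        Xval_s = (Xval - centers) / scale
        Xval_s[:, sd == 0.0] = 0.0
        XtX = np.ascontiguousarray(Xs.T @ Xs)
        Xty = np.ascontiguousarray(Xs.T @ yc)
        betas = cd_gram_path(XtX, Xty, np.ascontiguousarray(wv),
                             np.ascontiguousarray(grid), float(len(tr_idx)),
                             1e-9, _CD_MAX_ITER)
        pred = Xval_s @ betas.T + ybar
        mse[k] = ((yval[:, None] - pred) ** 2).mean(axis=0)

    mean_mse = mse.mean(axis=0)
    se_mse = mse.std(axis=0, ddof=1) / np.sqrt(K)
    i_min = int(np.argmin(mean_mse))
    if config.lambda_rule == "cv_min":
        lam = float(grid[i_min])
    else:  # cv_1se: grid is descending, first qualifying index = largest lambda
        cutoff = mean_mse[i_min] + se_mse[i_min]
        lam = float(grid[int(np.argmax(mean_mse <= cutoff))])
    return LambdaSelection(lam=lam, grid=grid, mean_mse=mean_mse,
                           se_mse=se_mse, rule=config.lambda_rule)


def _standardized_blocks(data: PanelDataset, standardize: bool):
    """Z-score items per wave and continuous covariates; binaries untouched."""
    C, cov_names, cov_kinds = data.expand_covariates()

    def zscore(M):
        mu = M.mean(axis=0)
        sd = M.std(axis=0)
        sd = np.where(sd > 0, sd, 1.0)
        return (M - mu) / sd, mu, sd

    if standardize:
        X1z, mu1, sd1 = zscore(data.X1)
        X2z, mu2, sd2 = zscore(data.X2)
        Cz = C.copy()
        for j, kind in enumerate(cov_kinds):
            if kind == "continuous":
                col = C[:, j]
                sd = col.std()
                Cz[:, j] = (col - col.mean()) / (sd if sd > 0 else 1.0)
        std_info = {"mu1": mu1, "sd1": sd1, "mu2": mu2, "sd2": sd2}
    else:
        X1z, X2z, Cz = data.X1, data.X2, C
        std_info = {}
    return X1z, X2z, Cz, cov_names, std_info


def fit_clpn(
    data: PanelDataset,
    config: FitConfig | None = None,
    fixed_lambdas: Sequence[float] | None = None,
) -> CLPNetwork:
    """Estimate the cross-lagged panel network from a completed panel.

    For each item j, item j at wave 2 is regressed on all p wave-1 items plus
    expanded covariates.  Item predictors carry penalty factor 1; covariates
    carry 0 unless ``penalize_covariates``.  Column j of ``B`` is filled from
    the item coefficients of regression j.  ``fixed_lambdas`` (one per node)
    overrides penalty selection — used by the frozen-lambda bootstrap.
    """
    config = config or FitConfig()
    if data.p < 2:
        raise ValueError("need at least 2 items")
    if np.isnan(data.X1).any() or np.isnan(data.X2).any():
        raise ValueError("panel contains missing item scores; impute first")
    X1z, X2z, Cz, cov_names, std_info = _standardized_blocks(data, config.standardize)
    if np.isnan(Cz).any():
        raise ValueError("covariates contain missing values; impute first")

    p = data.p
    c = Cz.shape[1]
    design = np.column_stack([X1z, Cz]) if c else X1z
    w = np.ones(p + c)
    if not config.penalize_covariates:
        w[p:] = 0.0

    net_warnings: list[str] = []
    if data.n <= p + c:
        net_warnings.append(
            f"n={data.n} <= number of predictors {p + c}: estimates rely "
            "entirely on the penalty"
        )

    B = np.zeros((p, p))
    G = np.zeros((c, p))
    intercepts = np.zeros(p)
    lambdas = np.zeros(p)
    for j in range(p):
        yj = X2z[:, j]
        if fixed_lambdas is not None:
            lam = float(fixed_lambdas[j])
        elif config.lambda_rule == "fixed":
            lam = config.fixed_lambda
        else:
            rng = np.random.default_rng(
                seed_sequence(config.fold_seed, f"clpn-node-{j}")
            )
            lam = select_lambda(yj, design, w, config, rng=rng).lam
        fit = fit_lasso(yj, design, lam, w, standardize=False)
        B[:, j] = fit.coef[:p]
        G[:, j] = fit.coef[p:]
        intercepts[j] = fit.intercept
        lambdas[j] = lam

    return CLPNetwork(
        labels=data.item_labels,
        B=B,
        G=G,
        covariate_names=cov_names,
        intercepts=intercepts,
        lambdas=lambdas,
        standardization=std_info,
        n=data.n,
        warnings_=net_warnings,
    )
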