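"""Missing-data diagnostics and imputation.

Two tools applied before network estimation: Little's test of the
missing-completely-at-random hypothesis (a chi-square over missingness
patterns, built on EM estimates of the multivariate-normal mean and
covariance), and an iterative random-forest imputation in the missForest
style, which fills each incomplete column from forests trained on the other
columns and stops when the out-of-iteration change first increases.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor

__all__ = [
    "MCARTestResult",
    "ImputationResult",
    "em_norm",
    "little_mcar_test",
    "random_forest_impute",
]


@dataclass
class MCARTestResult:
    statistic: float
    df: int
    p_value: float
    n_patterns: int
    em_iterations: int
    ridge_stabilized_patterns: int = 0


@dataclass
class ImputationResult:
    completed: np.ndarray
    iterations: int
    convergence_trace: list[dict]
    imputed_cells: list[tuple[int, int]]


# ---------------------------------------------------------------------------
# EM for the multivariate normal with missing data
# ---------------------------------------------------------------------------

def _pattern_groups(mask: np.ndarray) -> dict[tuple[bool, ...], np.ndarray]:
    keys = [tuple(row) for row in mask]
    groups: dict[tuple[bool, ...], list[int]] = {}
    for i, key in enumerate(keys):
        groups.setdefault(key, []).append(i)
    return {k: np.asarray(v) for k, v in groups.items()}


def em_norm(
    X: np.ndarray, max_iter: int = 500, tol: float = 1e-6
) -> tuple[np.ndarray, np.ndarray, int]:
    """ML mean and covariance (denominator n) of a normal model under
    ignorable missingness, by EM grouped over missingness patterns.

    On complete data this reduces in one step to the sample mean and the
    ML (denominator n) covariance.
    """
    X = np.asarray(X, dtype=float)
    n, k = X.shape
    mask = np.isnan(X)
    if mask.all(axis=1).any():
        raise ValueError("rows with no observed values cannot be used")

    mu = np.nanmean(X, axis=0)
    var = np.nanvar(X, axis=0)
    var = np.where(var > 0, var, 1.0)
    Sigma = np.diag(var)

    groups = _pattern_groups(mask)
    it = 0
    for it in range(1, max_iter + 1):
        S1 = np.zeros(k)
        S2 = np.zeros((k, k))
        for key, idx in groups.items():
            miss = np.asarray(key)
            obs = ~miss
            rows = X[idx][:, obs]
            nj = len(idx)
            if not miss.any():
                S1[obs] += rows.sum(axis=0)
                S2[np.ix_(obs, obs)] += rows.T @ rows
                continue
            Soo = Sigma[np.ix_(obs, obs)]
            Som = Sigma[np.ix_(obs, miss)]
            K = np.linalg.solve(Soo, Som)  # obs x miss regression weights
            resid = rows - mu[obs]
            Xm = mu[miss] + resid @ K
            Cmm = Sigma[np.ix_(miss, miss)] - Som.T @ K
            S1[obs] += rows.sum(axis=0)
            S1[miss] += Xm.sum(axis=0)
            S2[np.ix_(obs, obs)] += rows.T @ rows
            S2[np.ix_(obs, miss)] += rows.T @ Xm
            S2[np.ix_(miss, obs)] += Xm.T @ rows
            S2[np.ix_(miss, miss)] += Xm.T @ Xm + nj * Cmm
        mu_new = S1 / n
        Sigma_new = S2 / n - np.outer(mu_new, mu_new)
        delta = max(np.abs(mu_new - mu).max(), np.abs(Sigma_new - Sigma).max())
        mu, Sigma = mu_new, Sigma_new
        if delta < tol:
            break
    return mu, Sigma, it


def little_mcar_test(data: np.ndarray) -> MCARTestResult:
    """Little's chi-square test of missing completely at random.

    Under MCAR the observed-variable means of every missingness pattern
    estimate the same mean vector, so

        d^2 = sum_j n_j (ybar_j - mu_obs(j))' Sigma_obs(j)^{-1} (ybar_j - mu_obs(j))

    is asymptotically chi-square with df = sum_j k_j - k, where k_j counts
    the observed variables of pattern j.  mu and Sigma are the EM (ML)
    estimates under normality.
    """
    X = np.asarray(data, dtype=float)
    if hasattr(data, "to_numpy"):
        X = data.to_numpy(dtype=float)
    n, k = X.shape
    mask = np.isnan(X)
    if not mask.any():
        raise ValueError("test undefined: single complete pattern (no missing data)")
    groups = _pattern_groups(mask)
    if len(groups) < 2:
        raise ValueError("test requires at least 2 distinct missingness patterns")

    mu, Sigma, em_iters = em_norm(X)

    d2 = 0.0
    df = 0
    ridge_flagged = 0
    for key, idx in groups.items():
        obs = ~np.asarray(key)
        kj = int(obs.sum())
        if kj == 0:
            continue
        rows = X[idx][:, obs]
        nj = len(idx)
        diff = rows.mean(axis=0) - mu[obs]
        Soo = Sigma[np.ix_(obs, obs)]
        try:
            contrib = float(nj * diff @ np.linalg.solve(Soo, diff))
        except np.linalg.LinAlgError:
            contrib = float(
                nj * diff @ np.linalg.solve(Soo + 1e-8 * np.eye(kj), diff)
            )
            ridge_flagged += 1
        d2 += contrib
        df += kj
    df -= k
    p_value = float(stats.chi2.sf(d2, df))
    return MCARTestResult(
        statistic=float(d2),
        df=int(df),
        p_value=p_value,
        n_patterns=len(groups),
        em_iterations=em_iters,
        ridge_stabilized_patterns=ridge_flagged,
    )


# ---------------------------------------------------------------------------
# missForest-style imputation
# ---------------------------------------------------------------------------

def _column_change(new: np.ndarray, old: np.ndarray, cells: np.ndarray) -> float:
    num = float(((new - old)[cells] ** 2).sum())
    den = float((new[cells] ** 2).sum())
    return num / den if den > 0 else 0.0


def random_forest_impute(
    data: np.ndarray,
    trees: int = 100,
    max_iter: int = 10,
    seed: int = 0,
    categorical: np.ndarray | None = None,
    scales: list[tuple[float, float] | None] | None = None,
) -> ImputationResult:
    """Iterative random-forest imputation (missForest algorithm).

    Missing cells start at column means (continuous) or modes (categorical
    columns, per the ``categorical`` boolean mask).  Columns are visited in
    ascending missingness order; each incomplete column is refit by a random
    forest on all other columns using originally observed rows, and its
    originally missing rows are replaced by forest predictions.  Iteration
    stops the first time either change statistic (normalized squared change
    for continuous columns, proportion changed for categorical columns)
    increases, and the previous iterate is returned.  Columns with a scale
    range in ``scales`` are rounded and clipped afterwards.
    """
    X = np.asarray(data, dtype=float).copy()
    n, p = X.shape
    mask = np.isnan(X)
    if (mask.all(axis=0)).any():
        raise ValueError("all-missing column cannot be imputed")
    imputed_cells = [(int(r), int(c)) for r, c in zip(*np.where(mask))]
    if not mask.any():
        return ImputationResult(X, 0, [], [])

    cat = np.zeros(p, dtype=bool) if categorical is None else np.asarray(categorical, bool)
    rng = np.random.default_rng(seed)

    # initial fill
    for j in range(p):
        col = X[:, j]
        obs = ~mask[:, j]
        if mask[:, j].any():
            if cat[j]:
                vals, counts = np.unique(col[obs], return_counts=True)
                fill = vals[np.argmax(counts)]
            else:
                fill = col[obs].mean()
            col[mask[:, j]] = fill

    order = np.argsort(mask.sum(axis=0), kind="stable")
    order = [j for j in order if mask[:, j].any()]
    cont_cols = [j for j in order if not cat[j]]
    cat_cols = [j for j in order if cat[j]]

    trace: list[dict] = []
    prev_cont = np.inf
    prev_cat = np.inf
    iterations = 0
    completed = X.copy()
    for _ in range(max_iter):
        new = X.copy()
        for j in order:
            obs = ~mask[:, j]
            others = np.delete(np.arange(p), j)
            model_cls = RandomForestClassifier if cat[j] else RandomForestRegressor
            forest = model_cls(
                n_estimators=trees,
                random_state=int(rng.integers(2**31)),
                n_jobs=1,
            )
            ycol = new[obs, j].astype(int) if cat[j] else new[obs, j]
            forest.fit(new[np.ix_(obs, others)], ycol)
            new[mask[:, j], j] = forest.predict(new[np.ix_(mask[:, j], others)])

        d_cont = 0.0
        if cont_cols:
            d_cont = _column_change(
                new[:, cont_cols], X[:, cont_cols], mask[:, cont_cols]
            )
        d_cat = 0.0
        if cat_cols:
            changed = (new[:, cat_cols] != X[:, cat_cols])[mask[:, cat_cols]]
            d_cat = float(changed.mean()) if changed.size else 0.0
        trace.append({"continuous": d_cont, "categorical": d_cat})

        if (cont_cols and d_cont > prev_cont) or (cat_cols and d_cat > prev_cat):
            completed = X  # change increased: keep the previous iterate
            break
        iterations += 1
        prev_cont, prev_cat = d_cont, d_cat
        X = new
        completed = X

    if scales is not None:
        for j, rng_j in enumerate(scales):
            if rng_j is None:
                continue
            lo, hi = rng_j
            completed[mask[:, j], j] = np.clip(
                np.round(completed[mask[:, j], j]), lo, hi
            )

    # observed cells are untouched by construction; assert the contract
    src = np.asarray(data, dtype=float)
    assert np.array_equal(completed[~mask], src[~mask])
    return ImputationResult(
        completed=completed,
        iterations=iterations,
        convergence_trace=trace,
        imputed_cells=imputed_cells,
    )
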