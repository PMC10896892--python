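"""Statistical primitives used across the pipeline.

Logistic regression (IRLS, with Nagelkerke pseudo-R² — the model-selection
metric for picking each trait's optimal PRS threshold), the
baseline-characteristics tests (pooled-variance t, Yates-corrected chi-square
on 2x2 tables, Mann–Whitney U), Pearson correlation between PRSs, and
genotype principal components.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io_formats import GenotypePanel

__all__ = [
    "LogisticFit",
    "TestResult",
    "logistic_fit",
    "t_test_pooled",
    "chi2_2x2_yates",
    "mann_whitney_u",
    "pearson_corr",
    "genotype_pca",
]


@dataclass
class LogisticFit:
    names: list[str]
    coef: np.ndarray
    se: np.ndarray
    loglik: float
    loglik_null: float
    n: int
    nagelkerke_r2: float
    converged: bool
    separation: bool


@dataclass
class TestResult:
    test_name: str
    statistic: float
    p_value: float
    df: float | None = None


# ---------------------------------------------------------------------------
# logistic regression
# ---------------------------------------------------------------------------


def _bernoulli_loglik(y: np.ndarray, eta: np.ndarray) -> float:
    # numerically safe log-likelihood: -sum log(1 + exp(-(2y-1) eta))
    z = (2 * y - 1) * eta
    return float(-np.sum(np.logaddexp(0.0, -z)))


def logistic_fit(
    y: np.ndarray,
    X: np.ndarray | pd.DataFrame,
    names: list[str] | None = None,
    add_intercept: bool = True,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> LogisticFit:
    """Maximum-likelihood logistic regression via IRLS.

    Converges when the largest absolute score (gradient) component falls
    below ``tol``.  Nagelkerke R² rescales Cox–Snell R² to [0, 1]:
    ``(1 - exp(2(LL0 - LL1)/n)) / (1 - exp(2 LL0 / n))``.  A coefficient
    diverging past 15 on the standardized path flags (quasi-)separation.
    """
    y = np.asarray(y, float).reshape(-1)
    if isinstance(X, pd.DataFrame):
        names = names or list(X.columns)
        X = X.to_numpy(float)
    X = np.atleast_2d(np.asarray(X, float))
    if X.shape[0] != y.size:
        X = X.T
    if names is None:
        names = [f"x{j}" for j in range(X.shape[1])]
    if add_intercept:
        X = np.column_stack([np.ones(y.size), X])
        names = ["intercept"] + list(names)
    n, p = X.shape
    if n <= p:
        raise ValueError(f"n={n} too small for {p} coefficients")
    if y.min() == y.max():
        raise ValueError("outcome contains a single class")

    # standardize non-intercept columns so convergence and the separation
    # threshold are invariant to affine rescaling of the predictors
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    fixed = sd == 0  # intercept and any constant columns
    mean[fixed] = 0.0
    sd[fixed] = 1.0
    if not add_intercept:
        mean[:] = 0.0  # no intercept to absorb centering: scale only
    Z = (X - mean) / sd

    beta_z = np.zeros(p)
    separation = False
    converged = False
    for _ in range(max_iter):
        eta = Z @ beta_z
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        score = Z.T @ (y - mu)
        if np.max(np.abs(score)) < tol:
            converged = True
            break
        ZtWZ = (Z * w[:, None]).T @ Z
        try:
            step = np.linalg.solve(ZtWZ, score)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(ZtWZ, score, rcond=None)[0]
        beta_z = beta_z + step
        if np.max(np.abs(beta_z)) > 15.0:
            separation = True
            break

    # back-transform to the original predictor scale
    beta = beta_z / sd
    if add_intercept:
        beta[0] = beta_z[0] - np.sum((beta_z * mean / sd)[~fixed])
    eta = X @ beta
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = np.clip(mu * (1.0 - mu), 1e-12, None)
    XtWX = (X * w[:, None]).T @ X
    cov = np.linalg.pinv(XtWX)
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))

    ll1 = _bernoulli_loglik(y, eta)
    pbar = y.mean()
    ll0 = float(n * (pbar * np.log(pbar) + (1 - pbar) * np.log(1 - pbar)))
    cs = 1.0 - np.exp(2.0 * (ll0 - ll1) / n)
    cs_max = 1.0 - np.exp(2.0 * ll0 / n)
    r2 = float(np.clip(cs / cs_max, 0.0, 1.0)) if cs_max > 0 else 0.0
    return LogisticFit(
        names=list(names), coef=beta, se=se, loglik=ll1, loglik_null=ll0,
        n=n, nagelkerke_r2=r2, converged=converged, separation=separation,
    )


# ---------------------------------------------------------------------------
# two-group tests
# ---------------------------------------------------------------------------


def t_test_pooled(mean1, sd1=None, n1=None, mean2=None, sd2=None, n2=None) -> TestResult:
    """Two-sided pooled-variance two-sample t-test.

    Accepts either six summary numbers ``(mean1, sd1, n1, mean2, sd2, n2)``
    or two raw vectors ``t_test_pooled(x, y)``.
    """
    if n1 is None and sd1 is not None and mean2 is None:
        x = np.asarray(mean1, float)
        y = np.asarray(sd1, float)
        mean1, sd1, n1 = x.mean(), x.std(ddof=1), x.size
        mean2, sd2, n2 = y.mean(), y.std(ddof=1), y.size
    if min(n1, n2) < 2:
        raise ValueError("each group needs n >= 2")
    if sd1 <= 0 and sd2 <= 0:
        raise ValueError("zero pooled variance")
    res = sps.ttest_ind_from_stats(
        mean1, sd1, n1, mean2, sd2, n2, equal_var=True
    )
    return TestResult("t_test_pooled", float(res.statistic),
                      float(res.pvalue), df=float(n1 + n2 - 2))


def chi2_2x2_yates(a: int, b: int, c: int, d: int) -> TestResult:
    """Continuity-corrected chi-square test on the 2x2 table [[a, b], [c, d]].

    Statistic ``sum(max(|O - E| - 0.5, 0)^2 / E)`` with 1 df.
    """
    table = np.array([[a, b], [c, d]], float)
    if (table < 0).any():
        raise ValueError("negative cell count")
    rows = table.sum(axis=1)
    cols = table.sum(axis=0)
    total = table.sum()
    if (rows == 0).any() or (cols == 0).any():
        raise ValueError("zero margin in 2x2 table")
    expected = np.outer(rows, cols) / total
    stat = float(
        np.sum(np.maximum(np.abs(table - expected) - 0.5, 0.0) ** 2 / expected)
    )
    p = float(sps.chi2.sf(stat, df=1))
    return TestResult("chi2_2x2_yates", stat, p, df=1.0)


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    ranks = sps.rankdata(np.concatenate([x, y]))
    r1 = ranks[: x.size].sum()
    return float(r1 - x.size * (x.size + 1) / 2.0)


def mann_whitney_u(x: np.ndarray, y: np.ndarray, exact_max_n: int = 12) -> TestResult:
    """Two-sided Mann–Whitney U test.

    Exact enumeration over all group assignments when ``n1 + n2`` is at most
    ``exact_max_n``; otherwise the normal approximation with tie-corrected
    variance (identical samples then give p = 1 exactly).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size == 0 or y.size == 0:
        raise ValueError("empty sample")
    n1, n2 = x.size, y.size
    u_obs = _u_statistic(x, y)
    mu = n1 * n2 / 2.0

    if n1 + n2 <= exact_max_n:
        pooled = np.concatenate([x, y])
        dev_obs = abs(u_obs - mu)
        count = 0
        total = 0
        for idx in combinations(range(n1 + n2), n1):
            mask = np.zeros(n1 + n2, bool)
            mask[list(idx)] = True
            u = _u_statistic(pooled[mask], pooled[~mask])
            total += 1
            if abs(u - mu) >= dev_obs - 1e-12:
                count += 1
        return TestResult("mann_whitney_u_exact", u_obs, count / total)

    n = n1 + n2
    _, tie_counts = np.unique(np.concatenate([x, y]), return_counts=True)
    tie_term = np.sum(tie_counts ** 3 - tie_counts) / (n * (n - 1.0))
    var = n1 * n2 / 12.0 * ((n + 1.0) - tie_term)
    if var <= 0:
        return TestResult("mann_whitney_u", u_obs, 1.0)
    z = (u_obs - mu) / np.sqrt(var)
    p = float(min(1.0, 2.0 * sps.norm.sf(abs(z))))
    return TestResult("mann_whitney_u", u_obs, p)


def pearson_corr(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson correlation with two-sided p from the t transform."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size < 3 or x.size != y.size:
        raise ValueError("need two equal-length vectors with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


# ---------------------------------------------------------------------------
# genotype PCA
# ---------------------------------------------------------------------------


def genotype_pca(panel: GenotypePanel, k: int = 10) -> np.ndarray:
    """Top-``k`` principal-component scores of the standardized dosage matrix.

    Columns are centred and scaled to unit variance (constant columns
    dropped); scores are left singular vectors scaled by singular values,
    with a deterministic sign convention (the largest-magnitude variant
    loading of each component is positive).
    """
    X = np.asarray(panel.dosage, float)
    if np.isnan(X).any():
        raise ValueError("PCA requires a complete (QC'd, imputed) matrix")
    n, m = X.shape
    if k > min(n - 1, m):
        raise ValueError(f"k={k} exceeds min(n-1, m)={min(n - 1, m)}")
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    keep = sd > 0
    Z = (X[:, keep] - mean[keep]) / sd[keep]
    if Z.shape[1] < k:
        raise ValueError("too few non-constant variants for requested k")
    U, S, Vt = np.linalg.svd(Z, full_matrices=False)
    scores = U[:, :k] * S[:k]
    for comp in range(k):
        j = np.argmax(np.abs(Vt[comp]))
        if Vt[comp, j] < 0:
            scores[:, comp] = -scores[:, comp]
    return scores
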