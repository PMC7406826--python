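"""Behavioral-level statistics and Monte Carlo power for indirect effects.

The power routine reproduces the confidence-interval-based Monte Carlo
method for a*b: per replication a trivariate-normal sample (X, M, Y) is
drawn from an input correlation matrix, M ~ X and Y ~ X + M are fitted by
least squares, and a Monte Carlo confidence interval for the product a*b
is formed from independent normal draws around the fitted coefficients at
their estimated standard errors. Power is the fraction of replications
whose interval excludes zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = ["pearson", "partial_correlation", "two_sample_t", "PowerSpec", "mc_power_indirect"]


def pearson(u: np.ndarray, v: np.ndarray) -> tuple[float, float]:
    """Product-moment correlation with the two-tailed t-based p-value."""
    u = np.asarray(u, dtype=float).ravel()
    v = np.asarray(v, dtype=float).ravel()
    if u.size != v.size:
        raise ValueError("u and v must have equal length")
    if u.size < 3:
        raise ValueError("need at least 3 observations")
    if u.std() == 0 or v.std() == 0:
        raise ValueError("zero-variance input")
    res = stats.pearsonr(u, v)
    return float(res.statistic), float(res.pvalue)


def partial_correlation(
    u: np.ndarray, v: np.ndarray, cov: np.ndarray | None = None
) -> tuple[float, float]:
    """Correlation of u and v after removing covariates from both.

    Residualises both series on ``[cov, 1]`` by least squares and
    correlates the residuals; the p-value uses a t distribution with
    ``n - q - 2`` degrees of freedom. With no covariates this reduces
    exactly to :func:`pearson` (up to the identical formula).
    """
    u = np.asarray(u, dtype=float).ravel()
    v = np.asarray(v, dtype=float).ravel()
    n = u.size
    if cov is None or np.size(cov) == 0:
        return pearson(u, v)
    cov = np.atleast_2d(np.asarray(cov, dtype=float))
    if cov.shape[0] != n:
        raise ValueError("covariate rows must match series length")
    q = cov.shape[1]
    if n <= q + 2:
        raise ValueError(f"need n > q + 2 (n={n}, q={q})")
    W = np.hstack([cov, np.ones((n, 1))])
    pinvW = np.linalg.pinv(W)
    ru = u - W @ (pinvW @ u)
    rv = v - W @ (pinvW @ v)
    num = float(ru @ rv)
    den = math.sqrt(float(ru @ ru) * float(rv @ rv))
    if den == 0:
        raise ValueError("zero residual variance")
    r = max(-1.0, min(1.0, num / den))
    dof = n - q - 2
    if abs(r) == 1.0:
        return r, 0.0
    t = r * math.sqrt(dof / (1.0 - r * r))
    p = 2.0 * stats.t.sf(abs(t), dof)
    return r, float(p)


def two_sample_t(group1: np.ndarray, group2: np.ndarray) -> tuple[float, float]:
    """Pooled-variance two-sample t test, two-tailed."""
    g1 = np.asarray(group1, dtype=float).ravel()
    g2 = np.asarray(group2, dtype=float).ravel()
    if g1.size < 2 or g2.size < 2:
        raise ValueError("each group needs at least 2 observations")
    if g1.std(ddof=1) == 0 and g2.std(ddof=1) == 0 and g1.mean() == g2.mean():
        return 0.0, 1.0
    res = stats.ttest_ind(g1, g2, equal_var=True)
    return float(res.statistic), float(res.pvalue)


@dataclass
class PowerSpec:
    """Inputs of the Monte Carlo power analysis for an indirect effect.

    ``r_xm, r_my, r_xy`` parameterise the population correlation matrix of
    (X, M, Y); ``sds`` are the marginal standard deviations. Defaults for
    the replication count, Monte Carlo draws and confidence level follow
    the conventional web-tool settings (1000 / 20000 / 0.95).
    """

    r_xm: float
    r_my: float
    r_xy: float
    n: int
    sds: tuple[float, float, float] = (1.0, 1.0, 1.0)
    n_reps: int = 1000
    n_mc_draws: int = 20000
    ci_level: float = 0.95
    se_method: str = "ml"  # "ml" (RSS/n, SEM convention) or "ols" (RSS/df)
    rng_seed: int = 0

    def correlation_matrix(self) -> np.ndarray:
        R = np.array(
            [
                [1.0, self.r_xm, self.r_xy],
                [self.r_xm, 1.0, self.r_my],
                [self.r_xy, self.r_my, 1.0],
            ]
        )
        if np.linalg.eigvalsh(R).min() <= 1e-10:
            raise ValueError(
                f"correlations (r_xm={self.r_xm}, r_my={self.r_my}, r_xy={self.r_xy}) "
                "do not form a positive-definite matrix"
            )
        return R

    def __post_init__(self) -> None:
        if self.n < 5:
            raise ValueError("n must be at least 5")
        if not all(s > 0 for s in self.sds):
            raise ValueError("standard deviations must be positive")
        if not 0 < self.ci_level < 1:
            raise ValueError("ci_level must be in (0, 1)")
        if self.se_method not in ("ml", "ols"):
            raise ValueError("se_method must be 'ml' or 'ols'")
        self.correlation_matrix()  # validate now


@dataclass
class PowerResult:
    power: float
    mc_se: float
    spec: PowerSpec
    n_success: int = 0

    def as_dict(self) -> dict:
        d = {"power": self.power, "mc_se": self.mc_se, "spec": self.spec.__dict__.copy()}
        d["spec"]["sds"] = list(self.spec.sds)
        return d


def mc_power_indirect(spec: PowerSpec) -> PowerResult:
    """Monte Carlo power of the a*b confidence-interval test.

    Per replication: draw ``n`` observations of (X, M, Y) from the
    implied trivariate normal; fit ``M ~ X`` and ``Y ~ X + M``; draw
    ``n_mc_draws`` pairs (a*, b*) from independent normals centred at the
    estimates with the fitted standard errors; form the equal-tail
    ``ci_level`` interval of a* b*; count the replication a success when
    the interval excludes zero. Power is the success fraction, with
    ``mc_se = sqrt(p (1 - p) / n_reps)``.
    """
    rng = np.random.default_rng(spec.rng_seed)
    R = spec.correlation_matrix()
    S = np.diag(spec.sds) @ R @ np.diag(spec.sds)
    L = np.linalg.cholesky(S)
    n, reps = spec.n, spec.n_reps
    lo_q = (1.0 - spec.ci_level) / 2.0
    qs = [lo_q, 1.0 - lo_q]

    data = rng.standard_normal((reps, n, 3)) @ L.T  # columns X, M, Y
    X, M, Y = data[..., 0], data[..., 1], data[..., 2]
    Xc = X - X.mean(axis=1, keepdims=True)
    Mc = M - M.mean(axis=1, keepdims=True)
    Yc = Y - Y.mean(axis=1, keepdims=True)
    sxx = np.einsum("rn,rn->r", Xc, Xc)
    sxm = np.einsum("rn,rn->r", Xc, Mc)
    sxy = np.einsum("rn,rn->r", Xc, Yc)
    smm = np.einsum("rn,rn->r", Mc, Mc)
    smy = np.einsum("rn,rn->r", Mc, Yc)
    syy = np.einsum("rn,rn->r", Yc, Yc)

    # Residual-variance denominators: the structural-equation (ML) convention
    # divides by n, the OLS convention by the residual degrees of freedom.
    df_a, df_b = (n, n) if spec.se_method == "ml" else (n - 2, n - 3)
    # M ~ 1 + X
    a_hat = sxm / sxx
    rss_m = smm - a_hat * sxm
    se_a = np.sqrt(np.maximum(rss_m, 0.0) / df_a / sxx)
    # Y ~ 1 + X + M
    denom = sxx * smm - sxm**2
    b_hat = (sxx * smy - sxm * sxy) / denom
    cp_hat = (smm * sxy - sxm * smy) / denom
    rss_y = np.maximum(syy - cp_hat * sxy - b_hat * smy, 0.0)
    sigma2 = rss_y / df_b
    se_b = np.sqrt(sigma2 * sxx / denom)

    successes = 0
    chunk = max(1, int(2e6 // spec.n_mc_draws))
    for start in range(0, reps, chunk):
        stop = min(start + chunk, reps)
        k = stop - start
        a_star = a_hat[start:stop, None] + se_a[start:stop, None] * rng.standard_normal((k, spec.n_mc_draws))
        b_star = b_hat[start:stop, None] + se_b[start:stop, None] * rng.standard_normal((k, spec.n_mc_draws))
        prod = a_star * b_star
        lo, hi = np.quantile(prod, qs, axis=1)
        successes += int(np.count_nonzero((lo > 0) | (hi < 0)))

    power = successes / reps
    mc_se = math.sqrt(power * (1.0 - power) / reps)
    return PowerResult(power=power, mc_se=mc_se, spec=spec, n_success=successes)
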