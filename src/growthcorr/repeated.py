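"""Repeated-measures benchmark for marked individuals.

When individuals can be identified across occasions, growth
autocorrelation is estimable directly from a random-intercept linear
mixed model on per-step growth increments:

    y[i, j] = mu + b_i + e[i, j],   b_i ~ N(0, var_ind),  e ~ N(0, var_res).

Under the cohort growth model the increment variance components are
var_ind = rho^2 sigma^2 delta^2 and var_res = (1 - rho^2) sigma^2 delta,
so rho^2 = var_ind / (var_ind + delta * var_res). The null rho = 0 (no
individual variance component) is tested with a restricted likelihood
ratio statistic whose boundary-null distribution is obtained by
parametric-bootstrap simulation from the fitted null model.

For the balanced case (every individual measured at every occasion) the
REML estimates and restricted log-likelihoods have the classical one-way
ANOVA closed form, which is what makes a bootstrap with hundreds of null
refits affordable; unbalanced data fall back to statsmodels' MixedLM.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .simulate import CohortSizes

__all__ = ["LmmResult", "fit_lmm", "rlrt_test"]


@dataclass(frozen=True)
class LmmResult:
    """Variance components and derived autocorrelation from the LMM."""

    var_individual: float
    var_residual: float
    rho2_hat: float
    rlrt_stat: float
    p_value: float = np.nan


def _balanced_reml(y: np.ndarray) -> tuple[float, float, float]:
    """Closed-form balanced one-way REML: (var_ind, var_res, RLRT stat).

    ``y`` is (n_individuals, n_steps). The restricted -2 log-likelihood is
    (n-1) log(l1) + n(m-1) log(l2) + SSB/l1 + SSW/l2 (constants dropped)
    with l1 = var_res + m var_ind, l2 = var_res; the ANOVA mean squares
    maximize it, truncated at var_ind = 0.
    """
    n, m = y.shape
    gm = y.mean()
    row_means = y.mean(axis=1)
    ssb = m * float(np.sum((row_means - gm) ** 2))
    ssw = float(np.sum((y - row_means[:, None]) ** 2))
    msb = ssb / (n - 1)
    msw = ssw / (n * (m - 1))

    def neg2_rll(l1, l2):
        return (n - 1) * np.log(l1) + n * (m - 1) * np.log(l2) + ssb / l1 + ssw / l2

    if msw == 0.0:
        # degenerate rho = 1 limit: no within-individual variance at all
        return msb / m, 0.0, np.inf
    if msb > msw:
        var_res, var_ind = msw, (msb - msw) / m
        alt = neg2_rll(msb, msw)
    else:
        pooled = (ssb + ssw) / (n * m - 1)
        var_res, var_ind = pooled, 0.0
        alt = neg2_rll(pooled, pooled)
    pooled = (ssb + ssw) / (n * m - 1)
    null = neg2_rll(pooled, pooled)
    stat = max(null - alt, 0.0)
    return var_ind, var_res, stat


def _balanced_reml_batch(y: np.ndarray) -> np.ndarray:
    """Vectorized RLRT statistics for a batch of (sims, n, m) datasets."""
    _, n, m = y.shape
    row_means = y.mean(axis=2)
    gm = y.mean(axis=(1, 2))
    ssb = m * np.sum((row_means - gm[:, None]) ** 2, axis=1)
    ssw = np.sum((y - row_means[:, :, None]) ** 2, axis=(1, 2))
    msb = ssb / (n - 1)
    msw = ssw / (n * (m - 1))
    pooled = (ssb + ssw) / (n * m - 1)

    null = (n * m - 1) * np.log(pooled) + (ssb + ssw) / pooled
    alt_int = (
        (n - 1) * np.log(msb) + n * (m - 1) * np.log(msw) + (n - 1) + n * (m - 1)
    )
    alt = np.where(msb > msw, alt_int, null)
    return np.maximum(null - alt, 0.0)


def _increment_matrix(cohort: CohortSizes) -> tuple[np.ndarray, bool]:
    inc = cohort.increments()
    counts = (~inc.mask).sum(axis=1)
    keep = counts >= 2
    if keep.sum() < 2:
        raise ValueError("need >= 2 individuals with >= 2 increments each")
    inc = inc[keep]
    balanced = not inc.mask.any()
    return inc, balanced


def fit_lmm(cohort: CohortSizes, n_null_sims: int | None = None, seed=None) -> LmmResult:
    """Random-intercept LMM on per-step growth increments.

    Returns REML variance components, the derived rho^2 estimate
    var_ind / (var_ind + delta * var_res) with delta the scaled step
    length, and the restricted LR statistic for the individual variance
    component. Pass ``n_null_sims`` and ``seed`` to also compute a
    bootstrap p-value (see :func:`rlrt_test`).
    """
    inc, balanced = _increment_matrix(cohort)
    t = np.asarray(cohort.times, dtype=float)
    delta = float(np.mean(np.diff(t)) / (t[-1] - t[0]))

    if balanced:
        y = np.asarray(inc)
        var_ind, var_res, stat = _balanced_reml(y)
    else:
        var_ind, var_res, stat = _mixedlm_reml(inc)

    denom = var_ind + delta * var_res
    rho2 = var_ind / denom if denom > 0 else 0.0
    result = LmmResult(
        var_individual=var_ind,
        var_residual=var_res,
        rho2_hat=min(rho2, 1.0),
        rlrt_stat=stat,
    )
    if n_null_sims is not None:
        _, p = rlrt_test(cohort, n_null_sims, seed, _observed=result)
        result = LmmResult(
            var_individual=var_ind,
            var_residual=var_res,
            rho2_hat=result.rho2_hat,
            rlrt_stat=stat,
            p_value=p,
        )
    return result


def _neg2_rll_groups(groups: list[np.ndarray], var_ind: float, var_res: float) -> float:
    """Restricted -2 log-likelihood (constants dropped) for a random-
    intercept model with intercept-only fixed effects, per-group data.

    Per group of size m: |V| = var_res^(m-1) (var_res + m var_ind), and
    V^-1 = (I - (var_ind / (var_res + m var_ind)) J) / var_res.
    """
    l2 = var_res
    logdet = 0.0
    xtvx = 0.0
    xtvy = 0.0
    for y in groups:
        m = len(y)
        l1 = var_res + m * var_ind
        logdet += (m - 1) * np.log(l2) + np.log(l1)
        xtvx += m / l1
        xtvy += y.sum() / l1
    beta = xtvy / xtvx
    quad = 0.0
    for y in groups:
        m = len(y)
        l1 = var_res + m * var_ind
        r = y - beta
        quad += (r @ r) / l2 - (var_ind / (l2 * l1)) * r.sum() ** 2
    return logdet + np.log(xtvx) + quad


def _mixedlm_reml(inc: np.ma.MaskedArray) -> tuple[float, float, float]:
    """REML via statsmodels MixedLM for unbalanced increment tables.

    Point estimates come from MixedLM; the RLRT statistic is computed by
    evaluating one consistent restricted-likelihood expression at the
    fitted and the null variance components.
    """
    import statsmodels.api as sm

    rows, cols = np.where(~inc.mask)
    y = np.asarray(inc)[rows, cols]
    exog = np.ones((len(y), 1))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM(y, exog, groups=rows)
        res = model.fit(reml=True, method="lbfgs")
        var_ind = max(float(np.asarray(res.cov_re)[0, 0]), 0.0)
        var_res = float(res.scale)
    groups = [y[rows == g] for g in np.unique(rows)]
    s2_null = float(np.sum((y - y.mean()) ** 2)) / (len(y) - 1)
    alt = _neg2_rll_groups(groups, var_ind, var_res)
    null = _neg2_rll_groups(groups, 0.0, s2_null)
    stat = max(null - alt, 0.0)
    return var_ind, var_res, stat


def rlrt_test(
    cohort: CohortSizes,
    n_null_sims: int,
    seed,
    _observed: LmmResult | None = None,
) -> tuple[float, float]:
    """Bootstrap restricted likelihood-ratio test of rho = 0.

    The observed statistic is 2 x (restricted log-likelihood with the
    individual random effect - without). Its null distribution sits on
    the boundary of the parameter space, so it is simulated: datasets are
    drawn from the fitted null model (iid normal increments) and refit;
    p = (1 + #{null stats >= observed}) / (n_null_sims + 1).
    """
    if n_null_sims < 99:
        raise ValueError("n_null_sims must be >= 99 for usable p resolution")
    obs = _observed if _observed is not None else fit_lmm(cohort)
    inc, balanced = _increment_matrix(cohort)
    rng = np.random.default_rng(seed)

    if balanced:
        y = np.asarray(inc)
        n, m = y.shape
        mu, sd = y.mean(), y.std(ddof=1)
        null_y = rng.normal(mu, sd, size=(n_null_sims, n, m))
        null_stats = _balanced_reml_batch(null_y)
    else:
        null_stats = np.empty(n_null_sims)
        mask = inc.mask
        mu = float(inc.mean())
        sd = float(inc.std(ddof=1))
        for s in range(n_null_sims):
            sim = np.ma.masked_array(
                rng.normal(mu, sd, size=inc.shape), mask=mask
            )
            _, _, null_stats[s] = _mixedlm_reml(sim)

    p = (1.0 + float(np.sum(null_stats >= obs.rlrt_stat))) / (n_null_sims + 1.0)
    return obs.rlrt_stat, p
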