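"""Synthetic cohort growth data.

Each individual i follows

    x[i, t + delta] = x[i, t] + (g + eps_i) * delta + eta[i, t],

with a permanent rate deviation eps_i ~ N(0, rho^2 sigma^2) per unit
scaled time and step noise eta ~ N(0, (1 - rho^2) sigma^2 delta). Scaling
the among-individual variance by delta^2 per step and the within-individual
variance by delta per step makes the total variance increase over [0, 1]
equal to sigma^2 regardless of how many occasions subdivide the window.

Optional extras mimic the failure modes real cohorts exhibit: logistic
size-dependent mortality (smaller individuals die more, selectively
thinning the lower tail) and a saturating-exponential observation scale
(growth decelerates toward an asymptote, as in late larval ontogeny).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import GrowthParams, VarianceTrajectory

__all__ = [
    "CohortSizes",
    "MortalityParams",
    "simulate_cohort",
    "apply_mortality",
    "simulate_nonlinear_cohort",
]


@dataclass(frozen=True)
class MortalityParams:
    """Logistic size-dependent survival.

    Per unit scaled time, an individual of size x survives with probability
    1 / (1 + exp(-r (x - x0))); per step the survival probability is that
    logistic raised to the power delta_t (hazard scaling), so the overall
    survival of an individual holding size x for the whole window is the
    logistic itself, independent of how finely the window is sampled.
    """

    r: float = 0.4
    x0: float = -10.0
    enabled: bool = True

    def __post_init__(self) -> None:
        if self.enabled and self.r <= 0:
            raise ValueError("r must be > 0 when mortality is enabled")


@dataclass
class CohortSizes:
    """Per-individual sizes on a shared occasion grid with a survival mask.

    ``sizes`` is (n_individuals, n_t); ``alive`` is a boolean matrix of the
    same shape, monotone non-increasing along rows (no resurrection); a
    dead individual is unmeasured from its death occasion onward.
    """

    sizes: np.ndarray
    alive: np.ndarray
    times: np.ndarray
    individual_ids: np.ndarray
    # censoring (e.g. linearization dropping sizes above the asymptote)
    # may puncture rows; mortality masks must stay monotone
    allow_gaps: bool = False

    def __post_init__(self) -> None:
        self.sizes = np.asarray(self.sizes, dtype=float)
        self.alive = np.asarray(self.alive, dtype=bool)
        self.times = np.asarray(self.times, dtype=float)
        if self.sizes.shape != self.alive.shape:
            raise ValueError("sizes and alive must have identical shapes")
        if self.sizes.shape[1] != len(self.times):
            raise ValueError("times must match the number of occasions")
        if not self.allow_gaps and np.any(
            np.diff(self.alive.astype(int), axis=1) > 0
        ):
            raise ValueError("alive mask must be monotone along rows")

    @property
    def n_individuals(self) -> int:
        return self.sizes.shape[0]

    @property
    def n_t(self) -> int:
        return self.sizes.shape[1]

    def realized_mortality(self) -> float:
        """Fraction of individuals dead by the final occasion."""
        return 1.0 - float(self.alive[:, -1].mean())

    def variance_trajectory(self) -> VarianceTrajectory:
        """Occasion-wise sample variance (n-1 denominator) over survivors."""
        n_obs = self.alive.sum(axis=0)
        if np.any(n_obs < 2):
            raise ValueError(
                "fewer than 2 alive individuals at some occasion; "
                "variance undefined"
            )
        masked = np.ma.masked_array(self.sizes, mask=~self.alive)
        variances = masked.var(axis=0, ddof=1).filled(np.nan)
        return VarianceTrajectory(self.times, variances, n_obs)

    def increments(self) -> np.ma.MaskedArray:
        """Per-step size increments, masked where either endpoint is dead."""
        inc = np.diff(self.sizes, axis=1)
        valid = self.alive[:, 1:] & self.alive[:, :-1]
        return np.ma.masked_array(inc, mask=~valid)


def simulate_cohort(
    params: GrowthParams, n_individuals: int, seed
) -> CohortSizes:
    """Simulate one all-alive cohort under the linear growth model.

    Initial sizes are N(0, sigma0^2); each individual receives a permanent
    per-step increment deviation with variance rho^2 sigma^2 delta_t^2 and
    an independent per-step deviate with variance (1 - rho^2) sigma^2
    delta_t, plus the deterministic drift g delta_t. The expected occasion
    variances then follow the quadratic V(t) exactly.
    """
    if n_individuals < 2:
        raise ValueError("need at least 2 individuals for a variance")
    rng = np.random.default_rng(seed)
    n_t, delta = params.n_t, params.delta_t
    rho2 = params.rho**2

    x0 = rng.normal(0.0, np.sqrt(params.sigma0_2), size=n_individuals)
    # permanent rate deviation per unit time, N(0, rho^2 sigma^2)
    eps = rng.normal(0.0, np.sqrt(rho2 * params.sigma2), size=n_individuals)
    eta = rng.normal(
        0.0,
        np.sqrt((1.0 - rho2) * params.sigma2 * delta),
        size=(n_individuals, n_t - 1),
    )
    steps = (params.g + eps)[:, None] * delta + eta
    sizes = np.empty((n_individuals, n_t))
    sizes[:, 0] = x0
    sizes[:, 1:] = x0[:, None] + np.cumsum(steps, axis=1)

    return CohortSizes(
        sizes=sizes,
        alive=np.ones_like(sizes, dtype=bool),
        times=params.times,
        individual_ids=np.arange(n_individuals),
    )


def apply_mortality(
    cohort: CohortSizes, mort: MortalityParams, params: GrowthParams, seed
) -> CohortSizes:
    """Thin a cohort by per-step Bernoulli survival trials.

    At each step an alive individual survives with probability
    [1 / (1 + exp(-r (x - x0)))]^delta_t evaluated at its current size;
    the dead are masked from the next occasion onward. Returns a new
    CohortSizes; the input is not modified.
    """
    if not mort.enabled:
        return cohort
    rng = np.random.default_rng(seed)
    delta = params.delta_t
    alive = cohort.alive.copy()
    for k in range(cohort.n_t - 1):
        x = cohort.sizes[:, k]
        p_surv = np.exp(delta * -np.log1p(np.exp(-mort.r * (x - mort.x0))))
        survive = rng.random(cohort.n_individuals) < p_surv
        alive[:, k + 1] = alive[:, k] & survive & alive[:, k + 1]
    return CohortSizes(
        sizes=cohort.sizes,
        alive=alive,
        times=cohort.times,
        individual_ids=cohort.individual_ids,
    )


def simulate_nonlinear_cohort(
    params: GrowthParams,
    curve,
    n_individuals: int,
    seed,
    latent_offset: float = 0.2,
) -> CohortSizes:
    """Simulate a cohort observed on a saturating-exponential size scale.

    A latent cohort grows linearly (as in :func:`simulate_cohort`, shifted
    by ``latent_offset`` so latent sizes are mostly positive); observed
    sizes are c (1 - exp(-y)), strictly below the asymptote c. The
    linearization module's inverse transform recovers the latent scale.
    """
    if curve.c <= 0:
        raise ValueError("asymptotic size c must be positive")
    latent = simulate_cohort(params, n_individuals, seed)
    y = latent.sizes + latent_offset
    observed = curve.c * -np.expm1(-y)
    return CohortSizes(
        sizes=observed,
        alive=latent.alive,
        times=latent.times,
        individual_ids=latent.individual_ids,
    )
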