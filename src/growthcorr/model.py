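"""Closed-form variance dynamics of a linearly growing cohort.

A cohort of individuals grows linearly in size with a shared mean rate
``g``. Each individual deviates from that rate in two ways: a permanent,
individual-specific rate deviation (among-individual variation, the source
of positive growth autocorrelation) and an independent per-step deviation
(within-individual variation). With time scaled so the observation window
is [0, 1], the cohort's size variance is quadratic in time,

    V(t) = sigma0^2 + sigma^2 * (rho^2 * t^2 + (1 - rho^2) * t),

where ``rho^2`` is the fraction of growth-rate variance attributable to
permanent among-individual differences and ``sigma^2`` is the total
increase in cohort variance over the window. Among-individual deviations
accumulate coherently (variance grows like t^2) while within-individual
deviations accumulate as a random walk (variance grows like t); rho^2
interpolates between the two regimes. The between-step change in variance
is linear in t, which is what the estimator exploits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GrowthParams",
    "VarianceTrajectory",
    "variance_at_time",
    "expected_change",
    "invert_regression",
]


@dataclass(frozen=True)
class GrowthParams:
    """Generative parameters of the linear cohort growth model.

    Parameters
    ----------
    g
        Mean growth rate per unit scaled time. Does not enter the variance
        dynamics; default 1.0 (a choice of time units).
    rho
        Growth autocorrelation parameter in [0, 1]. ``rho**2`` is the
        fraction of growth-rate variance that is permanent among-individual
        variation.
    sigma2
        Total (relative) increase in cohort variance over the scaled
        observation window [0, 1], in size-units^2.
    sigma0_2
        Initial cohort variance, size-units^2. Default 1.0 (a choice of
        size units).
    n_t
        Number of evenly spaced sampling occasions (>= 3).
    """

    rho: float
    sigma2: float
    n_t: int
    g: float = 1.0
    sigma0_2: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.rho <= 1.0:
            raise ValueError(f"rho must be in [0, 1], got {self.rho}")
        if self.sigma2 < 0.0:
            raise ValueError(f"sigma2 must be >= 0, got {self.sigma2}")
        if self.sigma0_2 <= 0.0:
            raise ValueError(f"sigma0_2 must be > 0, got {self.sigma0_2}")
        if self.n_t < 3:
            raise ValueError(f"n_t must be >= 3, got {self.n_t}")

    @property
    def delta_t(self) -> float:
        """Scaled step length 1/(n_t - 1); the grid spans [0, 1] exactly."""
        return 1.0 / (self.n_t - 1)

    @property
    def times(self) -> np.ndarray:
        """The evenly spaced scaled occasion times."""
        return np.linspace(0.0, 1.0, self.n_t)


@dataclass(frozen=True)
class VarianceTrajectory:
    """Per-occasion sample variances of cohort size on a scaled time grid.

    ``times`` are strictly increasing and span [0, 1] after scaling;
    ``variances`` are the occasion-wise sample variances (size-units^2);
    ``n_obs`` records how many individuals contributed to each variance.
    """

    times: np.ndarray
    variances: np.ndarray
    n_obs: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        variances = np.asarray(self.variances, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "variances", variances)
        if times.ndim != 1 or len(times) < 2:
            raise ValueError("times must be a 1-d array with >= 2 entries")
        if np.any(np.diff(times) <= 0):
            raise ValueError("times must be strictly increasing")
        if len(variances) != len(times):
            raise ValueError("variances must align with times")
        if np.any(variances < 0):
            raise ValueError("variances must be non-negative")
        if self.n_obs is None:
            object.__setattr__(self, "n_obs", np.full(len(times), -1, dtype=int))
        else:
            object.__setattr__(self, "n_obs", np.asarray(self.n_obs, dtype=int))

    def __len__(self) -> int:
        return len(self.times)

    def changes(self) -> np.ndarray:
        """Between-step variance changes, entry k = V[k+1] - V[k]."""
        return np.diff(self.variances)

    def scaled(self) -> "VarianceTrajectory":
        """Affinely rescale times to [0, 1] (identity if already scaled)."""
        t0, t1 = self.times[0], self.times[-1]
        return VarianceTrajectory(
            (self.times - t0) / (t1 - t0), self.variances, self.n_obs
        )


def variance_at_time(params: GrowthParams, t) -> np.ndarray | float:
    """Cohort size variance V(t) at scaled time ``t`` in [0, 1].

    V(t) = sigma0^2 + sigma^2 (rho^2 t^2 + (1 - rho^2) t): among-individual
    deviations contribute the quadratic term, within-individual deviations
    the linear term. V(0) = sigma0^2 and V(1) = sigma0^2 + sigma^2.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0.0) or np.any(t > 1.0):
        raise ValueError("t must lie in the scaled window [0, 1]")
    rho2 = params.rho**2
    out = params.sigma0_2 + params.sigma2 * (rho2 * t**2 + (1.0 - rho2) * t)
    return out.item() if out.ndim == 0 else out


def expected_change(params: GrowthParams, t, delta) -> np.ndarray | float:
    """Expected one-step change in cohort variance over [t, t + delta].

    Delta V(t, delta) = sigma^2 (rho^2 (2 t delta + delta^2)
    + (1 - rho^2) delta); linear in t for fixed delta, and it telescopes:
    summed over any partition of [0, 1] it equals sigma^2 exactly.
    """
    t = np.asarray(t, dtype=float)
    delta = np.asarray(delta, dtype=float)
    if np.any(t < 0.0) or np.any(delta <= 0.0) or np.any(t + delta > 1.0 + 1e-12):
        raise ValueError("need t >= 0, delta > 0 and t + delta <= 1")
    rho2 = params.rho**2
    out = params.sigma2 * (
        rho2 * (2.0 * t * delta + delta**2) + (1.0 - rho2) * delta
    )
    return out.item() if out.ndim == 0 else out


def invert_regression(
    intercept: float, slope: float, delta: float
) -> tuple[float, float, bool]:
    """Solve (rho^2, sigma^2) from a linear fit of variance changes vs time.

    On an even grid, Delta V(t, delta) = a + b t with
    a = sigma^2 (1 - rho^2) delta + sigma^2 rho^2 delta^2 and
    b = 2 sigma^2 rho^2 delta, so sigma^2 rho^2 = b / (2 delta) and
    sigma^2 (1 - rho^2) = (a - b delta / 2) / delta. Estimates outside the
    feasible region [0, 1] x [0, inf) are clipped to its boundary.

    Returns
    -------
    (rho2, sigma2, clipped)
        ``clipped`` is True when the raw solution fell outside the feasible
        region and was projected onto its boundary.
    """
    if delta <= 0:
        raise ValueError("delta must be positive")
    s_among = slope / (2.0 * delta)  # sigma^2 * rho^2
    s_within = (intercept - slope * delta / 2.0) / delta  # sigma^2 * (1 - rho^2)
    clipped = False
    if s_among < 0.0:
        s_among = 0.0
        clipped = True
    if s_within < 0.0:
        s_within = 0.0
        clipped = True
    sigma2 = s_among + s_within
    if sigma2 <= 0.0:
        return 0.0, 0.0, True
    rho2 = s_among / sigma2
    if rho2 > 1.0:  # unreachable after clipping, kept as a guard
        rho2, clipped = 1.0, True
    return rho2, sigma2, clipped
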