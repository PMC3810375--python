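"""Monte-Carlo power, coverage, bias and design-guidance experiments.

Every experiment loops over scenarios (growth parameters x cohort size x
optional size-dependent mortality), simulates replicate cohorts with
deterministic per-replicate child seeds, fits the variance-pattern
estimator (and, where requested, the repeated-measures comparator on the
same cohorts), and aggregates power, coverage, bias and CI width.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .estimate import fit, test_rho_positive
from .model import GrowthParams
from .repeated import rlrt_test
from .simulate import CohortSizes, MortalityParams, apply_mortality, simulate_cohort

__all__ = [
    "Scenario",
    "StudyResult",
    "run_scenario",
    "min_individuals_for_power",
    "mortality_bias_study",
    "compare_methods",
    "BEYOND_GRID",
    "MORTALITY_BINS",
]

logger = logging.getLogger(__name__)

#: Sentinel returned when no cohort size in the grid reaches the target power.
BEYOND_GRID = "beyond grid"

#: Realized-mortality bin edges (fractions): <5%, 5-10%, 10-20%, 20-30%.
MORTALITY_BINS = [(0.0, 0.05), (0.05, 0.10), (0.10, 0.20), (0.20, 0.30)]


@dataclass(frozen=True)
class Scenario:
    """One simulation condition: growth parameters, design, replication."""

    params: GrowthParams
    n_individuals: int
    n_replicates: int
    seed: int
    mortality: MortalityParams | None = None

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.n_individuals < 2:
            raise ValueError("n_individuals must be >= 2")


@dataclass
class StudyResult:
    """Aggregated Monte-Carlo summaries plus per-replicate records."""

    scenario: Scenario
    power: float
    coverage: float
    mean_bias_rho: float
    mean_bias_rho2: float
    mean_ci_width_rho2: float
    mean_realized_mortality: float
    n_failed: int
    records: pd.DataFrame = field(repr=False)


def _child_seed(base: int, index: int) -> list[int]:
    # list-seeding default_rng keeps child streams independent of each other
    return [int(base), int(index)]


def _simulate_replicate(s: Scenario, i: int) -> CohortSizes:
    cohort = simulate_cohort(s.params, s.n_individuals, _child_seed(s.seed, i))
    if s.mortality is not None and s.mortality.enabled:
        cohort = apply_mortality(
            cohort, s.mortality, s.params, _child_seed(s.seed, i) + [1]
        )
    return cohort


def run_scenario(s: Scenario) -> StudyResult:
    """Simulate, fit and aggregate one scenario.

    Replicates whose fit raises (e.g. mortality leaves fewer than two
    survivors at an occasion) are logged and excluded from the summaries;
    their count is reported in ``n_failed``.
    """
    rows = []
    n_failed = 0
    true_rho = s.params.rho
    for i in range(s.n_replicates):
        cohort = _simulate_replicate(s, i)
        try:
            traj = cohort.variance_trajectory()
            fr = fit(traj)
        except (ValueError, FloatingPointError) as exc:
            n_failed += 1
            logger.warning("replicate %d failed: %s", i, exc)
            continue
        lo, hi = fr.rho_ci
        rows.append(
            {
                "replicate": i,
                "rho_hat": fr.rho_hat,
                "rho2_hat": fr.rho2_hat,
                "sigma2_hat": fr.sigma2_hat,
                "ci_lower": lo,
                "ci_upper": hi,
                "reject_null": test_rho_positive(fr),
                "covered": lo <= true_rho <= hi,
                "ci_width_rho2": hi**2 - lo**2,
                "realized_mortality": cohort.realized_mortality(),
            }
        )
    rec = pd.DataFrame(rows)
    if rec.empty:
        raise RuntimeError("all replicates failed; scenario unusable")
    return StudyResult(
        scenario=s,
        power=float(rec["reject_null"].mean()),
        coverage=float(rec["covered"].mean()),
        mean_bias_rho=float((rec["rho_hat"] - true_rho).mean()),
        mean_bias_rho2=float((rec["rho2_hat"] - true_rho**2).mean()),
        mean_ci_width_rho2=float(rec["ci_width_rho2"].mean()),
        mean_realized_mortality=float(rec["realized_mortality"].mean()),
        n_failed=n_failed,
        records=rec,
    )


def min_individuals_for_power(
    rho2: float,
    sigma2: float,
    n_t: int,
    grid: list[int],
    n_replicates: int = 1000,
    seed: int = 0,
    target_power: float = 0.8,
) -> tuple[int | str, pd.DataFrame]:
    """Smallest cohort size whose interpolated power reaches the target.

    Runs the power study over an ascending grid of cohort sizes, then
    linearly interpolates power between adjacent grid points and returns
    the (rounded-up) size at the first upward crossing of
    ``target_power``; :data:`BEYOND_GRID` if power never reaches it.
    Also returns the per-size power table.
    """
    if not grid:
        raise ValueError("grid of cohort sizes must be non-empty")
    if sorted(grid) != list(grid):
        raise ValueError("grid must be ascending")
    rho = float(np.sqrt(rho2))
    powers = []
    for j, n in enumerate(grid):
        s = Scenario(
            params=GrowthParams(rho=rho, sigma2=sigma2, n_t=n_t),
            n_individuals=n,
            n_replicates=n_replicates,
            seed=seed + j,
        )
        powers.append(run_scenario(s).power)
        logger.info("n=%d power=%.3f", n, powers[-1])
    table = pd.DataFrame({"n_individuals": grid, "power": powers})

    if target_power <= powers[0]:
        return grid[0], table
    for j in range(1, len(grid)):
        if powers[j] >= target_power:
            n0, n1 = grid[j - 1], grid[j]
            p0, p1 = powers[j - 1], powers[j]
            if p1 == p0:
                return n1, table
            n_star = n0 + (target_power - p0) / (p1 - p0) * (n1 - n0)
            return int(np.ceil(n_star)), table
    return BEYOND_GRID, table


def mortality_bias_study(
    x0_values=(-10.0, -9.0, -8.0, -7.0),
    r: float = 0.4,
    sigma2_values=(4.0, 16.0, 64.0, 256.0),
    rho_values=(0.5, 0.7, 0.9),
    n_individuals: int = 128,
    n_t: int = 16,
    n_replicates: int = 250,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Bias of rho_hat under size-dependent mortality, binned by realized
    mortality.

    Pools replicates across the mortality-position, variance and
    autocorrelation grids, bins each replicate by its cohort's realized
    mortality and reports the mean of (rho_hat - rho) and of
    (rho2_hat - rho^2) per bin. Empty bins are reported as missing.
    Returns (bin summary, pooled per-replicate records).
    """
    frames = []
    idx = 0
    for x0 in x0_values:
        for sigma2 in sigma2_values:
            for rho in rho_values:
                s = Scenario(
                    params=GrowthParams(rho=rho, sigma2=sigma2, n_t=n_t),
                    n_individuals=n_individuals,
                    n_replicates=n_replicates,
                    seed=seed + idx,
                    mortality=MortalityParams(r=r, x0=x0),
                )
                res = run_scenario(s)
                rec = res.records.copy()
                rec["x0"] = x0
                rec["sigma2"] = sigma2
                rec["rho"] = rho
                rec["bias_rho"] = rec["rho_hat"] - rho
                rec["bias_rho2"] = rec["rho2_hat"] - rho**2
                frames.append(rec)
                idx += 1
    pooled = pd.concat(frames, ignore_index=True)

    rows = []
    for lo, hi in MORTALITY_BINS:
        sel = pooled[
            (pooled["realized_mortality"] >= lo)
            & (pooled["realized_mortality"] < hi)
        ]
        rows.append(
            {
                "bin": f"[{lo:.0%}, {hi:.0%})",
                "bin_low": lo,
                "bin_high": hi,
                "n": len(sel),
                "mean_bias_rho": float(sel["bias_rho"].mean()) if len(sel) else np.nan,
                "mean_bias_rho2": float(sel["bias_rho2"].mean()) if len(sel) else np.nan,
            }
        )
    return pd.DataFrame(rows), pooled


def compare_methods(
    scenarios: list[Scenario],
    n_null_sims: int = 199,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Paired power comparison: variance-pattern test vs LMM/RLRT.

    Both tests run on the SAME simulated cohorts per replicate (pairing
    reduces the Monte-Carlo variance of the power difference). Scenarios
    must be mortality-free (the repeated-measures model assumes balance).
    Returns one row per scenario with both powers and the gap
    (LMM - variance-pattern).
    """
    rows = []
    for s in scenarios:
        if s.mortality is not None and s.mortality.enabled:
            raise ValueError("method comparison requires mortality-free scenarios")
        vp_reject = []
        lmm_reject = []
        for i in range(s.n_replicates):
            cohort = _simulate_replicate(s, i)
            fr = fit(cohort.variance_trajectory())
            vp_reject.append(test_rho_positive(fr))
            _, p = rlrt_test(
                cohort, n_null_sims, seed=_child_seed(s.seed, i) + [2]
            )
            lmm_reject.append(p < alpha)
        vp_power = float(np.mean(vp_reject))
        lmm_power = float(np.mean(lmm_reject))
        rows.append(
            {
                "rho2": s.params.rho**2,
                "sigma2": s.params.sigma2,
                "n_t": s.params.n_t,
                "n_individuals": s.n_individuals,
                "n_replicates": s.n_replicates,
                "vp_power": vp_power,
                "lmm_power": lmm_power,
                "power_gap": lmm_power - vp_power,
            }
        )
    return pd.DataFrame(rows)
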