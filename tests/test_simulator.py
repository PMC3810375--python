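"""Cohort simulator: scaling of the variance trajectory, mortality, seeds."""

import numpy as np
import pytest

from growthcorr import (
    CohortSizes,
    GrowthCurveParams,
    GrowthParams,
    MortalityParams,
    apply_mortality,
    simulate_cohort,
    simulate_nonlinear_cohort,
    variance_at_time,
)


class TestSimulateCohort:
    def test_identical_seeds_identical_cohorts(self):
        p = GrowthParams(rho=0.5, sigma2=16.0, n_t=16)
        a = simulate_cohort(p, 50, seed=[42, 0])
        b = simulate_cohort(p, 50, seed=[42, 0])
        assert np.array_equal(a.sizes, b.sizes)

    def test_rho_one_increments_constant_per_individual(self):
        """With rho = 1 there is no step noise: each individual's
        increments are identical across steps."""
        p = GrowthParams(rho=1.0, sigma2=16.0, n_t=16)
        c = simulate_cohort(p, 20, seed=1)
        inc = np.diff(c.sizes, axis=1)
        assert np.allclose(inc, inc[:, [0]], atol=1e-12)

    def test_too_few_individuals(self):
        with pytest.raises(ValueError):
            simulate_cohort(GrowthParams(rho=0.5, sigma2=16.0, n_t=16), 1, seed=0)

    def test_final_variance_matches_total_increase(self):
        """Mean final-occasion sample variance over 2000 cohorts of 50
        individuals is sigma0^2 + sigma^2 within 3 Monte-Carlo SEs."""
        p = GrowthParams(rho=0.7, sigma2=16.0, n_t=16)
        finals = np.empty(2000)
        for i in range(2000):
            finals[i] = simulate_cohort(p, 50, seed=[7, i]).sizes[:, -1].var(ddof=1)
        target = p.sigma0_2 + p.sigma2
        se = finals.std(ddof=1) / np.sqrt(len(finals))
        assert abs(finals.mean() - target) < 3 * se

    @pytest.mark.parametrize("rho,sigma2", [(0.1, 4.0), (0.5, 32.0), (0.9, 256.0)])
    def test_mean_trajectory_matches_quadratic(self, rho, sigma2):
        """The Monte-Carlo mean variance trajectory follows V(t)."""
        p = GrowthParams(rho=rho, sigma2=sigma2, n_t=16)
        reps = 400
        vs = np.empty((reps, p.n_t))
        for i in range(reps):
            vs[i] = simulate_cohort(p, 50, seed=[11, i]).sizes.var(axis=0, ddof=1)
        mean_v = vs.mean(axis=0)
        se = vs.std(axis=0, ddof=1) / np.sqrt(reps)
        expected = variance_at_time(p, p.times)
        assert np.all(np.abs(mean_v - expected) < 3 * se + 1e-9)

    def test_rho_zero_trajectory_is_linear(self):
        """With rho = 0 the mean variance trajectory has no quadratic
        component: the fitted t^2 coefficient is negligible."""
        p = GrowthParams(rho=0.0, sigma2=16.0, n_t=16)
        reps = 600
        vs = np.zeros(p.n_t)
        for i in range(reps):
            vs += simulate_cohort(p, 50, seed=[13, i]).sizes.var(axis=0, ddof=1)
        vs /= reps
        t = p.times
        coef = np.polyfit(t, vs, 2)
        assert abs(coef[0]) < 0.05 * p.sigma2  # quadratic term ~ 0 vs sigma^2


class TestMortality:
    def _cohort(self, sigma2=4.0, n=200, seed=3):
        p = GrowthParams(rho=0.7, sigma2=sigma2, n_t=16)
        return p, simulate_cohort(p, n, seed=seed)

    def test_disabled_leaves_everyone_alive(self):
        p, c = self._cohort()
        out = apply_mortality(c, MortalityParams(enabled=False), p, seed=0)
        assert out.alive.all()
        assert out.realized_mortality() == 0.0

    def test_steep_logistic_above_threshold_no_deaths(self):
        p, c = self._cohort()
        mort = MortalityParams(r=1000.0, x0=float(c.sizes.min()) - 5.0)
        out = apply_mortality(c, mort, p, seed=0)
        assert out.realized_mortality() == 0.0

    def test_low_mortality_at_far_threshold(self):
        """x0 = -10, r = 0.4, sizes near N(0..1, few): per-unit-time
        survival ~ logistic(4) = 0.982, so realized mortality stays low."""
        p, c = self._cohort(sigma2=4.0, n=500)
        out = apply_mortality(c, MortalityParams(r=0.4, x0=-10.0), p, seed=5)
        assert out.realized_mortality() < 0.05

    def test_larger_sigma2_more_mortality(self):
        mort = MortalityParams(r=0.4, x0=-8.0)
        morts = []
        for sigma2 in (4.0, 256.0):
            p, c = self._cohort(sigma2=sigma2, n=400, seed=9)
            morts.append(apply_mortality(c, mort, p, seed=10).realized_mortality())
        assert morts[1] > morts[0]

    def test_mask_monotone_and_sizes_untouched(self):
        p, c = self._cohort(sigma2=64.0)
        out = apply_mortality(c, MortalityParams(r=0.4, x0=-7.0), p, seed=2)
        assert np.all(np.diff(out.alive.astype(int), axis=1) <= 0)
        assert np.array_equal(out.sizes, c.sizes)
        assert c.alive.all()  # input not mutated


class TestNonlinearCohort:
    def test_observed_below_asymptote(self):
        p = GrowthParams(rho=0.7, sigma2=0.25, n_t=8, sigma0_2=0.01)
        curve = GrowthCurveParams(c=40.0, b=0.2, d=1.0)
        c = simulate_nonlinear_cohort(p, curve, 50, seed=1)
        assert np.all(c.sizes < curve.c)

    def test_large_asymptote_is_near_linear(self):
        """For c >> latent sizes, c(1 - exp(-y)) ~ c*y: observed sizes are
        proportional to latent ones."""
        p = GrowthParams(rho=0.7, sigma2=1e-4, n_t=8, sigma0_2=1e-6, g=0.01)
        curve = GrowthCurveParams(c=1e6, b=0.0, d=1.0)
        obs = simulate_nonlinear_cohort(p, curve, 30, seed=2, latent_offset=0.01)
        latent = simulate_cohort(p, 30, seed=2).sizes + 0.01
        assert np.allclose(obs.sizes / curve.c, latent, atol=1e-3)

    def test_transform_round_trip(self):
        curve = GrowthCurveParams(c=40.0, b=0.2, d=1.0)
        y = np.linspace(0.01, 3.0, 50)
        x = curve.c * -np.expm1(-y)
        back = -np.log1p(-x / curve.c)
        assert np.allclose(back, y, rtol=1e-12)


class TestCohortSizes:
    def test_no_resurrection_enforced(self):
        sizes = np.zeros((2, 3))
        alive = np.array([[True, False, True], [True, True, True]])
        with pytest.raises(ValueError):
            CohortSizes(sizes, alive, np.linspace(0, 1, 3), np.arange(2))

    def test_variance_trajectory_uses_survivors(self):
        sizes = np.array([[0.0, 1.0, 5.0], [2.0, 3.0, 9.0], [4.0, 5.0, 99.0]])
        alive = np.array(
            [[True, True, True], [True, True, True], [True, True, False]]
        )
        c = CohortSizes(sizes, alive, np.linspace(0, 1, 3), np.arange(3))
        traj = c.variance_trajectory()
        assert traj.variances[0] == pytest.approx(4.0)
        assert traj.variances[2] == pytest.approx(8.0)  # only first two rows
        assert list(traj.n_obs) == [3, 3, 2]
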