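"""Step-ahead likelihood estimator: recovery, OLS equivalence, profiles."""

import numpy as np
import pytest

from growthcorr import (
    FitResult,
    GrowthParams,
    VarianceTrajectory,
    expected_change,
    fit,
    invert_regression,
    neg_log_likelihood,
    profile_ci_rho,
    simulate_cohort,
    test_rho_positive as reject_null,
    variance_at_time,
)


def noiseless_trajectory(rho, sigma2, n_t):
    p = GrowthParams(rho=rho, sigma2=sigma2, n_t=n_t)
    return VarianceTrajectory(p.times, variance_at_time(p, p.times))


def noisy_trajectory(rho, sigma2, n_t, tau, seed):
    p = GrowthParams(rho=rho, sigma2=sigma2, n_t=n_t)
    rng = np.random.default_rng(seed)
    clean = variance_at_time(p, p.times)
    dv = np.diff(clean) + rng.normal(0, tau, n_t - 1)
    v = np.concatenate([[clean[0]], clean[0] + np.cumsum(dv)])
    return VarianceTrajectory(p.times, np.maximum(v, 0.0))


class TestNegLogLikelihood:
    def test_zero_residual_at_truth(self):
        traj = noiseless_trajectory(0.6, 32.0, 16)
        nll_true = neg_log_likelihood(0.6, 32.0, 1.0, traj)
        # residual term vanishes: only the log tau + constant part remains
        m = len(traj) - 1
        assert nll_true == pytest.approx(m * 0.5 * np.log(2 * np.pi))

    def test_tau_minimizer_is_rms_residual(self):
        traj = noisy_trajectory(0.5, 16.0, 16, tau=0.8, seed=4)
        rho, sigma2 = 0.5, 16.0
        dv = traj.changes()
        p = GrowthParams(rho=rho, sigma2=sigma2, n_t=16)
        pred = np.array(
            [
                expected_change(p, traj.times[k], traj.times[k + 1] - traj.times[k])
                for k in range(len(dv))
            ]
        )
        tau_star = float(np.sqrt(np.mean((dv - pred) ** 2)))
        taus = np.linspace(0.5 * tau_star, 2.0 * tau_star, 401)
        nlls = [neg_log_likelihood(rho, sigma2, t, traj) for t in taus]
        assert abs(taus[int(np.argmin(nlls))] - tau_star) < 0.01 * tau_star

    def test_domain_errors(self):
        traj = noiseless_trajectory(0.5, 16.0, 16)
        with pytest.raises(ValueError):
            neg_log_likelihood(0.5, 16.0, 0.0, traj)
        with pytest.raises(ValueError):
            neg_log_likelihood(1.5, 16.0, 1.0, traj)


class TestFit:
    @pytest.mark.parametrize(
        "rho,sigma2,n_t", [(0.6, 32.0, 16), (0.3, 4.0, 8), (0.9, 128.0, 32)]
    )
    def test_noiseless_round_trip(self, rho, sigma2, n_t):
        fr = fit(noiseless_trajectory(rho, sigma2, n_t))
        assert fr.rho_hat == pytest.approx(rho, abs=1e-5)
        assert fr.sigma2_hat == pytest.approx(sigma2, rel=1e-4)

    def test_ols_equivalence_on_interior_solutions(self):
        """When the OLS inversion is interior it IS the MLE: the
        constant-dispersion likelihood makes the equivalence exact."""
        n_interior = 0
        for seed in range(40):
            traj = noisy_trajectory(0.6, 32.0, 16, tau=1.0, seed=seed)
            dv = traj.changes()
            t = traj.times[:-1]
            b, a = np.polyfit(t, dv, 1)
            rho2_ols, sigma2_ols, clipped = invert_regression(a, b, 1.0 / 15)
            if clipped or not (0.02 < rho2_ols < 0.98):
                continue
            n_interior += 1
            fr = fit(traj)
            assert fr.rho_hat == pytest.approx(np.sqrt(rho2_ols), abs=1e-5)
            assert fr.sigma2_hat == pytest.approx(sigma2_ols, rel=1e-4)
        assert n_interior > 10  # the check actually exercised something

    def test_decreasing_variances_hit_sigma2_boundary(self):
        traj = VarianceTrajectory(
            np.linspace(0, 1, 8), np.linspace(5.0, 1.0, 8)
        )
        fr = fit(traj)
        assert fr.sigma2_hat == 0.0
        assert fr.on_boundary["sigma2_zero"]

    def test_flat_variances_warn_not_raise(self):
        traj = VarianceTrajectory(np.linspace(0, 1, 8), np.full(8, 2.0))
        with pytest.warns(UserWarning):
            fr = fit(traj)
        assert fr.sigma2_hat == 0.0

    def test_deterministic(self):
        traj = noisy_trajectory(0.5, 16.0, 16, tau=1.0, seed=2)
        assert fit(traj) == fit(traj)

    def test_scale_invariance_of_rho(self):
        """Rescaling all sizes by k multiplies variances by k^2: rho_hat
        is unchanged, sigma2_hat scales by k^2."""
        traj = noisy_trajectory(0.5, 16.0, 16, tau=1.0, seed=6)
        fr = fit(traj)
        scaled = VarianceTrajectory(traj.times, 4.0 * traj.variances)
        fr2 = fit(scaled)
        assert fr2.rho_hat == pytest.approx(fr.rho_hat, abs=1e-8)
        assert fr2.sigma2_hat == pytest.approx(4.0 * fr.sigma2_hat, rel=1e-8)

    def test_too_few_occasions(self):
        with pytest.raises(ValueError):
            fit(VarianceTrajectory([0.0, 1.0], [1.0, 2.0]))


class TestProfileCI:
    def test_null_data_lower_bound_zero(self):
        p = GrowthParams(rho=0.0, sigma2=16.0, n_t=16)
        hits = 0
        for i in range(10):
            fr = fit(simulate_cohort(p, 128, seed=[17, i]).variance_trajectory())
            if fr.rho_ci[0] == 0.0:
                hits += 1
        assert hits >= 9  # rejection rate under the null is a few percent

    def test_ci_ordering_and_range(self):
        traj = noisy_trajectory(0.6, 16.0, 16, tau=1.0, seed=8)
        fr = fit(traj)
        lo, hi = fr.rho_ci
        assert 0.0 <= lo <= fr.rho_hat <= hi <= 1.0
        assert fr.rho2_ci == (lo**2, hi**2)

    def test_width_shrinks_with_more_individuals(self):
        p = {"rho": 0.7, "sigma2": 16.0, "n_t": 16}
        widths = []
        for n in (8, 512):
            w = []
            for i in range(30):
                c = simulate_cohort(GrowthParams(**p), n, seed=[19, n, i])
                fr = fit(c.variance_trajectory())
                w.append(fr.rho_ci[1] - fr.rho_ci[0])
            widths.append(np.mean(w))
        assert widths[1] < widths[0]

    def test_non_converged_rejected(self):
        traj = noisy_trajectory(0.6, 16.0, 16, tau=1.0, seed=9)
        bad = FitResult(
            rho_hat=0.5, sigma2_hat=16.0, tau_hat=1.0, loglik=0.0,
            rho_ci=(np.nan, np.nan), rho2_ci=(np.nan, np.nan),
            on_boundary={}, converged=False,
        )
        with pytest.raises(ValueError):
            profile_ci_rho(traj, bad)


class TestRhoPositive:
    def test_boundary_ci_not_significant(self):
        fr = fit(noisy_trajectory(0.0, 16.0, 16, tau=3.0, seed=1))
        fake = FitResult(**{**fr.__dict__, "rho_ci": (0.0, 0.8)})
        assert not reject_null(fake)
        fake = FitResult(**{**fr.__dict__, "rho_ci": (0.1, 0.9)})
        assert reject_null(fake)
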