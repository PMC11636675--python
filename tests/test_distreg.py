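"""Distributional-regression fitter: basis calibration, recovery, ascent."""

import dataclasses

import numpy as np
import pytest

from normsim import (
    DistRegSpec,
    SimulatedSample,
    build_spline_basis,
    fit_distreg,
    predict_percentiles,
    sample_ages,
    simulate_sample,
)


@pytest.fixture(scope="module")
def ages_1000():
    return sample_ages(1000, seed=31).ages


class TestSplineBasis:
    def test_edf_limits(self, ages_1000):
        """lambda -> inf collapses to a line; lambda = 0 gives dim - 2 df."""
        b = build_spline_basis(ages_1000, df=3.0)
        B = b.design(ages_1000)
        BtB = B.T @ B

        def edf(lam):  # independent trace computation
            A = BtB + lam * b.penalty + 1e-10 * np.eye(b.dim)
            return float(np.trace(np.linalg.solve(A, BtB))) - 2.0

        assert edf(1e12) == pytest.approx(0.0, abs=1e-2)
        assert edf(1e12) < edf(1e8) < edf(1e4)  # monotone decrease in lambda
        assert edf(0.0) == pytest.approx(b.dim - 2, abs=1e-6)

    def test_bisection_hits_target_df(self, ages_1000):
        b = build_spline_basis(ages_1000, df=3.0)
        B = b.design(ages_1000)
        BtB = B.T @ B
        A = BtB + b.lam * b.penalty + 1e-10 * np.eye(b.dim)
        edf = float(np.trace(np.linalg.solve(A, BtB))) - 2.0
        assert edf == pytest.approx(3.0, abs=0.05)

    def test_penalty_annihilates_lines(self, ages_1000):
        """A straight line in the basis has exactly zero roughness penalty."""
        b = build_spline_basis(ages_1000, df=3.0)
        grid = np.linspace(ages_1000.min(), ages_1000.max(), 200)
        B = b.design(grid)
        target = 2.0 + 0.5 * grid
        beta, *_ = np.linalg.lstsq(B, target, rcond=None)
        np.testing.assert_allclose(B @ beta, target, atol=1e-8)
        assert float(beta @ b.penalty @ beta) == pytest.approx(0.0, abs=1e-10)

    def test_too_few_distinct_ages(self):
        with pytest.raises(ValueError):
            build_spline_basis(np.array([50.0, 50.0, 60.0, 60.0, 70.0]), df=3.0)


class TestFit:
    def test_noiseless_line_recovery(self):
        ages = np.linspace(45, 80, 200)
        values = 4000.0 - 5.0 * ages
        s = SimulatedSample(ages, values)
        fit = fit_distreg(s, DistRegSpec("SHASH", "linear"))
        assert fit.blocks[0].beta[1] == pytest.approx(-5.0, abs=1e-6)
        assert fit.blocks[0].beta[0] == pytest.approx(4000.0, abs=1e-4)

    def test_penalized_loglik_monotone_ascent(self, nonlin_sample_2000, nonlin_gt):
        fit = fit_distreg(
            nonlin_sample_2000,
            DistRegSpec("SHASH", "mu_sigma_spline"),
            age_range=nonlin_gt.age_range,
        )
        assert fit.converged
        trace = np.array(fit.trace)
        assert np.all(np.diff(trace) >= -1e-6 * (np.abs(trace[:-1]) + 1.0))

    def test_nested_structures_do_not_fit_worse(self, nonlin_sample_2000, nonlin_gt):
        """More flexible structures reach at least the simpler optimum."""
        plls = {}
        for structure in ("linear", "mu_spline", "mu_sigma_spline"):
            fit = fit_distreg(
                nonlin_sample_2000,
                DistRegSpec("SHASH", structure),
                age_range=nonlin_gt.age_range,
            )
            assert fit.converged
            plls[structure] = fit.loglik
        assert plls["mu_spline"] >= plls["linear"] - 1e-4
        assert plls["mu_sigma_spline"] >= plls["mu_spline"] - 1e-4

    def test_shash_shape_recovery_across_replicates(self, lin_gt):
        """Median fitted skew ~ 0 and tail ~ 1 on Gaussian linear-truth data."""
        d = sample_ages(2000, seed=37)
        skews, tails = [], []
        for r in range(50):
            s = simulate_sample(lin_gt, d, r, 41)
            fit = fit_distreg(s, DistRegSpec("SHASH", "linear"), age_range=lin_gt.age_range)
            if fit.converged:
                skews.append(float(fit.blocks[2].beta[0]))
                tails.append(float(np.exp(fit.blocks[3].beta[0])))
        assert len(skews) >= 45
        assert abs(np.median(skews)) < 0.05
        assert abs(np.median(tails) - 1.0) < 0.05

    def test_affine_equivariance_within_tolerance(self, lin_gt):
        d = sample_ages(1000, seed=43)
        s = simulate_sample(lin_gt, d, 0, 43)
        a, b = 500.0, 2.0
        s2 = dataclasses.replace(s, values=a + b * s.values)
        grid = np.linspace(46, 79, 12)
        c1 = predict_percentiles(
            fit_distreg(s, DistRegSpec("SHASH", "linear"), age_range=lin_gt.age_range),
            grid,
        )
        c2 = predict_percentiles(
            fit_distreg(s2, DistRegSpec("SHASH", "linear"), age_range=lin_gt.age_range),
            grid,
        )
        scale = float(np.mean(np.abs(c2.curves)))
        assert np.max(np.abs(c2.curves - (a + b * c1.curves))) < 1e-3 * scale

    def test_bct_linear_fit_smoke(self, lin_gt):
        d = sample_ages(500, seed=47)
        s = simulate_sample(lin_gt, d, 0, 47)
        fit = fit_distreg(s, DistRegSpec("BCT", "linear"), age_range=lin_gt.age_range)
        assert fit.converged
        assert fit.blocks[0].beta[1] == pytest.approx(-7.0, abs=1.5)
        c = predict_percentiles(fit, np.linspace(46, 79, 10))
        assert np.all(np.diff(c.curves, axis=0) > 0)

    def test_rejects_tiny_samples_and_nonpositive_bct(self):
        ages = np.linspace(45, 80, 30)
        with pytest.raises(ValueError):
            fit_distreg(SimulatedSample(ages, np.ones(30)), DistRegSpec("SHASH", "linear"))
        ages = np.linspace(45, 80, 60)
        vals = np.ones(60)
        vals[0] = -1.0
        with pytest.raises(ValueError):
            fit_distreg(SimulatedSample(ages, vals), DistRegSpec("BCT", "linear"))


class TestPredict:
    def test_median_equals_location_when_symmetric(self, nonlin_sample_2000, nonlin_gt):
        fit = fit_distreg(
            nonlin_sample_2000, DistRegSpec("SHASH", "mu_spline"), age_range=nonlin_gt.age_range
        )
        fit.blocks[2].beta[:] = 0.0  # force exact symmetry
        grid = np.arange(46.0, 80.0)
        c = predict_percentiles(fit, grid, percentiles=[0.5])
        mu = fit.params_at(grid)[0]
        np.testing.assert_allclose(c.curves[0], mu, rtol=1e-6)

    def test_curves_monotone_in_percentile(self, nonlin_sample_2000, nonlin_gt):
        fit = fit_distreg(
            nonlin_sample_2000, DistRegSpec("SHASH", "linear"), age_range=nonlin_gt.age_range
        )
        c = predict_percentiles(fit, np.arange(45.0, 81.0), percentiles=[0.01, 0.05, 0.10])
        assert np.all(np.diff(c.curves, axis=0) > 0)

    def test_no_extrapolation(self, nonlin_sample_2000, nonlin_gt):
        fit = fit_distreg(
            nonlin_sample_2000, DistRegSpec("SHASH", "linear"), age_range=nonlin_gt.age_range
        )
        with pytest.raises(ValueError):
            predict_percentiles(fit, np.array([44.0]))

    def test_serialisation_json(self, nonlin_sample_2000, nonlin_gt):
        import json

        fit = fit_distreg(
            nonlin_sample_2000, DistRegSpec("SHASH", "linear"), age_range=nonlin_gt.age_range
        )
        payload = json.loads(fit.to_json())
        assert payload["converged"] is True
        assert payload["spec"]["family"] == "SHASH"
        assert len(payload["blocks"]) == 4
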