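"""SHASH and Box-Cox-t family correctness: round-trips, limits, integrals."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate, optimize, stats

from normsim import (
    BctParams,
    ShashParams,
    bct_cdf,
    bct_logpdf,
    bct_quantile,
    shash_cdf,
    shash_logpdf,
    shash_quantile,
)
from normsim.distributions import InvalidParameterError

SHASH_GRID = [
    ShashParams(0.0, 1.0, 0.0, 1.0),
    ShashParams(6000.0, 200.0, 0.0, 1.0),
    ShashParams(1.0, 2.0, 0.5, 1.5),
    ShashParams(-3.0, 0.5, -1.2, 0.7),
    ShashParams(100.0, 30.0, 2.0, 2.5),
]
BCT_GRID = [
    BctParams(6000.0, 0.05, 1.0, 30.0),
    BctParams(5000.0, 0.06, 0.3, 8.0),
    BctParams(10.0, 0.2, -0.5, 5.0),
    BctParams(1.0, 0.1, 0.0, 15.0),
]


def _bisect_quantile(cdf, p, lo, hi):
    """Independent quantile oracle: bisection on the cdf."""
    return optimize.brentq(lambda y: cdf(y) - p, lo, hi, xtol=1e-12, rtol=1e-14)


@settings(max_examples=60, derandomize=True)
@given(
    location=st.floats(-100.0, 100.0),
    scale=st.floats(0.1, 50.0),
    skew=st.floats(-2.0, 2.0),
    tail=st.floats(0.3, 3.0),
    p=st.floats(1e-4, 1.0 - 1e-4),
)
def test_shash_roundtrip_property(location, scale, skew, tail, p):
    """cdf(quantile(p)) == p across the whole valid parameter space."""
    params = ShashParams(location, scale, skew, tail)
    assert float(shash_cdf(shash_quantile(p, params), params)) == pytest.approx(
        p, rel=1e-9, abs=1e-12
    )


class TestShash:
    def test_standard_normal_median(self):
        assert shash_cdf(0.0, ShashParams(0, 1, 0, 1)) == pytest.approx(0.5)
        assert shash_quantile(0.5, ShashParams(6000, 200, 0, 1)) == pytest.approx(6000.0)

    def test_reduction_to_gaussian(self):
        """skew=0, tail=1 must match the Gaussian cdf pointwise to 1e-12."""
        p = ShashParams(6000.0, 200.0, 0.0, 1.0)
        y = np.linspace(5000.0, 7000.0, 41)
        np.testing.assert_allclose(
            shash_cdf(y, p), stats.norm.cdf(y, 6000.0, 200.0), atol=1e-12
        )
        assert shash_quantile(0.01, p) == pytest.approx(
            6000.0 + 200.0 * stats.norm.ppf(0.01), abs=1e-8
        )

    @pytest.mark.parametrize("params", SHASH_GRID)
    def test_cdf_quantile_roundtrip(self, params):
        p = np.array([1e-4, 0.01, 0.05, 0.3, 0.5, 0.7, 0.95, 0.99, 0.9999])
        y = shash_quantile(p, params)
        np.testing.assert_allclose(shash_cdf(y, params), p, rtol=1e-10, atol=1e-12)

    def test_quantile_matches_bisection_oracle(self):
        params = ShashParams(1.0, 2.0, 0.5, 1.5)
        direct = float(shash_quantile(0.3, params))
        oracle = _bisect_quantile(lambda y: shash_cdf(y, params), 0.3, -100.0, 100.0)
        assert direct == pytest.approx(oracle, rel=1e-9)

    def test_quantiles_monotone_in_p(self):
        for params in SHASH_GRID:
            q = shash_quantile(np.array([0.01, 0.05, 0.10]), params)
            assert q[0] < q[1] < q[2]

    @pytest.mark.parametrize("params", SHASH_GRID)
    def test_pdf_integrates_to_one(self, params):
        lo = float(shash_quantile(1e-12, params))
        hi = float(shash_quantile(1 - 1e-12, params))
        total, _ = integrate.quad(
            lambda y: np.exp(shash_logpdf(y, params)), lo, hi, limit=200
        )
        assert total == pytest.approx(1.0, abs=1e-6)

    def test_logpdf_standard_normal_at_zero(self):
        assert shash_logpdf(0.0, ShashParams(0, 1, 0, 1)) == pytest.approx(
            -0.9189385332046727, abs=1e-12
        )

    def test_logpdf_finite_deep_in_tails(self):
        params = ShashParams(0.0, 1.0, 0.0, 2.0)
        y = np.array([-20.0, 20.0])
        assert np.all(np.isfinite(shash_logpdf(y, params)))

    def test_affine_equivariance(self):
        """Quantiles of a + b*Y equal a + b*quantile(Y) for b > 0."""
        base = ShashParams(1.0, 2.0, 0.5, 1.3)
        a, b = 10.0, 3.0
        moved = ShashParams(a + b * base.location, b * base.scale, base.skew, base.tail)
        p = np.array([0.01, 0.25, 0.5, 0.9])
        np.testing.assert_allclose(
            shash_quantile(p, moved), a + b * shash_quantile(p, base), rtol=1e-12
        )

    def test_invalid_params_and_domain(self):
        with pytest.raises(InvalidParameterError):
            ShashParams(0, -1.0, 0, 1)
        with pytest.raises(InvalidParameterError):
            ShashParams(0, 1.0, 0, 0.0)
        with pytest.raises(ValueError):
            shash_quantile(0.0, ShashParams(0, 1, 0, 1))
        with pytest.raises(ValueError):
            shash_quantile(1.5, ShashParams(0, 1, 0, 1))


class TestBct:
    def test_median_is_location(self):
        assert bct_quantile(0.5, BctParams(6000, 0.05, 1, 30)) == pytest.approx(6000.0)

    @pytest.mark.parametrize("params", BCT_GRID)
    def test_cdf_quantile_roundtrip(self, params):
        p = np.array([0.001, 0.01, 0.05, 0.5, 0.95, 0.999])
        y = bct_quantile(p, params)
        np.testing.assert_allclose(bct_cdf(y, params), p, rtol=1e-10, atol=1e-12)

    def test_quantile_matches_bisection_oracle(self):
        params = BctParams(5000.0, 0.06, 0.3, 8.0)
        direct = float(bct_quantile(0.05, params))
        oracle = _bisect_quantile(lambda y: bct_cdf(y, params), 0.05, 1.0, 50000.0)
        assert direct == pytest.approx(oracle, rel=1e-8)

    def test_gaussian_limit(self):
        """power=1, dof -> inf: quantiles approach Gaussian(loc, loc*scale)."""
        s = 0.05
        params = BctParams(6000.0, s, 1.0, 1e6)
        p = np.array([0.01, 0.1, 0.5, 0.9, 0.99])
        gauss = 6000.0 + 6000.0 * s * stats.norm.ppf(p)
        np.testing.assert_allclose(bct_quantile(p, params), gauss, rtol=1e-3)

    @pytest.mark.parametrize("params", BCT_GRID)
    def test_pdf_integrates_to_one(self, params):
        """Quadrature in log-y space (stable for the heavy power<0 tail)."""
        eps = 1e-8
        lo = float(bct_quantile(eps, params))
        hi = float(bct_quantile(1 - eps, params))
        total, _ = integrate.quad(
            lambda t: np.exp(bct_logpdf(np.exp(t), params) + t),
            np.log(lo), np.log(hi), limit=400,
        )
        assert total == pytest.approx(1.0 - 2 * eps, abs=1e-5)

    def test_domain_and_param_errors(self):
        with pytest.raises(ValueError):
            bct_cdf(-1.0, BctParams(1, 0.1, 1, 5))
        with pytest.raises(ValueError):
            bct_quantile(1.0, BctParams(1, 0.1, 1, 5))
        with pytest.raises(InvalidParameterError):
            BctParams(0.0, 0.1, 1, 5)
        with pytest.raises(InvalidParameterError):
            BctParams(1.0, 0.1, 1, -2)
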