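"""Angle transform, density, moments, CDF and sampling of the SNP family."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate
from scipy.stats import kstest

from snpmix.snp_density import (
    SNPParams,
    coeffs_from_angles,
    restriction_value,
    snp_cdf,
    snp_logpdf,
    snp_moments,
    snp_pdf,
    snp_sample,
)

PI2 = math.pi / 2


def quad_moments(p: SNPParams) -> tuple[float, float]:
    """Independent quadrature oracle for the density moments."""
    lo, hi = p.u - 15 * p.v, p.u + 15 * p.v
    m1 = integrate.quad(lambda z: z * snp_pdf(p, z), lo, hi, limit=200)[0]
    m2 = integrate.quad(lambda z: z * z * snp_pdf(p, z), lo, hi, limit=200)[0]
    return m1, math.sqrt(m2 - m1**2)


class TestCoeffsFromAngles:
    @pytest.mark.parametrize(
        "K, angles, expected",
        [
            (0, (), (1.0,)),
            (1, (PI2,), (1.0, 0.0)),
            # oracle-verified against the unit-integral restriction
            (2, (2.0, 2.75), (0.637312, -0.158827, 0.271985)),
        ],
    )
    def test_examples(self, K, angles, expected):
        np.testing.assert_allclose(coeffs_from_angles(K, angles), expected, atol=1e-6)

    def test_unsupported_order_raises(self):
        with pytest.raises(ValueError):
            coeffs_from_angles(3, (0.1, 0.2, 0.3))
        with pytest.raises(ValueError):
            coeffs_from_angles(2, (0.1,))

    @pytest.mark.parametrize("K", [1, 2])
    def test_restriction_holds_for_random_angles(self, K, rng):
        for _ in range(200):
            a = coeffs_from_angles(K, rng.uniform(-10, 10, K))
            assert restriction_value(a) == pytest.approx(1.0, abs=1e-10)


@given(st.lists(st.floats(-10, 10, allow_nan=False), min_size=1, max_size=2))
@settings(max_examples=60, deadline=None, derandomize=True)
def test_restriction_is_invariant_of_angles(angles):
    """The unit-integral restriction holds identically over the angle space."""
    a = coeffs_from_angles(len(angles), angles)
    assert restriction_value(a) == pytest.approx(1.0, abs=1e-10)


@given(
    st.floats(-6, 6, allow_nan=False),
    st.floats(-6, 6, allow_nan=False),
    st.floats(-4.0, 4.0, allow_nan=False),
    st.floats(-4.0, 4.0, allow_nan=False),
)
@settings(max_examples=40, deadline=None, derandomize=True)
def test_cdf_bounded_and_monotone(phi1, phi2, z1, z2):
    p = SNPParams(2, (phi1, phi2), 0.0, 1.0)
    lo, hi = sorted((z1, z2))
    c_lo, c_hi = snp_cdf(p, lo), snp_cdf(p, hi)
    assert 0.0 <= c_lo <= c_hi <= 1.0


class TestLogpdf:
    def test_standard_normal_at_zero(self):
        p = SNPParams(0, (), 0.0, 1.0)
        assert snp_logpdf(p, 0.0) == pytest.approx(math.log(1 / math.sqrt(2 * math.pi)))

    def test_k1_reduces_to_normal_at_mean(self):
        p = SNPParams(1, (PI2,), 3.0, 2.0)
        assert snp_logpdf(p, 3.0) == pytest.approx(math.log(1 / (2 * math.sqrt(2 * math.pi))))

    def test_k2_value_matches_quadrature_verified_constant(self):
        # hand/quadrature evaluation with the oracle-verified coefficients
        p = SNPParams(2, (2.0, 2.75), 0.0, 1.0)
        assert snp_logpdf(p, 1.0) == pytest.approx(-1.9930486, abs=1e-6)

    def test_density_zero_gives_minus_inf(self):
        p = SNPParams(1, (0.0,), 0.0, 1.0)  # a0=0, a1=1: zero at z=u
        assert snp_logpdf(p, 0.0) == -np.inf

    @pytest.mark.parametrize(
        "params",
        [SNPParams(0, (), 1.0, 0.7), SNPParams(1, (2.17,), -3.0, 2.0), SNPParams(2, (2.0, 2.75), 5.0, 1.5)],
    )
    def test_integrates_to_one(self, params):
        total = integrate.quad(
            lambda z: snp_pdf(params, z), params.u - 15 * params.v, params.u + 15 * params.v, limit=200
        )[0]
        assert total == pytest.approx(1.0, abs=1e-8)


class TestMoments:
    def test_k0_is_location_scale(self):
        assert snp_moments(SNPParams(0, (), 2.5, 0.3)) == pytest.approx((2.5, 0.3))

    @pytest.mark.parametrize(
        "params, mean, sd",
        [
            (SNPParams(1, (2.17,), 19.4, 3.0), 16.6056, 2.6300),
            (SNPParams(2, (2.0, 2.75), 18.0, 2.0), 17.0767, 3.1103),
        ],
    )
    def test_known_values(self, params, mean, sd):
        m, s = snp_moments(params)
        assert m == pytest.approx(mean, abs=1e-3)
        assert s == pytest.approx(sd, abs=1e-3)

    def test_agrees_with_quadrature_for_random_params(self, rng):
        for _ in range(10):
            K = int(rng.integers(0, 3))
            p = SNPParams(K, tuple(rng.uniform(-4, 4, K)), float(rng.normal(0, 5)), float(rng.uniform(0.3, 3)))
            m, s = snp_moments(p)
            qm, qs = quad_moments(p)
            assert m == pytest.approx(qm, abs=1e-6)
            assert s == pytest.approx(qs, abs=1e-6)


class TestCdf:
    def test_median_of_symmetric_core(self):
        assert snp_cdf(SNPParams(0, (), 0.0, 1.0), 0.0) == pytest.approx(0.5)

    def test_tails(self):
        p = SNPParams(2, (1.3, -0.4), 2.0, 0.5)
        assert snp_cdf(p, p.u - 12 * p.v) < 1e-6
        assert snp_cdf(p, p.u + 12 * p.v) > 1 - 1e-6

    def test_matches_quadrature(self):
        p = SNPParams(2, (2.0, 2.75), 0.0, 1.0)
        for x in (-2.0, 0.0, 0.7, 3.0):
            num = integrate.quad(lambda z: snp_pdf(p, z), p.u - 15 * p.v, x, limit=200)[0]
            assert snp_cdf(p, x) == pytest.approx(num, abs=1e-8)

    def test_monotone(self, rng):
        p = SNPParams(2, tuple(rng.uniform(-4, 4, 2)), 0.0, 1.0)
        grid = np.linspace(-8, 8, 400)
        c = np.asarray(snp_cdf(p, grid))
        assert np.all(np.diff(c) >= -1e-12)


class TestSampling:
    def test_deterministic_under_seed(self):
        p = SNPParams(1, (2.17,), 1.0, 2.0)
        np.testing.assert_array_equal(snp_sample(p, 100, 7), snp_sample(p, 100, 7))

    def test_mean_within_clt_bound(self):
        x = snp_sample(SNPParams(0, (), 5.0, 2.0), 100_000, 3)
        assert abs(x.mean() - 5.0) < 3 * 2.0 / math.sqrt(100_000)

    def test_ks_distance_to_cdf(self):
        p = SNPParams(2, (2.0, 2.75), 0.0, 1.0)
        x = snp_sample(p, 100_000, 11)
        d = kstest(x, lambda v: np.asarray(snp_cdf(p, v))).statistic
        assert d < 0.01


class TestSNPParams:
    def test_invalid_scale_rejected(self):
        with pytest.raises(ValueError):
            SNPParams(0, (), 0.0, -1.0)

    def test_angle_length_checked(self):
        with pytest.raises(ValueError):
            SNPParams(2, (0.3,), 0.0, 1.0)

    def test_json_round_trip(self):
        p = SNPParams(2, (0.4, -1.2), 3.5, 0.8)
        assert SNPParams.from_json(p.to_json()) == p
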