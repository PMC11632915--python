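"""Unit and property tests for the closed-form model algebra."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cirbe import (
    LQMParams,
    ModelParameters,
    RadiosensitivityEndpoint,
    alpha_beta_from_endpoints,
    dose_at_survival,
    intercept_quadratic,
    lqm_from_endpoint_set,
    poisson_lethal_lesion_mean,
    predict_cion_lqm,
    predict_endpoints,
    rbe_at_dose,
    rbe_at_survival,
    slope_inverse_linear,
    slope_inverse_linear_squared,
    survival_fraction,
)

E3 = math.exp(-3)
E1 = math.exp(-1)


class TestSurvivalFraction:
    @pytest.mark.parametrize(
        "alpha,beta,dose,expected",
        [
            (0.3, 0.03, 0.0, 1.0),
            (1.0, 0.0, 3.0, math.exp(-3)),
            (13 / 30, 1 / 30, 2.0, math.exp(-1)),
        ],
    )
    def test_values(self, alpha, beta, dose, expected):
        assert survival_fraction(LQMParams(alpha, beta), dose) == pytest.approx(
            expected, rel=1e-12
        )

    def test_negative_dose_rejected(self):
        with pytest.raises(ValueError):
            survival_fraction(LQMParams(0.3, 0.03), -1.0)

    def test_degenerate_curve_rejected(self):
        with pytest.raises(ValueError):
            LQMParams(0.0, 0.0)
        with pytest.raises(ValueError):
            LQMParams(-0.1, 0.05)


class TestDoseAtSurvival:
    @pytest.mark.parametrize(
        "alpha,beta,sf,expected",
        [
            (1.0, 0.0, E3, 3.0),
            (0.5, 0.05, E3, (-0.5 + math.sqrt(0.25 + 0.6)) / 0.1),
            (0.0, 1.0, E1, 1.0),
        ],
    )
    def test_values(self, alpha, beta, sf, expected):
        assert dose_at_survival(LQMParams(alpha, beta), sf) == pytest.approx(
            expected, rel=1e-12
        )

    @pytest.mark.parametrize("sf", [0.0, 1.0, -0.2, 1.5])
    def test_domain(self, sf):
        with pytest.raises(ValueError):
            dose_at_survival(LQMParams(0.5, 0.05), sf)

    @given(
        alpha=st.one_of(st.just(0.0), st.floats(1e-4, 2.0)),
        beta=st.one_of(st.just(0.0), st.floats(1e-5, 0.2)),
        sf=st.floats(0.001, 0.999),
    )
    @settings(derandomize=True, deadline=None, max_examples=200)
    def test_inversion_round_trip(self, alpha, beta, sf):
        """survival_fraction(dose_at_survival(sf)) == sf to 1e-10 relative."""
        if alpha == 0 and beta == 0:
            return
        lqm = LQMParams(alpha, beta)
        dose = dose_at_survival(lqm, sf)
        assert survival_fraction(lqm, dose) == pytest.approx(sf, rel=1e-10)

    def test_tiny_beta_stable(self):
        """The root form must not lose precision as beta -> 0."""
        lqm = LQMParams(0.5, 1e-14)
        dose = dose_at_survival(lqm, E1)
        assert dose == pytest.approx(2.0, rel=1e-10)


class TestTrendFunctions:
    def test_slope_values(self, published):
        assert slope_inverse_linear(0.0, 0.37) == 1.0
        assert slope_inverse_linear(100.0, 0.01) == pytest.approx(0.5)
        assert slope_inverse_linear(60.5, published.f1) == pytest.approx(
            0.441011, abs=5e-7
        )
        assert slope_inverse_linear_squared(0.0, 0.37) == 1.0
        assert slope_inverse_linear_squared(100.0, 0.01) == pytest.approx(0.25)
        assert slope_inverse_linear_squared(60.5, published.f1) == pytest.approx(
            0.194491, abs=5e-7
        )

    def test_slope_monotone_decreasing(self, published):
        lets = np.linspace(0.0, 350.0, 200)
        for fn in (slope_inverse_linear, slope_inverse_linear_squared):
            vals = fn(lets, published.f1)
            assert vals[0] == 1.0
            assert np.all(np.diff(vals) < 0)

    def test_slope_domain(self):
        with pytest.raises(ValueError):
            slope_inverse_linear(100.0, -0.02)
        with pytest.raises(ValueError):
            slope_inverse_linear(-1.0, 0.02)

    def test_intercept_values(self, published):
        assert intercept_quadratic(0.0, 1.23, published.m1) == published.m1
        assert intercept_quadratic(10.0, 0.0, 0.0) == 0.0
        assert intercept_quadratic(60.5, published.q1, published.m1) == pytest.approx(
            0.673652, abs=5e-7
        )


class TestPredictEndpoints:
    def test_zero_let_shift(self, published):
        d3, d1 = predict_endpoints(5.0, 2.0, 0.0, published)
        assert d3 == pytest.approx(5.0 + published.m1, rel=1e-12)
        assert d1 == pytest.approx(2.0, rel=1e-12)

    def test_mid_let(self, published):
        d3, d1 = predict_endpoints(5.0, 2.0, 60.5, published)
        assert d3 == pytest.approx(2.87871, abs=5e-6)
        assert d1 == pytest.approx(0.85120, abs=5e-6)

    def test_identity_limit(self, published):
        params = ModelParameters(f1=published.f1, m1=0.0, q1=0.0, f2=published.f2)
        assert predict_endpoints(3.0, 1.0, 0.0, params) == pytest.approx((3.0, 1.0))

    def test_nonpositive_rejected(self, published):
        with pytest.raises(ValueError):
            predict_endpoints(-1.0, 2.0, 10.0, published)


class TestEndpointConversion:
    @pytest.mark.parametrize(
        "d3,d1,alpha,beta,branch",
        [
            (3.0, 1.0, 1.0, 0.0, "unconstrained"),
            # sqrt(3) is the exact alpha=0 boundary: either branch label is
            # acceptable in floating point, the values are identical.
            (math.sqrt(3.0), 1.0, 0.0, 1.0, None),
            (5.0, 2.0, 13 / 30, 1 / 30, "unconstrained"),
            (4.0, 1.0, 13 / 17, 0.0, "beta_zeroed"),
        ],
    )
    def test_examples(self, d3, d1, alpha, beta, branch):
        lqm, got_branch = alpha_beta_from_endpoints(d3, d1)
        if branch is not None:
            assert got_branch == branch
        assert lqm.alpha == pytest.approx(alpha, rel=1e-12, abs=1e-12)
        assert lqm.beta == pytest.approx(beta, rel=1e-12, abs=1e-12)

    def test_ordering_error(self):
        with pytest.raises(ValueError):
            alpha_beta_from_endpoints(1.0, 2.0)
        with pytest.raises(ValueError):
            alpha_beta_from_endpoints(2.0, 2.0)

    def test_exact_interpolation_oracle(self):
        """Unconstrained output reproduces both endpoints and the 2x2 solve."""
        rng = np.random.default_rng(0)
        d1 = rng.uniform(0.2, 6.0, 10_000)
        d3 = d1 * rng.uniform(math.sqrt(3.0), 3.0, 10_000)
        for a, b in zip(d3[:500], d1[:500]):
            lqm, branch = alpha_beta_from_endpoints(a, b)
            # independent oracle: direct 2x2 linear solve
            sol = np.linalg.solve([[a, a**2], [b, b**2]], [3.0, 1.0])
            assert lqm.alpha == pytest.approx(sol[0], rel=1e-10, abs=1e-12)
            assert lqm.beta == pytest.approx(sol[1], rel=1e-10, abs=1e-12)
            assert survival_fraction(lqm, a) == pytest.approx(E3, rel=1e-9)
            assert survival_fraction(lqm, b) == pytest.approx(E1, rel=1e-9)

    @pytest.mark.parametrize("ratio,branch", [(3.5, "beta_zeroed"), (1.3, "alpha_zeroed")])
    def test_constrained_branch_grid_oracle(self, ratio, branch):
        """Constrained closed forms match a dense 1-D grid least-squares search."""
        rng = np.random.default_rng(1)
        lethality = np.array([3.0, 1.0])
        for d1 in rng.uniform(0.3, 4.0, 50):
            d3 = ratio * d1
            doses = np.array([d3, d1])
            lqm, got = alpha_beta_from_endpoints(d3, d1)
            assert got == branch
            if branch == "beta_zeroed":
                grid = np.linspace(0.0, 4.0 * lqm.alpha, 200_001)
                loss = ((grid[:, None] * doses - lethality) ** 2).sum(axis=1)
                assert abs(lqm.alpha - grid[np.argmin(loss)]) <= grid[1] - grid[0]
            else:
                grid = np.linspace(0.0, 4.0 * lqm.beta, 200_001)
                loss = ((grid[:, None] * doses**2 - lethality) ** 2).sum(axis=1)
                assert abs(lqm.beta - grid[np.argmin(loss)]) <= grid[1] - grid[0]

    @given(d1=st.floats(0.05, 8.0), ratio=st.floats(1.0001, 12.0))
    @settings(derandomize=True, deadline=None, max_examples=300)
    def test_branch_exclusivity_and_validity(self, d1, ratio):
        """No endpoint pair triggers both constraints; output is always a valid LQ."""
        lqm, branch = alpha_beta_from_endpoints(d1 * ratio, d1)
        assert lqm.alpha >= 0 and lqm.beta >= 0
        if branch == "beta_zeroed":
            assert d1 * ratio > 3.0 * d1 * (1 - 1e-12)
        if branch == "alpha_zeroed":
            assert d1 * ratio < math.sqrt(3.0) * d1 * (1 + 1e-12)


class TestLqmFromEndpointSet:
    def test_two_endpoint_reduction(self):
        eps = [RadiosensitivityEndpoint(E3, 5.0), RadiosensitivityEndpoint(E1, 2.0)]
        alpha, beta = lqm_from_endpoint_set(eps)
        assert alpha == pytest.approx(13 / 30, rel=1e-10)
        assert beta == pytest.approx(1 / 30, rel=1e-10)

    def test_collinear_exponential(self):
        eps = [
            RadiosensitivityEndpoint(math.exp(-k), float(k)) for k in (1, 2, 3)
        ]
        alpha, beta = lqm_from_endpoint_set(eps)
        assert alpha == pytest.approx(1.0, rel=1e-10)
        assert beta == pytest.approx(0.0, abs=1e-10)

    def test_pure_quadratic(self):
        eps = [
            RadiosensitivityEndpoint(math.exp(-k), math.sqrt(k)) for k in (1, 2, 3)
        ]
        alpha, beta = lqm_from_endpoint_set(eps)
        assert alpha == pytest.approx(0.0, abs=1e-10)
        assert beta == pytest.approx(1.0, rel=1e-10)

    def test_matches_lstsq_oracle(self):
        """The printed sum formulas equal the OLS normal-equation solution."""
        rng = np.random.default_rng(3)
        for _ in range(50):
            doses = rng.uniform(0.5, 8.0, 4)
            sfs = np.exp(-rng.uniform(0.3, 3.5, 4))
            eps = [RadiosensitivityEndpoint(s, d) for s, d in zip(sfs, doses)]
            alpha, beta = lqm_from_endpoint_set(eps)
            design = np.column_stack([doses, doses**2])
            expected, *_ = np.linalg.lstsq(design, -np.log(sfs), rcond=None)
            assert alpha == pytest.approx(expected[0], rel=1e-8, abs=1e-10)
            assert beta == pytest.approx(expected[1], rel=1e-8, abs=1e-10)

    def test_rank_error(self):
        eps = [RadiosensitivityEndpoint(E3, 2.0), RadiosensitivityEndpoint(E1, 2.0)]
        with pytest.raises(ValueError):
            lqm_from_endpoint_set(eps)

    def test_reduction_matches_random_pairs(self):
        """With two generic endpoints the OLS solution is the exact interpolant."""
        rng = np.random.default_rng(4)
        d1 = rng.uniform(0.2, 6.0, 10_000)
        d3 = d1 * rng.uniform(math.sqrt(3.0), 3.0, 10_000)
        # vectorized closed forms on both routes
        denom = d1 * d3**2 - d3 * d1**2
        alpha_direct = (d3**2 - 3 * d1**2) / denom
        beta_direct = (3 * d1 - d3) / denom
        s2, s3, s4 = d3**2 + d1**2, d3**3 + d1**3, d3**4 + d1**4
        sdl = d3 * (-3.0) + d1 * (-1.0)
        sd2l = d3**2 * (-3.0) + d1**2 * (-1.0)
        den = s3 * s3 - s2 * s4
        alpha_ols = (s4 * sdl - s3 * sd2l) / den
        beta_ols = (s2 * sd2l - s3 * sdl) / den
        np.testing.assert_allclose(alpha_ols, alpha_direct, rtol=1e-10, atol=1e-14)
        np.testing.assert_allclose(beta_ols, beta_direct, rtol=1e-10, atol=1e-14)


class TestPredictCionLqm:
    def test_zero_let_identity(self, published):
        params = ModelParameters(f1=published.f1, m1=0.0, q1=0.0, f2=published.f2)
        photon = LQMParams(0.3, 0.03)
        res = predict_cion_lqm(photon, 0.0, params)
        assert res.lqm_cion.alpha == pytest.approx(0.3, abs=1e-8)
        assert res.lqm_cion.beta == pytest.approx(0.03, abs=1e-8)

    def test_high_let_beta_zeroed(self, published):
        res = predict_cion_lqm(LQMParams(0.3, 0.03), 200.0, published)
        assert res.branch == "beta_zeroed"
        assert res.lqm_cion.beta == 0.0

    def test_self_consistency(self, published):
        """When unconstrained, the curve passes through its own endpoints."""
        res = predict_cion_lqm(LQMParams(0.2, 0.02), 30.0, published)
        assert res.branch == "unconstrained"
        assert survival_fraction(res.lqm_cion, res.d_e3) == pytest.approx(E3, rel=1e-10)
        assert survival_fraction(res.lqm_cion, res.d_e1) == pytest.approx(E1, rel=1e-10)

    def test_high_let_linearization_threshold(self, published):
        """Above some finite LET every positive-beta photon curve linearizes."""
        for alpha_x, beta_x in [(0.1, 0.02), (0.3, 0.03), (0.6, 0.08)]:
            photon = LQMParams(alpha_x, beta_x)
            branches = [
                predict_cion_lqm(photon, let, published).branch
                for let in np.linspace(1.0, 350.0, 120)
            ]
            assert branches[-1] == "beta_zeroed"
            first = branches.index("beta_zeroed")
            assert all(b == "beta_zeroed" for b in branches[first:])

    def test_overkill_interior_maximum(self, published):
        """RBE at 10% survival peaks at an interior LET for radioresistant cells."""
        photon = LQMParams(0.1, 0.02)
        lets = np.linspace(1.0, 350.0, 200)
        rbe = [
            rbe_at_survival(photon, predict_cion_lqm(photon, l, published).lqm_cion, 0.10)
            for l in lets
        ]
        imax = int(np.argmax(rbe))
        assert 0 < imax < len(lets) - 1
        assert rbe[imax] > rbe[0] and rbe[imax] > rbe[-1]


class TestRBE:
    def test_rbe_at_survival(self):
        photon = LQMParams(0.3, 0.03)
        cion = LQMParams(0.9, 0.0)
        assert rbe_at_survival(photon, photon, 0.37) == pytest.approx(1.0)
        assert rbe_at_survival(photon, cion, 0.10) == pytest.approx(
            5.0873 / 2.5584, abs=2e-4
        )
        assert rbe_at_survival(LQMParams(1, 0), LQMParams(2, 0), 0.42) == pytest.approx(2.0)

    def test_rbe_at_dose(self):
        photon = LQMParams(0.3, 0.03)
        cion = LQMParams(0.9, 0.0)
        assert rbe_at_dose(photon, photon, 1.7) == pytest.approx(1.0)
        assert rbe_at_dose(photon, cion, 2.0) == pytest.approx(4.21954 / 2, abs=1e-5)
        assert rbe_at_dose(LQMParams(1, 0), LQMParams(3, 0), 1.0) == pytest.approx(3.0)

    def test_rbe_at_dose_photon_convention(self):
        """The photon-dose-fixed variant inverts the C-ion curve instead."""
        photon = LQMParams(0.3, 0.03)
        cion = LQMParams(0.9, 0.0)
        dose = 3.0
        sf = survival_fraction(photon, dose)
        expected = dose / dose_at_survival(cion, sf)
        assert rbe_at_dose(photon, cion, dose, fixed="photon") == pytest.approx(expected)
        with pytest.raises(ValueError):
            rbe_at_dose(photon, cion, 2.0, fixed="midpoint")


class TestPoisson:
    def test_values(self):
        assert poisson_lethal_lesion_mean(0.10) == pytest.approx(2.302585, abs=1e-6)
        assert poisson_lethal_lesion_mean(E1) == pytest.approx(1.0, rel=1e-12)
        assert poisson_lethal_lesion_mean(0.05) == pytest.approx(2.9957, abs=1e-4)

    def test_domain(self):
        for sf in (0.0, 1.0, 2.0, -0.5):
            with pytest.raises(ValueError):
                poisson_lethal_lesion_mean(sf)
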