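import math

import pytest
from hypothesis import given
from hypothesis import strategies as st

from panelpower import (
    FrechetError,
    GrossChangeSpecMeans,
    GrossChangeSpecProps,
    InfeasibleDesignError,
    NetChangeSpecMeans,
    NetChangeSpecProps,
    TestParams,
    critical_factor,
    n_gross_means,
    n_gross_props,
    n_net_means,
    n_net_props,
    n_next_wave_means,
    n_next_wave_props,
)

ONE = TestParams(0.05, 0.80, "one")
TWO = TestParams(0.05, 0.80, "two")


class TestCriticalFactor:
    @pytest.mark.parametrize(
        "test, expected",
        [
            (ONE, 6.18256),  # (1.644854 + 0.841621)^2
            (TWO, 7.84888),  # (1.959964 + 0.841621)^2
            (TestParams(0.05, 0.50, "one"), 2.70554),  # power-0.5 quantile is 0
        ],
    )
    def test_known_values(self, test, expected):
        assert critical_factor(test) == pytest.approx(expected, abs=5e-5)


class TestGross:
    def test_means_worked_design(self, means_gross):
        sol = n_gross_means(means_gross)
        assert sol.n == 28
        assert sol.n_raw == pytest.approx(27.478, abs=1e-3)

    def test_means_two_sided(self):
        spec = GrossChangeSpecMeans(delta_gross=3, sigma_o2=200, rho=0.9, test=TWO)
        sol = n_gross_means(spec)
        assert sol.n == 35
        assert sol.n_raw == pytest.approx(34.884, abs=1e-3)

    def test_perfect_correlation_limit_clamps_to_one(self):
        spec = GrossChangeSpecMeans(
            delta_gross=3, sigma_o2=200, rho=1 - 1e-12, test=ONE
        )
        sol = n_gross_means(spec)
        assert sol.n == 1
        assert sol.n_raw < 1e-6

    def test_props_worked_design(self, props_gross):
        sol = n_gross_props(props_gross)
        assert sol.n == 22
        assert sol.n_raw == pytest.approx(21.295, abs=1e-3)

    def test_props_independence(self):
        spec = GrossChangeSpecProps(p_t=0.5, p_t1=0.8, p_xy=0.40, test=ONE)
        sol = n_gross_props(spec)
        assert sol.n == 29
        assert sol.n_raw == pytest.approx(28.165, abs=1e-3)

    def test_props_frechet_violation(self):
        with pytest.raises(FrechetError):
            GrossChangeSpecProps(p_t=0.5, p_t1=0.8, p_xy=0.25, test=ONE)


class TestNet:
    @pytest.mark.parametrize(
        "gamma, n, n_raw", [(0.0, 121, 120.216), (1.0, 14, 13.131)]
    )
    def test_means_overlap_extremes(self, means_net, gamma, n, n_raw):
        sol = n_net_means(means_net, gamma=gamma)
        assert sol.n == n
        assert sol.n_raw == pytest.approx(n_raw, abs=1e-3)

    def test_means_zero_correlation_ignores_gamma(self):
        spec = NetChangeSpecMeans(delta=3, sigma_x2=100, sigma_y2=75, rho=0.0, test=ONE)
        assert n_net_means(spec, gamma=0.7).n_raw == n_net_means(spec, gamma=0.0).n_raw

    @pytest.mark.parametrize("gamma, n, n_raw", [(0.0, 72, 71.099), (1.0, 41, 40.187)])
    def test_props_overlap_extremes(self, props_net, gamma, n, n_raw):
        sol = n_net_props(props_net, gamma=gamma)
        assert sol.n == n
        assert sol.n_raw == pytest.approx(n_raw, abs=1e-3)

    def test_props_independent_joint_ignores_gamma(self):
        spec = NetChangeSpecProps(p_t=0.5, p_t1=0.7, p_xy=0.35, test=ONE)
        assert n_net_props(spec, gamma=0.9).n_raw == pytest.approx(
            n_net_props(spec, gamma=0.0).n_raw, abs=1e-12
        )

    def test_reports_second_wave_size(self, means_net):
        import dataclasses

        spec = dataclasses.replace(means_net, r=2.0)
        sol = n_net_means(spec, gamma=0.5)
        assert sol.components["n_t1"] == math.ceil(sol.n / 2.0)

    def test_deff_scales_linearly(self, means_net):
        base = n_net_means(means_net, gamma=0.5).n_raw
        assert n_net_means(means_net, gamma=0.5, deff=1.8).n_raw == pytest.approx(
            1.8 * base, rel=1e-12
        )


class TestNextWave:
    def test_means_worked_value_and_back_substitution(self):
        spec = NetChangeSpecMeans(delta=3, sigma_x2=100, sigma_y2=100, rho=0.8, test=TWO)
        sol = n_next_wave_means(150, 28, spec)
        assert sol.n == 147
        assert sol.n_raw == pytest.approx(146.113, abs=1e-3)
        # the raw solution must put the estimator variance exactly on target
        c = critical_factor(TWO)
        var = 100 / 150 + 100 / sol.n_raw - 2 * 0.8 * 100 * 28 / (150 * sol.n_raw)
        assert var == pytest.approx(9 / c, abs=1e-9)

    def test_means_infeasible_first_wave(self):
        spec = NetChangeSpecMeans(delta=3, sigma_x2=100, sigma_y2=100, rho=0.8, test=TWO)
        with pytest.raises(InfeasibleDesignError, match="first-wave sample too small"):
            n_next_wave_means(87, 28, spec)

    def test_means_no_overlap_matches_independent_formula(self):
        spec = NetChangeSpecMeans(delta=3, sigma_x2=100, sigma_y2=100, rho=0.8, test=TWO)
        sol = n_next_wave_means(150, 0, spec)
        c = critical_factor(TWO)
        expected = c * 150 * 100 / (150 * 9 - 100 * c)
        assert sol.n_raw == pytest.approx(expected, rel=1e-12)

    def test_props_worked_value(self):
        spec = NetChangeSpecProps(p_t=0.5, p_t1=0.7, p_xy=0.45, test=ONE)
        sol = n_next_wave_props(80, 22, spec)
        assert sol.n == 47
        assert sol.n_raw == pytest.approx(46.340, abs=1e-3)

    def test_props_infeasible_threshold(self):
        spec = NetChangeSpecProps(p_t=0.5, p_t1=0.7, p_xy=0.45, test=ONE)
        with pytest.raises(InfeasibleDesignError):
            n_next_wave_props(38, 22, spec)

    def test_props_independent_joint_matches_no_overlap(self):
        spec = NetChangeSpecProps(p_t=0.5, p_t1=0.7, p_xy=0.35, test=ONE)
        assert n_next_wave_props(80, 22, spec).n_raw == pytest.approx(
            n_next_wave_props(80, 0, spec).n_raw, rel=1e-12
        )

    def test_overlap_already_sufficient_signal(self):
        spec = NetChangeSpecMeans(delta=3, sigma_x2=100, sigma_y2=100, rho=0.99, test=TWO)
        sol = n_next_wave_means(10_000, 9_000, spec)
        assert sol.n == 9_000
        assert any("overlap already sufficient" in w for w in sol.warnings)


test_params = st.builds(
    TestParams,
    alpha=st.sampled_from([0.01, 0.05, 0.10]),
    power=st.sampled_from([0.7, 0.8, 0.9]),
    sided=st.sampled_from(["one", "two"]),
)


class TestProperties:
    @given(
        sigma=st.floats(min_value=0.5, max_value=500),
        delta=st.floats(min_value=0.1, max_value=10),
        rho=st.floats(min_value=-0.95, max_value=0.95),
        test=test_params,
    )
    def test_reduction_identity_means(self, sigma, delta, rho, test):
        """At r=1, gamma=1 and equal variances, the net formula collapses to the gross one."""
        net = NetChangeSpecMeans(
            delta=delta, sigma_x2=sigma, sigma_y2=sigma, rho=rho, r=1.0, test=test
        )
        gross = GrossChangeSpecMeans(delta_gross=delta, sigma_o2=sigma, rho=rho, test=test)
        assert n_net_means(net, gamma=1.0).n_raw == pytest.approx(
            n_gross_means(gross).n_raw, abs=1e-9, rel=1e-9
        )

    @given(
        p_t=st.floats(min_value=0.05, max_value=0.95),
        p_t1=st.floats(min_value=0.05, max_value=0.95),
        u=st.floats(min_value=0.0, max_value=1.0),
        test=test_params,
    )
    def test_reduction_identity_props(self, p_t, p_t1, u, test):
        if abs(p_t - p_t1) < 1e-3:
            return
        lo = max(0.0, p_t + p_t1 - 1.0)
        hi = min(p_t, p_t1)
        p_xy = lo + u * (hi - lo)
        net = NetChangeSpecProps(p_t=p_t, p_t1=p_t1, p_xy=p_xy, r=1.0, test=test)
        gross = GrossChangeSpecProps(p_t=p_t, p_t1=p_t1, p_xy=p_xy, test=test)
        assert n_net_props(net, gamma=1.0).n_raw == pytest.approx(
            n_gross_props(gross).n_raw, abs=1e-9, rel=1e-9
        )

    @given(
        n_t=st.integers(min_value=100, max_value=5000),
        gamma=st.floats(min_value=0.0, max_value=1.0),
        sigma_x2=st.floats(min_value=1, max_value=200),
        sigma_y2=st.floats(min_value=1, max_value=200),
        rho=st.floats(min_value=-0.9, max_value=0.9),
        test=test_params,
    )
    def test_back_substitution_means(self, n_t, gamma, sigma_x2, sigma_y2, rho, test):
        """The solved second-wave size puts the estimator variance at delta^2/C."""
        c = critical_factor(test)
        # choose delta so the first wave comfortably clears the feasibility bound
        delta = math.sqrt(2.0 * sigma_x2 * c / n_t)
        spec = NetChangeSpecMeans(
            delta=delta, sigma_x2=sigma_x2, sigma_y2=sigma_y2, rho=rho, test=test
        )
        n11 = int(gamma * n_t)
        sol = n_next_wave_means(n_t, n11, spec)
        if sol.warnings:  # overlap-sufficient clamp: identity no longer applies
            return
        sxsy = math.sqrt(sigma_x2 * sigma_y2)
        var = (
            sigma_x2 / n_t
            + sigma_y2 / sol.n_raw
            - 2 * rho * sxsy * n11 / (n_t * sol.n_raw)
        )
        assert var == pytest.approx(delta**2 / c, abs=1e-9, rel=1e-9)

    @given(
        n_t=st.integers(min_value=200, max_value=5000),
        gamma=st.floats(min_value=0.0, max_value=1.0),
        p_t=st.floats(min_value=0.1, max_value=0.9),
        p_t1=st.floats(min_value=0.1, max_value=0.9),
        u=st.floats(min_value=0.0, max_value=1.0),
    )
    def test_back_substitution_props(self, n_t, gamma, p_t, p_t1, u):
        if abs(p_t - p_t1) < 0.05:
            return
        test = TestParams(0.05, 0.8, "two")
        c = critical_factor(test)
        lo = max(0.0, p_t + p_t1 - 1.0)
        hi = min(p_t, p_t1)
        spec = NetChangeSpecProps(p_t=p_t, p_t1=p_t1, p_xy=lo + u * (hi - lo), test=test)
        if n_t * spec.delta**2 - p_t * (1 - p_t) * c < 0.05:
            return  # too near the feasibility boundary for a stable check
        n11 = int(gamma * n_t)
        sol = n_next_wave_props(n_t, n11, spec)
        if sol.warnings:
            return
        cov = spec.p_xy - p_t * p_t1
        var = (
            p_t * (1 - p_t) / n_t
            + p_t1 * (1 - p_t1) / sol.n_raw
            - 2 * cov * n11 / (n_t * sol.n_raw)
        )
        assert var == pytest.approx(spec.delta**2 / c, abs=1e-9, rel=1e-9)

    @given(
        delta=st.floats(min_value=0.5, max_value=5),
        scale=st.floats(min_value=0.01, max_value=100),
        gamma=st.floats(min_value=0.0, max_value=1.0),
        rho=st.floats(min_value=-0.9, max_value=0.9),
    )
    def test_scale_invariance_means(self, delta, scale, gamma, rho):
        """Multiplying delta, sigma_x and sigma_y by a constant leaves n unchanged."""
        base = NetChangeSpecMeans(delta=delta, sigma_x2=100, sigma_y2=60, rho=rho, test=ONE)
        scaled = NetChangeSpecMeans(
            delta=delta * scale,
            sigma_x2=100 * scale**2,
            sigma_y2=60 * scale**2,
            rho=rho,
            test=ONE,
        )
        assert n_net_means(scaled, gamma).n_raw == pytest.approx(
            n_net_means(base, gamma).n_raw, rel=1e-9
        )

    def test_monotonicity_in_gamma_rho_deff(self, means_net):
        gammas = [0.0, 0.25, 0.5, 0.75, 1.0]
        sizes = [n_net_means(means_net, g).n_raw for g in gammas]
        assert all(a > b for a, b in zip(sizes, sizes[1:]))
        import dataclasses

        rhos = [0.0, 0.3, 0.6, 0.9]
        sizes = [
            n_net_means(dataclasses.replace(means_net, rho=r), 0.5).n_raw for r in rhos
        ]
        assert all(a > b for a, b in zip(sizes, sizes[1:]))
        deffs = [1.0, 1.5, 2.0]
        sizes = [n_net_means(means_net, 0.5, deff=d).n_raw for d in deffs]
        assert all(a < b for a, b in zip(sizes, sizes[1:]))
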