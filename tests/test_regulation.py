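"""The RI geometry: spline fit, reference lines, areas, both branches."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from oxyreg import (
    DegenerateProfileError,
    RateProfile,
    RegulationIndex,
    build_reference_lines,
    compute_ri,
    fit_response_curve,
    integrate_auc,
    ri_batch,
)
from oxyreg.preprocessing import qc_filter

from conftest import make_powerlaw_profile


class TestResponseCurve:
    def test_reproduces_linear_data(self):
        x = np.linspace(10, 100, 8)
        curve = fit_response_curve(do=x, rate=0.03 * x)
        grid = np.linspace(10, 100, 200)
        assert np.allclose(curve(grid), 0.03 * grid, atol=1e-10)

    def test_reproduces_constant_data(self):
        x = np.linspace(10, 100, 8)
        curve = fit_response_curve(do=x, rate=np.full(8, 1.4))
        assert np.allclose(curve(np.linspace(10, 100, 50)), 1.4, atol=1e-12)

    def test_interpolates_knots_of_cubic(self):
        x = np.linspace(5, 95, 10)
        y = 1e-4 * x**3 - 0.01 * x**2 + 0.5 * x
        curve = fit_response_curve(do=x, rate=y)
        assert np.max(np.abs(curve(x) - y)) < 1e-8

    def test_duplicate_oxygen_mean_aggregated(self):
        curve = fit_response_curve(do=[10, 10, 50, 100], rate=[1.0, 3.0, 2.0, 2.0])
        assert curve(10) == pytest.approx(2.0)

    def test_degenerate_profile_rejected(self):
        with pytest.raises(DegenerateProfileError):
            fit_response_curve(do=[10, 10, 10, 50], rate=[1, 1, 1, 2])


class TestReferenceLines:
    def test_constant_curve(self):
        refs = build_reference_lines(lambda x: np.full_like(np.asarray(x, float), 3.0), 10, 100)
        assert refs.conformity_slope == pytest.approx(0.03)
        assert refs.regulation_level == pytest.approx(3.0)

    def test_proportional_curve(self):
        refs = build_reference_lines(lambda x: 0.05 * np.asarray(x, float), 10, 100)
        assert refs.conformity_slope == pytest.approx(0.05)
        assert refs.regulation_level == pytest.approx(5.0)

    def test_interior_maximum_found(self):
        # quadratic peaking at DO = 60 inside [10, 100]: max = 2.0, endpoint lower
        f = lambda x: 2.0 - 1e-3 * (np.asarray(x, float) - 60.0) ** 2
        refs = build_reference_lines(f, 10, 100, grid_size=2001)
        assert refs.regulation_level == pytest.approx(2.0, abs=1e-5)
        assert refs.regulation_level > f(100.0)


class TestIntegrateAuc:
    def test_constant_and_linear(self):
        assert integrate_auc(lambda x: 2.0, 0, 10) == pytest.approx(20.0)
        assert integrate_auc(lambda x: x, 0, 10) == pytest.approx(50.0)

    def test_matches_dense_trapezoid_on_random_splines(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            x = np.sort(rng.uniform(5, 100, 7))
            y = rng.uniform(0.1, 2.0, 7)
            curve = fit_response_curve(do=x, rate=y)
            lo, hi = x[0], x[-1]
            grid = np.linspace(lo, hi, 100_000)
            oracle = np.trapezoid(curve(grid), grid)
            assert integrate_auc(curve, lo, hi) == pytest.approx(oracle, rel=1e-6)

    def test_bad_bounds(self):
        with pytest.raises(ValueError):
            integrate_auc(lambda x: 1.0, 5, 5)


class TestComputeRi:
    def test_perfect_regulator_is_one(self, regulator_profile):
        res = compute_ri(regulator_profile)
        assert res.ri == pytest.approx(1.0, abs=1e-9)
        assert res.branch == "positive"

    def test_perfect_conformer_is_zero(self, conformer_profile):
        res = compute_ri(conformer_profile)
        assert res.ri == pytest.approx(0.0, abs=1e-9)

    def test_floor_profile_is_minus_one(self):
        # respiration collapsed to zero everywhere except the normoxic anchor
        do = np.linspace(100, 0, 50)
        rate = np.zeros(50)
        rate[0] = 1.0
        res = compute_ri(RateProfile("floor", do, rate))
        assert res.ri == pytest.approx(-1.0, abs=0.05)
        assert res.branch in ("negative", "mixed")

    @pytest.mark.parametrize("gamma", [0.0, 0.25, 0.5, 1.0, 2.0, 3.0, 5.0])
    def test_power_law_closed_form(self, gamma):
        # analytic: RI = 2/(gamma+1) - 1 on the full oxygen range
        res = compute_ri(make_powerlaw_profile(gamma))
        assert res.ri == pytest.approx(2.0 / (gamma + 1.0) - 1.0, abs=0.01)

    def test_branch_switch_continuous_near_gamma_one(self):
        lo = compute_ri(make_powerlaw_profile(0.95)).ri
        hi = compute_ri(make_powerlaw_profile(1.05)).ri
        assert lo > 0 > hi
        assert abs(lo - hi) < 0.06

    def test_michaelis_saturation_value(self):
        # rate = DO/(25+DO) on [0,100]: A_c = 100 - 25 ln 5, A_f = 40, A_r = 80
        do = np.linspace(100, 0, 400)
        res = compute_ri(RateProfile("mm", do, do / (25.0 + do)))
        expected = (100.0 - 25.0 * np.log(5.0) - 40.0) / 40.0
        assert expected == pytest.approx(0.494, abs=5e-4)
        assert res.ri == pytest.approx(expected, abs=0.005)

    def test_area_components_consistent(self, regulator_profile):
        res = compute_ri(regulator_profile)
        assert res.auc_regulation >= res.auc_curve - 1e-9
        assert res.do_lo_pct < res.do_hi_pct
        recomputed = (res.auc_curve - res.auc_conformity) / (
            res.auc_regulation - res.auc_conformity
        )
        assert res.ri == pytest.approx(recomputed)

    def test_qc_failed_profile_rejected(self, conformer_profile):
        bad = qc_filter(conformer_profile, max_min_frac=0.05)
        assert not bad.qc_pass
        with pytest.raises(ValueError, match="QC"):
            compute_ri(bad)

    def test_degenerate_geometry_flat_zero(self):
        do = np.linspace(100, 10, 10)
        with pytest.raises(DegenerateProfileError, match="degenerate"):
            compute_ri(RateProfile("z", do, np.zeros(10)))

    def test_summary_mentions_ri(self, regulator_profile):
        text = compute_ri(regulator_profile).summary()
        assert "RI" in text and "reg" in text


class TestInvariances:
    @pytest.mark.parametrize("scale", [1e-3, 0.5, 7.0, 1e4])
    def test_rate_scale_invariance(self, scale):
        p = make_powerlaw_profile(0.5, n=40)
        base = compute_ri(p).ri
        scaled = compute_ri(RateProfile("s", p.do_pct_airsat, scale * p.rate_mlO2_h_gww)).ri
        assert scaled == pytest.approx(base, rel=1e-9, abs=1e-12)

    @pytest.mark.parametrize("scale", [0.2095, 1.0, 6.3])
    def test_oxygen_unit_invariance(self, scale):
        # through-origin rescaling of the oxygen axis = a unit change (e.g. kPa)
        p = make_powerlaw_profile(2.0, n=40)
        base = compute_ri(p).ri
        scaled = compute_ri(RateProfile("u", scale * p.do_pct_airsat, p.rate_mlO2_h_gww)).ri
        assert scaled == pytest.approx(base, rel=1e-9, abs=1e-12)

    def test_uniform_offset_never_decreases_ri(self):
        rng = np.random.default_rng(11)
        do = np.linspace(100, 5, 30)
        rate = np.abs(np.sin(do / 17.0)) + 0.2
        base = compute_ri(RateProfile("b", do, rate)).ri
        for off in (0.1, 0.5, 2.0):
            shifted = compute_ri(RateProfile("o", do, rate + off)).ri
            assert shifted >= base - 1e-9
            base = shifted

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(
        rates=st.lists(st.floats(0.0, 10.0), min_size=4, max_size=25),
        seed=st.integers(0, 10_000),
    )
    def test_ri_bounded_for_nonnegative_profiles(self, rates, seed):
        rng = np.random.default_rng(seed)
        do = np.sort(rng.uniform(1.0, 100.0, len(rates)))
        if np.unique(do).size < 3 or all(r == 0 for r in rates):
            return
        try:
            res = compute_ri(RateProfile("h", do, np.asarray(rates)))
        except DegenerateProfileError:
            return
        assert -1.0 <= res.ri <= 1.0


class TestBatch:
    def test_qc_failures_recorded_not_dropped(self, conformer_profile, regulator_profile):
        bad = qc_filter(
            RateProfile("bad", np.linspace(100, 80, 10), np.ones(10)), 0.5
        )
        results, skipped = ri_batch([conformer_profile, regulator_profile, bad])
        assert len(results) == 2
        assert len(skipped) == 1 and skipped[0]["trace_id"] == "bad"
        assert "qc_fail" in skipped[0]["reason"]

    def test_empty_input(self):
        results, skipped = ri_batch([])
        assert results == [] and skipped == []


class TestModelInterface:
    def test_from_dataframe(self):
        import pandas as pd

        do = np.linspace(100, 10, 15)
        df = pd.DataFrame({"do_pct_airsat": do, "rate_mlO2_h_gww": np.full(15, 0.7)})
        res = RegulationIndex.from_dataframe(df, trace_id="df").fit()
        assert res.ri == pytest.approx(1.0, abs=1e-9)
        assert res.n_points == 15
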