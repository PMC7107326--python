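"""Synthetic archetypes, their analytic RI, and the chamber simulator."""

import numpy as np
import pytest
from scipy.integrate import quad

from oxyreg import (
    ArchetypeSpec,
    NoiseModel,
    TraceMetadata,
    UnitContext,
    compute_ri,
    make_study,
    response,
    sample_rate_profile,
    simulate_trace,
    trace_to_profile,
    true_ri,
)
from oxyreg.units import o2_solubility_ml_per_l

ALL_SPECS = [
    ArchetypeSpec("power_law", gamma=0.0),
    ArchetypeSpec("power_law", gamma=0.5),
    ArchetypeSpec("power_law", gamma=1.0),
    ArchetypeSpec("power_law", gamma=3.0),
    ArchetypeSpec("saturation", K=25.0),
    ArchetypeSpec("pcrit_regulator", pcrit_pct=30.0),
    ArchetypeSpec("suppressor", threshold_pct=60.0, suppression_fraction=0.3),
]


class TestTrueRi:
    @pytest.mark.parametrize("gamma,expected", [(0.0, 1.0), (1.0, 0.0), (3.0, -0.5)])
    def test_power_law_anchors(self, gamma, expected):
        assert true_ri(ArchetypeSpec("power_law", gamma=gamma)) == pytest.approx(expected)

    def test_saturation_closed_form(self):
        spec = ArchetypeSpec("saturation", K=25.0, rmax_mlO2_h_gww=1.0)
        expected = (100 - 25 * np.log(5.0) - 40.0) / 40.0
        assert true_ri(spec) == pytest.approx(expected, rel=1e-12)

    def test_pcrit_regulator_breakpoint_area(self):
        # linear rise to the breakpoint then flat: RI = 1 - pcrit/do_max
        spec = ArchetypeSpec("pcrit_regulator", pcrit_pct=30.0)
        assert true_ri(spec) == pytest.approx(0.7, rel=1e-12)

    @pytest.mark.parametrize("spec", ALL_SPECS, ids=lambda s: f"{s.kind}")
    def test_closed_form_matches_numerical_quadrature(self, spec):
        # independent oracle: integrate the response numerically and apply the
        # branch formulas directly
        lo, hi = 0.0, spec.do_max_pct
        a_c = quad(lambda x: float(response(spec, x)), lo, hi, limit=500)[0]
        top = float(response(spec, hi))
        a_f = top * hi / 2.0
        a_r = top * hi
        expected = (a_c - a_f) / (a_r - a_f) if a_c >= a_f else (a_c - a_f) / a_f
        assert true_ri(spec) == pytest.approx(expected, rel=1e-6)

    def test_partial_range_ri_differs_from_full(self):
        spec = ArchetypeSpec("pcrit_regulator", pcrit_pct=30.0)
        assert true_ri(spec, 5.0, 95.0) > true_ri(spec)

    def test_suppressor_is_negative(self):
        spec = ArchetypeSpec("suppressor", threshold_pct=60.0, suppression_fraction=0.3)
        assert -1.0 < true_ri(spec) < 0.0


class TestSampleProfile:
    def test_noiseless_conformer_scores_zero(self):
        spec = ArchetypeSpec("power_law", gamma=1.0)
        prof = sample_rate_profile(spec, 200, NoiseModel(seed=0), floor_pct=0.0)
        assert compute_ri(prof).ri == pytest.approx(0.0, abs=0.01)

    def test_fixed_seed_reproducible(self):
        spec = ArchetypeSpec("saturation", K=25.0)
        noise = NoiseModel(rate_sd_frac=0.1, seed=77)
        a = sample_rate_profile(spec, 50, noise)
        b = sample_rate_profile(spec, 50, noise)
        assert np.array_equal(a.rate_mlO2_h_gww, b.rate_mlO2_h_gww)

    def test_noisy_conformer_replicates_center_on_zero(self):
        spec = ArchetypeSpec("power_law", gamma=1.0)
        ris = []
        for i in range(20):
            noise = NoiseModel(rate_sd_frac=0.05, seed=1000 + i)
            prof = sample_rate_profile(spec, 60, noise)
            ris.append(compute_ri(prof, smooth=True).ri)
        assert abs(np.median(ris)) < 0.05

    def test_rates_nonnegative_under_noise(self):
        spec = ArchetypeSpec("power_law", gamma=2.0)
        prof = sample_rate_profile(spec, 100, NoiseModel(rate_sd_frac=0.3, seed=5))
        assert np.all(prof.rate_mlO2_h_gww >= 0)


class TestSimulateTrace:
    def test_constant_rate_gives_linear_decline(self, meta, ctx10):
        spec = ArchetypeSpec("power_law", gamma=0.0, rmax_mlO2_h_gww=0.4)
        tr = simulate_trace(spec, meta, NoiseModel(seed=0), duration_h=2.0)
        slopes = np.diff(tr.do_pct_airsat) / np.diff(tr.time_s)
        c_sat = o2_solubility_ml_per_l(10.0, 34.0)
        expected = -(0.4 * 0.05 / 0.02) / c_sat * 100.0 / 3600.0
        assert np.allclose(slopes, expected, rtol=1e-9)

    def test_conformer_exponential_decline(self, meta, ctx10):
        # dC/dt = -k C: analytic solution within 0.1% of the Euler trace
        spec = ArchetypeSpec("power_law", gamma=1.0, rmax_mlO2_h_gww=0.4)
        tr = simulate_trace(spec, meta, NoiseModel(seed=0), duration_h=4.0, step_s=5.0)
        c_sat = o2_solubility_ml_per_l(10.0, 34.0)
        k = 0.4 * 0.05 / 0.02 / c_sat / 3600.0  # per s, on the %airsat scale
        analytic = 100.0 * np.exp(-k * tr.time_s)
        assert np.max(np.abs(tr.do_pct_airsat - analytic) / analytic) < 1e-3

    def test_blank_trace_pure_drift(self, ctx10):
        blank = TraceMetadata("bl", is_blank=True, chamber_volume_mL=20.0,
                              temperature_C=10.0, sampling_interval_s=15.0)
        spec = ArchetypeSpec("power_law", gamma=0.0)
        tr = simulate_trace(spec, blank, NoiseModel(blank_slope_pct_per_h=1.2, seed=0),
                            duration_h=2.0)
        slopes = np.diff(tr.do_pct_airsat) / np.diff(tr.time_s) * 3600.0
        assert np.allclose(slopes, -1.2, rtol=1e-9)

    def test_truncates_at_floor(self, meta):
        spec = ArchetypeSpec("power_law", gamma=0.0, rmax_mlO2_h_gww=5.0)
        tr = simulate_trace(spec, meta, NoiseModel(seed=0), duration_h=50.0, floor_pct=1.0)
        assert tr.do_pct_airsat.min() >= 1.0
        assert tr.duration_s < 50 * 3600.0

    def test_oxygen_conservation(self, meta):
        # oxygen removed from the chamber equals the time-integral of the rate
        spec = ArchetypeSpec("saturation", K=25.0, rmax_mlO2_h_gww=0.4)
        tr = simulate_trace(spec, meta, NoiseModel(seed=0), duration_h=3.0)
        c_sat = o2_solubility_ml_per_l(10.0, 34.0)
        consumed_ml = (tr.do_pct_airsat[0] - tr.do_pct_airsat[-1]) / 100.0 * c_sat * 0.02
        rates = response(spec, tr.do_pct_airsat) * 0.05  # mL/h for the animal
        integral = np.sum(rates[:-1] * np.diff(tr.time_s)) / 3600.0
        assert consumed_ml == pytest.approx(integral, rel=0.01)

    def test_halving_step_converges(self, meta):
        spec = ArchetypeSpec("power_law", gamma=1.0, rmax_mlO2_h_gww=0.4)
        end = []
        for dt in (30.0, 15.0, 7.5):
            tr = simulate_trace(spec, meta, NoiseModel(seed=0), duration_h=3.0, step_s=dt)
            end.append(tr.do_pct_airsat[-1])
        assert abs(end[2] - end[1]) < abs(end[1] - end[0])


class TestPipelineRecovery:
    @pytest.mark.parametrize(
        "spec,duration_h",
        [
            (ArchetypeSpec("power_law", gamma=0.0, rmax_mlO2_h_gww=0.4), 30.0),
            (ArchetypeSpec("power_law", gamma=1.0, rmax_mlO2_h_gww=0.4), 30.0),
            (ArchetypeSpec("pcrit_regulator", pcrit_pct=25.0, rmax_mlO2_h_gww=0.4), 12.0),
            (ArchetypeSpec("suppressor", threshold_pct=60.0, suppression_fraction=0.3,
                           rmax_mlO2_h_gww=0.4), 30.0),
        ],
        ids=["regulator", "conformer", "pcrit", "suppressor"],
    )
    def test_zero_noise_range_matched_recovery(self, spec, duration_h, meta, ctx10):
        # trim -> windows -> mass-specific -> RI recovers the analytic RI of
        # the same archetype evaluated over the realized oxygen range
        tr = simulate_trace(spec, meta, NoiseModel(seed=3), duration_h=duration_h)
        prof = trace_to_profile(tr, ctx10, blank_disabled=True)
        res = compute_ri(prof)
        oracle = true_ri(spec, res.do_lo_pct, res.do_hi_pct)
        assert res.ri == pytest.approx(oracle, abs=0.02)


class TestMakeStudy:
    def test_shapes_and_truth(self):
        design = {
            "g1": (ArchetypeSpec("power_law", gamma=0.0), 5),
            "g2": (ArchetypeSpec("power_law", gamma=1.0), 5),
            "g3": (ArchetypeSpec("suppressor"), 5),
        }
        data, truth = make_study(design, NoiseModel(seed=4), mode="profile")
        assert len(data) == 15 and len(truth) == 15
        assert set(truth["group"]) == {"g1", "g2", "g3"}
        assert truth.loc[truth.group == "g1", "true_ri"].iloc[0] == pytest.approx(1.0)

    def test_seeded_determinism(self):
        design = {"g": (ArchetypeSpec("saturation"), 4)}
        a, _ = make_study(design, NoiseModel(rate_sd_frac=0.1, seed=11))
        b, _ = make_study(design, NoiseModel(rate_sd_frac=0.1, seed=11))
        for x, y in zip(a, b):
            assert np.array_equal(x.rate_mlO2_h_gww, y.rate_mlO2_h_gww)

    def test_single_group_zero_noise_median_recovery(self):
        spec = ArchetypeSpec("saturation", K=25.0)
        data, truth = make_study({"g": (spec, 8)}, NoiseModel(seed=2), floor_pct=0.5)
        ris = [compute_ri(p).ri for p in data]
        assert np.median(ris) == pytest.approx(true_ri(spec), abs=0.02)
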