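"""Dryer station model, response surface, cyclone, yield and sensor logs."""

import math

import numpy as np
import pandas as pd
import pytest

from spraydry.dryer_model import (
    CycloneConfig,
    DryerConfig,
    Phase,
    cyclone_cutoff,
    filter_pressure_check,
    fit_rh_response_surface,
    operation_limit_band,
    parse_sensor_log,
    process_yield,
    segment_phases,
    station_states,
    steady_state_extract,
)
from spraydry.material_state import TREHALOSE_GAB_PLACEHOLDER, TREHALOSE_WATER_GT, ZoneLabel
from spraydry.psychrometry import MoistAirState
from spraydry.synthetic import gen_process_log


def make_config(**kw) -> DryerConfig:
    base = dict(
        dry_gas_mass_flow=0.0107,
        inlet_set_temperature=403.15,
        feed_rate=1.86e-6 / 60.0,
        ambient_state=MoistAirState.from_rh(295.15, 0.40),
    )
    base.update(kw)
    return DryerConfig(**base)


class TestStationStates:
    def test_zero_feed_dry_air_behaviour(self):
        cfg = make_config(feed_rate=0.0)
        states = {s.station_id: s.state for s in station_states(cfg)}
        assert states["P4"].dry_bulb_temperature == states["P3"].dry_bulb_temperature
        ys = [states[p].specific_humidity for p in ("P3", "P4", "P5", "P7", "P9")]
        assert all(y == ys[0] for y in ys)

    def test_water_mass_balance_to_1e12(self):
        cfg = make_config()
        states = {s.station_id: s.state for s in station_states(cfg)}
        dy = states["P9"].specific_humidity - states["P1"].specific_humidity
        expected = cfg.water_evaporation_rate / cfg.dry_gas_mass_flow
        assert dy == pytest.approx(expected, rel=1e-12)

    def test_humidity_nondecreasing_downstream(self):
        cfg = make_config()
        sts = station_states(cfg)
        ys = [s.state.specific_humidity for s in sts if s.station_id != "P1"]
        assert all(b >= a for a, b in zip(ys, ys[1:]))

    def test_hot_dry_run_safe_cold_wet_run_risky(self):
        """High inlet temperature keeps P5 in the safe zone; a cold, heavily
        fed run drives downstream stations toward sticky/condensing states."""
        gt, iso = TREHALOSE_WATER_GT, TREHALOSE_GAB_PLACEHOLDER
        hot = make_config(
            inlet_set_temperature=403.15,
            heat_loss_p4_p5=45.0,
        )
        hot_states = {s.station_id: s for s in station_states(hot, gt, iso)}
        assert hot_states["P5"].zone is ZoneLabel.SAFE

        cold = make_config(
            inlet_set_temperature=313.15,
            feed_rate=5.5e-6 / 60.0,
            heat_loss_p4_p5=10.0,
        )
        cold_sts = station_states(cold, gt, iso)
        assert any(
            s.supersaturated or s.zone in (ZoneLabel.RISK, ZoneLabel.TRANSITION)
            for s in cold_sts
        )

    def test_supersaturation_flagged_pipeline_continues(self):
        cfg = make_config(
            inlet_set_temperature=313.15,
            feed_rate=8e-6 / 60.0,
            heat_loss_p4_p5=15.0,
        )
        sts = station_states(cfg, TREHALOSE_WATER_GT, TREHALOSE_GAB_PLACEHOLDER)
        assert len(sts) == 6
        assert any(s.supersaturated for s in sts)
        for s in sts:
            if s.supersaturated:
                assert s.zone is None


class TestResponseSurface:
    @staticmethod
    def quad(f, t):
        return 10.0 + 2.0 * f - 0.05 * t + 0.3 * f * f - 0.01 * f * t + 1e-4 * t * t

    def grid_points(self, noise=0.0, rng=None):
        pts = []
        for f in (1.0, 2.0, 3.0, 4.0):
            for t in (40.0, 70.0, 100.0, 130.0):
                r = self.quad(f, t)
                if noise and rng is not None:
                    r += noise * rng.standard_normal()
                pts.append((f, t, r, True))
        return pts

    def test_exact_quadratic_recovered(self):
        surf = fit_rh_response_surface(self.grid_points())
        expected = (10.0, 2.0, -0.05, 0.3, -0.01, 1e-4)
        assert np.allclose(surf.coefficients, expected, atol=1e-8)

    def test_noisy_predictions_within_2sigma(self):
        rng = np.random.default_rng(5)
        pts = self.grid_points(noise=0.5, rng=rng)[:12]
        surf = fit_rh_response_surface(pts)
        for f, t, r, _ in pts:
            assert abs(surf.predict(f, t) - r) < 2.0 * 0.5 + 1e-9

    def test_failed_points_excluded_but_stored(self):
        pts = self.grid_points()
        pts.append((9.0, 40.0, 70.0, False))
        surf = fit_rh_response_surface(pts)
        assert surf.excluded_points == ((9.0, 40.0, 70.0),)
        assert np.allclose(
            surf.coefficients, (10.0, 2.0, -0.05, 0.3, -0.01, 1e-4), atol=1e-8
        )

    def test_five_points_raise(self):
        with pytest.raises(ValueError, match="at least 6"):
            fit_rh_response_surface(self.grid_points()[:5])

    def test_collinear_points_raise(self):
        pts = [(float(i), 70.0, 50.0 + i, True) for i in range(8)]
        with pytest.raises(ValueError, match="rank"):
            fit_rh_response_surface(pts)


class TestOperationLimitBand:
    def test_published_style_toy_input(self):
        band = operation_limit_band([50.0, 57.64], [63.72, 70.0])
        assert band == (57.64, 63.72)

    def test_single_point_classes(self):
        assert operation_limit_band([40.0], [60.0]) == (40.0, 60.0)

    def test_overlap_warns(self):
        with pytest.warns(UserWarning, match="overlap"):
            band = operation_limit_band([65.0], [60.0])
        assert band == (65.0, 60.0)

    def test_missing_class_raises(self):
        with pytest.raises(ValueError):
            operation_limit_band([], [60.0])


class TestCycloneCutoff:
    def make(self, **kw) -> CycloneConfig:
        base = dict(
            inlet_width=0.006,
            inlet_height=0.0125,
            body_diameter=0.044,
            vortex_finder_diameter=0.011,
            effective_length=0.11,
            gas_volumetric_flow=35.0 / 3600.0,
        )
        base.update(kw)
        return CycloneConfig(**base)

    def test_hand_evaluated_reference_geometry(self):
        cfg = self.make()
        q = 35.0 / 3600.0
        v_in = q / (0.0125 * 0.006)
        v_theta = v_in * (0.044 - 0.006) / 0.011
        expected = math.sqrt(
            9.0 * 1.85e-5 * q / (math.pi * 0.11 * (1500.0 - 1.2) * v_theta**2)
        )
        assert cyclone_cutoff(cfg) == pytest.approx(expected, rel=1e-9)
        # sub-2-um cut size at lab scale, the right order of magnitude
        assert 1e-7 < cyclone_cutoff(cfg) < 2e-6

    def test_quadrupling_flow_halves_cut_size(self):
        d1 = cyclone_cutoff(self.make())
        d2 = cyclone_cutoff(self.make(gas_volumetric_flow=4.0 * 35.0 / 3600.0))
        assert d2 == pytest.approx(d1 / 2.0, rel=1e-12)

    def test_density_contrast_scaling(self):
        d1 = cyclone_cutoff(self.make(particle_density=1.2 + 1000.0))
        d2 = cyclone_cutoff(self.make(particle_density=1.2 + 2000.0))
        assert d2 == pytest.approx(d1 / math.sqrt(2.0), rel=1e-12)

    def test_nonphysical_geometry_raises(self):
        with pytest.raises(ValueError):
            self.make(body_diameter=-0.01)
        with pytest.raises(ValueError):
            self.make(particle_density=1.0, gas_density=1.2)


class TestProcessYield:
    def test_direct_substitution(self):
        # 500 mg at 4 wt% moisture from 20 mL of 30 mg/mL feed
        rec = process_yield(500e-6, 0.04, 30.0, 20e-6)
        assert rec.yield_fraction == pytest.approx(0.80, rel=1e-12)
        assert not rec.anomalous

    def test_zero_product_zero_yield(self):
        assert process_yield(0.0, 0.04, 30.0, 20e-6).yield_fraction == 0.0

    def test_dry_product_reduces_to_mass_ratio(self):
        rec = process_yield(450e-6, 0.0, 30.0, 20e-6)
        assert rec.yield_fraction == pytest.approx(450.0 / 600.0, rel=1e-12)

    def test_unit_invariance(self):
        # (mg, mg/mL, mL) vs (kg, kg/m^3, m^3) give the same fraction
        a = process_yield(500.0, 0.04, 30.0, 20.0).yield_fraction
        b = process_yield(5e-4, 0.04, 30.0, 2e-5).yield_fraction
        assert a == pytest.approx(b, rel=1e-12)

    def test_over_recovery_flagged(self):
        rec = process_yield(700e-6, 0.0, 30.0, 20e-6)
        assert rec.anomalous

    def test_zero_denominator_raises(self):
        with pytest.raises(ValueError):
            process_yield(500e-6, 0.04, 30.0, 0.0)


class TestSensorLogs:
    def test_missing_channel_raises(self):
        df = pd.DataFrame({"time_s": [0.0, 1.0]})
        with pytest.raises(ValueError, match="missing"):
            parse_sensor_log(df)

    def test_non_monotone_time_raises(self):
        log, _ = gen_process_log(make_config(), seed=3)
        raw = pd.DataFrame(
            {
                "time_s": [0.0, 2.0, 1.0],
                "T_P3_R_C": 100.0,
                "T_P5_R_C": 60.0,
                "T_P9_R_C": 40.0,
                "RH_P9_R_pct": 20.0,
                "p_P9_R_Pa": 101325.0,
                "FR_P11_R_mL_min": 0.0,
            }
        )
        with pytest.raises(ValueError, match="increasing"):
            parse_sensor_log(raw)

    def test_phase_boundaries_recovered_within_one_sample(self):
        cfg = make_config()
        log, truth = gen_process_log(cfg, sensor_noise={"T": 0.0, "RH": 0.0, "p": 0.0}, seed=11)
        bounds = segment_phases(
            log, solution_switch_time=truth[Phase.PrP][0]
        )
        dt = 5.0
        for phase in (Phase.PSP, Phase.PrP, Phase.S):
            assert abs(bounds[phase][0] - truth[phase][0]) <= dt

    def test_steady_state_statistics(self):
        cfg = make_config()
        log, truth = gen_process_log(cfg, sensor_noise={"T": 0.0, "RH": 0.0, "p": 0.0}, seed=2)
        # end of PSP: fully relaxed, zero noise -> sd ~ 0, stationary
        t0, t1 = truth[Phase.PSP][1] - 300.0, truth[Phase.PSP][1]
        stats = steady_state_extract(log, (t0, t1))
        assert bool(stats.loc["RH_P9", "stationary"])
        assert stats.loc["T_P5_K", "sd"] < 0.05

    def test_ramp_fails_stationarity(self):
        n = 60
        raw = pd.DataFrame(
            {
                "time_s": np.arange(n) * 5.0,
                "T_P3_R_C": 100.0,
                "T_P5_R_C": np.linspace(40.0, 70.0, n),  # ramp
                "T_P9_R_C": 40.0,
                "RH_P9_R_pct": 20.0,
                "p_P9_R_Pa": 101325.0,
                "FR_P11_R_mL_min": 0.0,
            }
        )
        log = parse_sensor_log(raw)
        stats = steady_state_extract(log, (0.0, 295.0))
        assert not bool(stats.loc["T_P5_K", "stationary"])

    def test_constant_channel_sd_zero(self):
        raw = pd.DataFrame(
            {
                "time_s": np.arange(10) * 5.0,
                "T_P3_R_C": 100.0,
                "T_P5_R_C": 60.0,
                "T_P9_R_C": 40.0,
                "RH_P9_R_pct": 20.0,
                "p_P9_R_Pa": 101325.0,
                "FR_P11_R_mL_min": 0.0,
            }
        )
        stats = steady_state_extract(parse_sensor_log(raw), (0.0, 45.0))
        assert stats.loc["T_P5_K", "sd"] == 0.0
        assert bool(stats.loc["T_P5_K", "stationary"])


class TestFilterPressure:
    def make_log(self, pressures):
        raw = pd.DataFrame(
            {
                "time_s": np.arange(len(pressures)) * 5.0,
                "T_P3_R_C": 100.0,
                "T_P5_R_C": 60.0,
                "T_P9_R_C": 40.0,
                "RH_P9_R_pct": 20.0,
                "p_P9_R_Pa": pressures,
                "FR_P11_R_mL_min": 0.0,
            }
        )
        return parse_sensor_log(raw)

    def test_constant_pressure_passes(self):
        log = self.make_log([101325.0] * 20)
        dp, ok = filter_pressure_check(log, (0.0, 20.0))
        assert dp == 0.0 and ok

    def test_three_percent_drift_passes(self):
        p0 = 101325.0
        pressures = [p0] * 5 + list(p0 * (1.0 - np.linspace(0.0, 0.03, 35)))
        dp, ok = filter_pressure_check(self.make_log(pressures), (0.0, 20.0))
        assert dp == pytest.approx(0.03, rel=1e-9)
        assert ok

    def test_eight_percent_step_fails(self):
        p0 = 101325.0
        pressures = [p0] * 10 + [p0 * 0.92] * 10
        dp, ok = filter_pressure_check(self.make_log(pressures), (0.0, 45.0))
        assert dp == pytest.approx(0.08, rel=0.01)
        assert not ok

    def test_empty_baseline_raises(self):
        log = self.make_log([101325.0] * 5)
        with pytest.raises(ValueError, match="baseline"):
            filter_pressure_check(log, (1000.0, 2000.0))
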