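"""Field layout, true-effect surface, flight planning, measurement simulation."""

import numpy as np
import pandas as pd
import pytest

import thermoview as tv
from thermoview import fieldsim


class TestMakeFieldLayout:
    def test_side_by_side_counts(self):
        lay = tv.make_field_layout(3, 4, 2, 2, 3, "side_by_side", seed=1)
        exp = lay.experiment_plots
        assert len(exp) == 12
        counts = exp.groupby(["genotype", "treatment"]).size()
        assert (counts == 3).all()

    def test_full_variety_trial_dimensions(self):
        lay = tv.make_field_layout(27, 10, 30, 3, 3, "nested", seed=7)
        assert len(lay.plots) == 270
        assert len(lay.experiment_plots) == 270
        counts = lay.experiment_plots.groupby(["genotype", "treatment"]).size()
        assert (counts == 3).all()

    def test_same_seed_identical_layouts(self):
        a = tv.make_field_layout(8, 6, 10, 2, 2, "nested", seed=3)
        b = tv.make_field_layout(8, 6, 10, 2, 2, "nested", seed=3)
        pd.testing.assert_frame_equal(a.plots, b.plots)

    def test_surplus_plots_become_border(self):
        lay = tv.make_field_layout(5, 5, 4, 2, 2, "nested", seed=0)
        assert (lay.plots["genotype"] == "border").sum() == 25 - 16

    def test_grid_too_small_names_required_count(self):
        with pytest.raises(ValueError, match="24"):
            tv.make_field_layout(2, 3, 4, 2, 3, "nested", seed=0)

    def test_grid_indices_unique(self):
        lay = tv.make_field_layout(6, 4, 6, 2, 2, "nested", seed=2)
        assert not lay.plots.duplicated(["row", "col"]).any()


class TestSimulateTrueSurface:
    def test_zero_sds_give_zero_effects(self, small_layout):
        eff = tv.simulate_true_surface(
            small_layout,
            tv.EffectConfig(sd_genotype=0, sd_treatment=0, sd_replicate=0,
                            sd_plot=0, sd_spatial=0),
            seed=5,
        )
        for fam in (eff.genotype, eff.treatment, eff.replicate, eff.plot, eff.spatial):
            assert np.allclose(fam.to_numpy(), 0.0)

    def test_families_sum_to_zero(self, small_layout):
        eff = tv.simulate_true_surface(small_layout, tv.EffectConfig(), seed=6)
        for fam in (eff.genotype, eff.treatment, eff.replicate, eff.plot):
            assert fam.sum() == pytest.approx(0.0, abs=1e-9)

    def test_genotype_sample_sd_within_chi2_bounds(self):
        # sd 1 with 30 genotypes: sample SD within [0.7, 1.3] almost surely
        lay = tv.make_field_layout(27, 10, 30, 3, 3, "nested", seed=7)
        eff = tv.simulate_true_surface(lay, tv.EffectConfig(sd_genotype=1.0), seed=8)
        sd = eff.genotype.drop("border", errors="ignore").std()
        assert 0.7 <= sd <= 1.3

    def test_spatial_field_lag1_row_autocorrelation(self):
        # AR(1)xAR(1), rho=0.9 on a 27x10 grid: empirical lag-1 row
        # autocorrelation concentrates near rho (Monte-Carlo over seeds)
        lay = tv.make_field_layout(27, 10, 30, 3, 3, "nested", seed=7)
        acs = []
        for seed in range(40):
            eff = tv.simulate_true_surface(
                lay, tv.EffectConfig(sd_spatial=1.0, rho_row=0.9, rho_col=0.9), seed=seed
            )
            grid = eff.spatial.to_numpy().reshape(27, 10)
            a, b = grid[:-1].ravel(), grid[1:].ravel()
            acs.append(np.corrcoef(a, b)[0, 1])
        assert 0.75 <= float(np.mean(acs)) <= 0.97

    def test_spatial_marginal_variance(self):
        lay = tv.make_field_layout(27, 10, 30, 3, 3, "nested", seed=7)
        vs = [
            tv.simulate_true_surface(
                lay, tv.EffectConfig(sd_spatial=1.0, rho_row=0.6, rho_col=0.6), seed=s
            ).spatial.var()
            for s in range(50)
        ]
        assert np.mean(vs) == pytest.approx(1.0, rel=0.2)

    def test_invalid_rho_raises(self, small_layout):
        with pytest.raises(ValueError):
            tv.simulate_true_surface(small_layout, tv.EffectConfig(rho_row=1.0), seed=0)

    def test_explicit_treatment_effects_honoured(self, small_layout):
        eff = tv.simulate_true_surface(
            small_layout,
            tv.EffectConfig(treatment_effects={"T1": 2.4, "T2": -2.4}),
            seed=0,
        )
        assert eff.treatment["T1"] == 2.4 and eff.treatment["T2"] == -2.4


class TestPlanFlight:
    def test_every_plot_center_in_nine_footprints(self):
        # typical survey: 40 m height, 80/80 % overlaps
        lay = tv.make_field_layout(27, 10, 30, 3, 3, "nested", seed=7)
        plan = tv.plan_flight(lay, flight_height=40.0, front_overlap=0.8,
                              side_overlap=0.8, seed=0)
        hx, hy = plan.footprint_half_extent()
        trig = plan.triggers
        for _, p in lay.plots.iterrows():
            inside = (
                (np.abs(trig["x"] - p["x"]) <= hx) & (np.abs(trig["y"] - p["y"]) <= hy)
            ).sum()
            assert inside >= 9

    def test_zero_side_overlap_footprints_only_touch(self, small_layout):
        plan = tv.plan_flight(small_layout, side_overlap=0.0, seed=0)
        hx, hy = plan.footprint_half_extent()
        ys = np.sort(plan.triggers["y"].unique())
        gaps = np.diff(ys)
        assert np.all(gaps >= 2 * hy - 1e-9)

    def test_duration_matches_path_length_arithmetic(self):
        # 180 m x 45 m field at 3 m/s with moderate overlaps: a few minutes
        lay = tv.make_field_layout(30, 25, 10, 2, 2, "nested", seed=0,
                                   plot_width=1.5, plot_length=7.2)
        plan = tv.plan_flight(lay, speed=3.0, front_overlap=0.7, side_overlap=0.7, seed=0)
        assert 4 * 60 <= plan.duration <= 12 * 60

    def test_trigger_times_strictly_increasing(self, small_plan):
        assert np.all(np.diff(small_plan.triggers["time_s"].to_numpy()) > 0)

    def test_invalid_overlap_raises(self, small_layout):
        with pytest.raises(ValueError):
            tv.plan_flight(small_layout, front_overlap=1.0, seed=0)


class TestSimulateMeasurements:
    def test_clean_simulation_reproduces_true_plot_values(
        self, small_layout, clean_simulation
    ):
        effects, meas = clean_simulation
        totals = effects.plot_totals(small_layout)
        expect = totals.reindex(meas["plot_id"]).to_numpy()
        assert np.allclose(meas["value_K"].to_numpy(), expect, atol=1e-12)

    def test_every_plot_measured_at_least_nine_times(self, clean_simulation):
        _, meas = clean_simulation
        assert meas.groupby("plot_id").size().min() >= 9

    def test_fcc_effect_slope_recovered_by_regression(self, small_layout, small_plan):
        effects = tv.simulate_true_surface(
            small_layout,
            tv.EffectConfig(sd_genotype=0, sd_treatment=0, sd_replicate=0,
                            sd_plot=0, sd_spatial=0),
            seed=2,
        )
        meas = tv.simulate_measurements(
            effects, small_layout, small_plan,
            geom=tv.GeometricEffectModel(fcc_effect=1.0), seed=3,
        )
        x = np.abs(np.radians(meas["rowdir_lat_angle_deg"].to_numpy()))
        slope = np.polyfit(x, meas["value_K"].to_numpy(), 1)[0]
        assert slope == pytest.approx(-1.0, abs=0.05)

    def test_seeded_run_bit_identical(self, small_layout, small_plan):
        effects = tv.simulate_true_surface(small_layout, tv.EffectConfig(), seed=2)
        geom = tv.GeometricEffectModel(noise_sd=0.4)
        a = tv.simulate_measurements(effects, small_layout, small_plan, geom=geom, seed=9)
        b = tv.simulate_measurements(effects, small_layout, small_plan, geom=geom, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_column_order_matches_export_contract(self, clean_simulation):
        _, meas = clean_simulation
        assert tuple(meas.columns[: len(fieldsim.MEASUREMENT_COLUMNS)]) == \
            fieldsim.MEASUREMENT_COLUMNS

    def test_record_covariates_match_scalar_geometry(self, small_layout, small_plan, clean_simulation):
        # vectorized simulator columns agree with the scalar reference path
        from thermoview import viewgeom as vg

        _, meas = clean_simulation
        sun = vg.SunPosition(azimuth=180.0, elevation=55.0)
        plots = small_layout.plots.set_index("plot_id")
        trig = small_plan.triggers.set_index("trigger_id")
        for _, rec in meas.sample(10, random_state=0).iterrows():
            p = plots.loc[rec["plot_id"]]
            t = trig.loc[rec["trigger_id"]]
            g = vg.raw_geometry(
                (t["x"], t["y"], t["z"]), 0.0, (p["x"], p["y"], 0.0),
                small_layout.row_direction, sun, t["time_s"],
            )
            lin = vg.linearize(g)
            assert rec["drone_elevation_deg"] == pytest.approx(g.drone_elevation)
            assert rec["rowdir_lat_dist_m"] == pytest.approx(g.rowdir_lat_dist)
            assert rec["sundir_lon_angle_deg"] == pytest.approx(g.sundir_lon_angle)
            for name in ("Drone-Elevation-sin", "SunDir-lon-Dist",
                         "Interact.-SunDir-Drone", "Dist-tot"):
                assert rec[name] == pytest.approx(lin[name])

    def test_variance_bookkeeping_of_plot_means(self):
        # var of simulated plot means ~ sum of configured component variances
        lay = tv.make_field_layout(15, 14, 20, 2, 5, "nested", seed=0)
        cfg = tv.EffectConfig(sd_genotype=0.4, sd_treatment=0.3, sd_replicate=0.1,
                              sd_plot=0.3, sd_spatial=0.8, rho_row=0.5, rho_col=0.5)
        expected = 0.4**2 + 0.3**2 + 0.1**2 + 0.3**2 + 0.8**2
        plan = tv.plan_flight(lay, seed=0)
        vs = []
        for seed in range(30):
            eff = tv.simulate_true_surface(lay, cfg, seed=seed)
            meas = tv.simulate_measurements(eff, lay, plan, seed=seed + 1000)
            vs.append(meas.groupby("plot_id")["value_K"].mean().var())
        assert np.mean(vs) == pytest.approx(expected, rel=0.15)


class TestFanExperiment:
    def test_no_events_constant_apparent_temperature(self):
        ts = fieldsim.simulate_fan_experiment([], fieldsim.FanResponse(duration=120))
        assert ts["apparent_target_temp"].nunique() == 1

    def test_lamp_on_apparent_temperature_strictly_decreases(self):
        ts = fieldsim.simulate_fan_experiment(
            [(0.0, "lamp_on")], fieldsim.FanResponse(duration=200)
        )
        seg = ts[ts["time_s"] > 0]["apparent_target_temp"].to_numpy()
        assert np.all(np.diff(seg) < 0)

    def test_sensor_and_apparent_move_in_opposite_directions(self):
        ts = fieldsim.simulate_fan_experiment(
            [(0.0, "lamp_on"), (400.0, "fan_on")], fieldsim.FanResponse(duration=800)
        )
        ds = np.diff(ts["sensor_temp"].to_numpy())
        da = np.diff(ts["apparent_target_temp"].to_numpy())
        moving = np.abs(ds) > 1e-9
        assert np.all(np.sign(ds[moving]) == -np.sign(da[moving]))

    def test_hot_object_elevates_pixel_sd_only_inside_window(self):
        ts = fieldsim.simulate_fan_experiment(
            [("hot_object", 10.0, 20.0)], fieldsim.FanResponse(duration=60)
        )
        inside = ts[(ts["time_s"] >= 10) & (ts["time_s"] <= 20)]
        outside = ts[(ts["time_s"] < 10) | (ts["time_s"] > 20)]
        assert inside["pixel_sd"].min() > outside["pixel_sd"].max()

    def test_unordered_events_raise(self):
        with pytest.raises(ValueError):
            fieldsim.simulate_fan_experiment(
                [(10.0, "fan_on"), (5.0, "fan_off")], fieldsim.FanResponse(duration=30)
            )
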