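"""Vegetation indices, FCC, trait correction and matched-level correlation."""

import numpy as np
import pandas as pd
import pytest

import thermoview as tv
from thermoview import stage1, traits


class TestVegetationIndices:
    def test_dvi_and_ndvi_arithmetic(self):
        v = traits.vegetation_indices(
            traits.BandReflectances(NIR842=0.5, Red668=0.25, Red650=0.1, Blue444=0.05)
        )
        assert v["DVI"] == pytest.approx(0.25)
        assert v["NDVI"] == pytest.approx(1 / 3)

    def test_equal_bands_zero_ndvi(self):
        v = traits.vegetation_indices(
            traits.BandReflectances(NIR842=0.3, Red668=0.3, Red650=0.1, Blue444=0.05)
        )
        assert v["NDVI"] == pytest.approx(0.0)

    def test_evi_savi_hand_computed(self):
        # EVI = 2.5*0.5/1.825, SAVI = 1.5*0.5/1.2
        v = traits.vegetation_indices(
            traits.BandReflectances(NIR842=0.6, Red668=0.25, Red650=0.1, Blue444=0.05)
        )
        assert v["EVI"] == pytest.approx(2.5 * 0.5 / 1.825, abs=1e-9)
        assert v["SAVI"] == pytest.approx(0.625, abs=1e-9)

    def test_ndvi_bounded(self, rng):
        for _ in range(50):
            nir, red = rng.uniform(0.01, 1.0, 2)
            v = traits.vegetation_indices(
                traits.BandReflectances(NIR842=nir, Red668=red, Red650=0.1, Blue444=0.05)
            )
            assert -1.0 <= v["NDVI"] <= 1.0

    def test_zero_denominator_flags_nan(self):
        v = traits.vegetation_indices(
            traits.BandReflectances(NIR842=0.0, Red668=0.0, Red650=0.1, Blue444=0.05)
        )
        assert np.isnan(v["NDVI"])

    def test_reflectance_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            traits.BandReflectances(NIR842=1.5, Red668=0.2, Red650=0.1, Blue444=0.05)


class TestFcc:
    @pytest.mark.parametrize(
        "counts,expected",
        [((50, 25, 25), 0.75), ((10, 5, 0), 1.0), ((0, 0, 10), 0.0)],
    )
    def test_pixel_count_fractions(self, counts, expected):
        assert traits.fcc(traits.PixelClassCounts(*counts)) == pytest.approx(expected)

    def test_no_pixels_raises(self):
        with pytest.raises(ValueError):
            traits.fcc(traits.PixelClassCounts(0, 0, 0))

    def test_fcc_always_in_unit_interval(self, rng):
        for _ in range(30):
            g, s, b = rng.integers(0, 100, 3)
            if g + s + b == 0:
                continue
            assert 0.0 <= traits.fcc(traits.PixelClassCounts(int(g), int(s), int(b))) <= 1.0


class TestYieldNormalization:
    def test_fifteen_percent_moisture_is_identity(self):
        assert traits.normalize_yield(60.0, 15.0) == pytest.approx(60.0)

    def test_wetter_grain_normalizes_down(self):
        assert traits.normalize_yield(60.0, 20.0) < 60.0


class TestFitReferenceTrait:
    def test_noiseless_genotype_trait_recovered(self, small_layout):
        lp = small_layout.plots[~small_layout.plots["is_border"]]
        geno_eff = {g: 0.5 * i for i, g in enumerate(sorted(lp["genotype"].unique()))}
        vals = pd.Series(
            [50.0 + geno_eff[g] for g in lp["genotype"]], index=lp["plot_id"].to_numpy()
        )
        ref = traits.fit_reference_trait(vals, small_layout)
        assert np.allclose(ref["ts_c"].to_numpy(), vals.reindex(ref.index), atol=1e-6)

    def test_spatial_gradient_removed(self, small_layout, rng):
        # gradient across columns (orthogonal to the replicate row-bands, so
        # it is a pure spatial trend rather than a design contrast)
        lp = small_layout.plots[~small_layout.plots["is_border"]]
        cols = lp.set_index("plot_id")["col"].astype(float)
        vals = 100.0 + 2.0 * cols + pd.Series(
            rng.normal(0, 0.3, len(lp)), index=cols.index
        )
        ref = traits.fit_reference_trait(vals, small_layout)
        r = np.corrcoef(ref["ts_c"].reindex(cols.index), cols)[0, 1]
        r_raw = np.corrcoef(ref["uncorrected"].reindex(cols.index), cols)[0, 1]
        assert abs(r) < 0.35
        assert abs(r) < abs(r_raw)

    def test_fcc_viewing_angle_slope_recovered(self, small_layout, small_plan):
        # per-image FCC rises with |lateral row angle| (oblique views close
        # the canopy); the mixed-model residuals recover a positive slope
        effects = tv.simulate_true_surface(
            small_layout, tv.EffectConfig(sd_genotype=0.02, sd_treatment=0.0,
                                          sd_replicate=0.0, sd_plot=0.01,
                                          sd_spatial=0.0, grand_mean=0.7),
            seed=61,
        )
        meas = tv.simulate_measurements(
            effects, small_layout, small_plan,
            geom=tv.GeometricEffectModel(fcc_effect=-0.2, noise_sd=0.01), seed=62,
        )
        res = stage1.fit_stage1(meas, small_layout)
        x = np.abs(np.radians(meas["rowdir_lat_angle_deg"].to_numpy()))
        slope = np.polyfit(x, res.residuals.to_numpy(), 1)[0]
        assert slope > 0.05


class TestCorrelate:
    def _ct_frame(self, vals, level):
        return pd.DataFrame(
            {"plot_id": vals.index, "estimate_K": vals.to_numpy(), "level": level}
        )

    def _trait_frame(self, vals, col):
        return pd.DataFrame({col: vals})

    def test_perfect_negative_linear_relation(self, rng):
        ct = pd.Series(rng.normal(size=30), index=[f"P{i}" for i in range(30)])
        trait = -2.0 * ct + 7.0
        rep = traits.correlate(
            self._ct_frame(ct, "ts_c"), self._trait_frame(trait, "ts_c"), "ts_c"
        )
        assert rep["r"].iloc[0] == pytest.approx(-1.0)
        assert rep["sig"].iloc[0]

    def test_independent_pairs_rarely_significant(self):
        rng = np.random.default_rng(5)
        sig, strong = 0, 0
        for _ in range(100):
            idx = [f"P{i}" for i in range(30)]
            ct = pd.Series(rng.normal(size=30), index=idx)
            tr = pd.Series(rng.normal(size=30), index=idx)
            rep = traits.correlate(
                self._ct_frame(ct, "ts_c"), self._trait_frame(tr, "ts_c"), "ts_c"
            )
            sig += int(rep["sig"].iloc[0])
            strong += int(abs(rep["r"].iloc[0]) >= 0.5)
        assert sig <= 5
        assert strong <= 5

    def test_level_pairing_enforced(self, rng):
        idx = [f"P{i}" for i in range(10)]
        ct = pd.Series(rng.normal(size=10), index=idx)
        with pytest.raises(ValueError, match="matched correction level"):
            traits.correlate(
                self._ct_frame(ct, "ts_c"),
                self._trait_frame(ct, "uncorrected"),
                "ts_c",
            )

    def test_ct_level_mismatch_detected(self, rng):
        idx = [f"P{i}" for i in range(10)]
        ct = pd.Series(rng.normal(size=10), index=idx)
        with pytest.raises(ValueError, match="level"):
            traits.correlate(
                self._ct_frame(ct, "mean"), self._trait_frame(ct, "ts_c"), "ts_c"
            )

    def test_shared_treatment_effect_dies_with_deflation(self, small_layout):
        # CT and trait share ONLY a treatment effect: strong correlation at
        # ts_c, gone after deflating the treatment means on both sides
        effects = tv.simulate_true_surface(
            small_layout,
            tv.EffectConfig(sd_genotype=0.0, sd_plot=0.1, sd_spatial=0.3,
                            treatment_effects={"T1": 1.5, "T2": -1.5}),
            seed=71,
        )
        plan = tv.plan_flight(small_layout, seed=0)
        meas = tv.simulate_measurements(
            effects, small_layout, plan,
            geom=tv.GeometricEffectModel(noise_sd=0.2), seed=72,
        )
        res = stage1.fit_stage1(meas, small_layout)
        lp = small_layout.plots[~small_layout.plots["is_border"]]
        rng = np.random.default_rng(73)
        tvals = pd.Series(
            50.0
            - 3.0 * effects.treatment.reindex(lp["treatment"]).to_numpy()
            + rng.normal(0, 0.5, len(lp)),
            index=lp["plot_id"].to_numpy(),
        )
        ref = traits.fit_reference_trait(tvals, small_layout)
        before = traits.correlate(res.predict("ts_c"), ref, "ts_c")
        after = traits.correlate(res.predict("t_defl"), ref, "t_defl")
        assert before["sig"].iloc[0]
        assert not after["sig"].iloc[0]
        assert abs(after["r"].iloc[0]) < abs(before["r"].iloc[0])

    def test_masked_genotypic_link_strengthens_after_deflation(self, small_layout):
        # genotypic height-CT link masked by an opposing treatment effect
        effects = tv.simulate_true_surface(
            small_layout,
            tv.EffectConfig(sd_genotype=0.4, sd_plot=0.05, sd_spatial=0.2,
                            treatment_effects={"T1": 2.0, "T2": -2.0}),
            seed=81,
        )
        plan = tv.plan_flight(small_layout, seed=0)
        meas = tv.simulate_measurements(
            effects, small_layout, plan,
            geom=tv.GeometricEffectModel(noise_sd=0.2), seed=82,
        )
        res = stage1.fit_stage1(meas, small_layout)
        lp = small_layout.plots[~small_layout.plots["is_border"]]
        rng = np.random.default_rng(83)
        height = pd.Series(
            90.0
            - 20.0 * effects.genotype.reindex(lp["genotype"]).to_numpy()
            + 8.0 * effects.treatment.reindex(lp["treatment"]).to_numpy()
            + rng.normal(0, 1.0, len(lp)),
            index=lp["plot_id"].to_numpy(),
        )
        ref = traits.fit_reference_trait(height, small_layout)
        before = traits.correlate(res.predict("ts_c"), ref, "ts_c")
        after = traits.correlate(res.predict("t_defl"), ref, "t_defl")
        assert abs(after["r"].iloc[0]) > abs(before["r"].iloc[0])


class TestRatingGroupTest:
    def test_shifted_groups_highly_significant(self, rng):
        ct = pd.Series(
            np.concatenate([rng.normal(0, 1, 30), rng.normal(5, 1, 30)]),
            index=range(60),
        )
        ratings = pd.Series([0] * 30 + [2] * 30, index=range(60))
        rep = traits.rating_group_test(ct, ratings)
        assert rep["p"].iloc[0] <= 0.001
        assert rep["sig"].iloc[0] == "***"

    def test_identical_samples_not_significant(self):
        vals = np.arange(10.0)
        ct = pd.Series(np.concatenate([vals, vals]), index=range(20))
        ratings = pd.Series([0] * 10 + [1] * 10, index=range(20))
        rep = traits.rating_group_test(ct, ratings)
        assert rep["sig"].iloc[0] == "ns"

    def test_small_groups_excluded(self, rng):
        ct = pd.Series(rng.normal(size=21), index=range(21))
        ratings = pd.Series([0] * 10 + [1] * 10 + [3], index=range(21))
        rep = traits.rating_group_test(ct, ratings)
        assert set(rep["group_a"]) | set(rep["group_b"]) == {0, 1}

    def test_fewer_than_two_groups_raises(self, rng):
        ct = pd.Series(rng.normal(size=5), index=range(5))
        ratings = pd.Series([0] * 5, index=range(5))
        with pytest.raises(ValueError):
            traits.rating_group_test(ct, ratings)
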