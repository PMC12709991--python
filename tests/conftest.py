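import numpy as np
import pytest

import thermoview as tv


@pytest.fixture(scope="session")
def small_layout():
    """6x4 grid: 6 genotypes x 2 treatments x 2 replicates, no border."""
    return tv.make_field_layout(6, 4, 6, 2, 2, "nested", seed=1)


@pytest.fixture(scope="session")
def small_plan(small_layout):
    return tv.plan_flight(small_layout, seed=0)


@pytest.fixture(scope="session")
def clean_simulation(small_layout, small_plan):
    """Noiseless, confounder-free flight: value == true plot value exactly."""
    effects = tv.simulate_true_surface(
        small_layout,
        tv.EffectConfig(
            sd_spatial=0.0, sd_plot=0.0, sd_replicate=0.0,
            sd_treatment=0.3, sd_genotype=0.5,
        ),
        seed=2,
    )
    meas = tv.simulate_measurements(effects, small_layout, small_plan, seed=3)
    return effects, meas


@pytest.fixture(scope="session")
def contaminated_simulation(small_layout, small_plan):
    """Drift + spatial field + geometric effects + noise, with ground truth."""
    effects = tv.simulate_true_surface(
        small_layout, tv.EffectConfig(sd_spatial=1.0), seed=4
    )
    drift = tv.DriftModel(2.0, small_plan.duration, seed=5)
    geom = tv.GeometricEffectModel(
        vignetting_amplitude=0.3, fcc_effect=0.5, sun_gradient=0.005, noise_sd=0.3
    )
    meas = tv.simulate_measurements(
        effects, small_layout, small_plan, drift=drift, geom=geom, seed=6
    )
    return effects, drift, meas


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
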