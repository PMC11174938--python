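import numpy as np
import pytest

import nocturne as nc
from nocturne import labels
from nocturne.simulate import simulate_balanced_cohort


@pytest.fixture(scope="session")
def short_config():
    """A one-hour night at full sensor rates."""
    return nc.SimConfig(seed=11, sleep_duration=3600.0)


@pytest.fixture(scope="session")
def ne_night():
    """A simulated enuretic night with a heart-rate ramp, 1.5 h."""
    cfg = nc.SimConfig(
        seed=21, sleep_duration=5400.0, ne_fraction=1.0, hr_ramp_probability=1.0
    )
    return nc.simulate_night(cfg, 0)


@pytest.fixture(scope="session")
def dry_night():
    cfg = nc.SimConfig(seed=22, sleep_duration=3600.0, ne_fraction=0.0)
    return nc.simulate_night(cfg, 0)


@pytest.fixture(scope="session")
def ne_frame(ne_night):
    grid = nc.resample_and_align(ne_night)
    return nc.extract_features(ne_night, grid)


@pytest.fixture(scope="session")
def dry_frame(dry_night):
    grid = nc.resample_and_align(dry_night)
    return nc.extract_features(dry_night, grid)


@pytest.fixture(scope="session")
def separable_cohort():
    """A small strongly separable cohort: steeper filling, guaranteed
    heart-rate ramp and denser limb movements on enuretic nights."""
    cfg = nc.SimConfig(
        seed=7,
        n_nights=12,
        sleep_duration=3600.0,
        bi_fill_slope=-4.0,
        bi_fill_slope_ne=-12.0,
        hr_ramp_probability=1.0,
        plm_index_target=5.0,
        plm_index_target_ne=30.0,
    )
    nights = simulate_balanced_cohort(cfg)
    data = []
    for n in nights:
        grid = nc.resample_and_align(n)
        frame = nc.extract_features(n, grid)
        curve = labels.probability_curve(n, grid)
        data.append((n, frame, curve))
    return data
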