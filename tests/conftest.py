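import numpy as np
import pytest

from svmscreen import (
    CompoundLibrary,
    SyntheticConfig,
    generate_compound_library,
    generate_spiked_dataset,
)


@pytest.fixture(scope="session")
def bundled_library() -> CompoundLibrary:
    return CompoundLibrary.bundled()


@pytest.fixture(scope="session")
def small_config() -> SyntheticConfig:
    """A reduced study design for fast unit tests."""
    return SyntheticConfig(seed=7, n_markers=20, n_background=30, n_erratic=6)


@pytest.fixture(scope="session")
def small_library() -> CompoundLibrary:
    return generate_compound_library(12, 8, seed=3)


@pytest.fixture(scope="session")
def small_dataset(small_config, bundled_library):
    return generate_spiked_dataset(small_config, bundled_library)


@pytest.fixture(scope="session")
def default_calibrated(bundled_library):
    """Default-scale spiked dataset after calibration and RSD filtering."""
    from svmscreen import CurveData, calibrate, fit_is_curve, recoveries_from_table, rsd_filter

    cfg = SyntheticConfig(seed=7)
    table, truth = generate_spiked_dataset(cfg, bundled_library)
    fits = tuple(
        fit_is_curve(CurveData([5, 50, 100], [s * l for l in (5, 50, 100)]))
        for s in cfg.is_response_slopes
    )
    recov = recoveries_from_table(table, fits)
    return rsd_filter(calibrate(table, recov)), truth


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
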