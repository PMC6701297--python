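import numpy as np
import pytest

import mcrquant as mq


@pytest.fixture(scope="session")
def grid():
    return mq.WavelengthGrid()


@pytest.fixture(scope="session")
def pure(grid):
    return mq.default_pure_spectra(grid)


@pytest.fixture(scope="session")
def cal_design():
    return mq.calibration_design()


@pytest.fixture(scope="session")
def val_design():
    return mq.validation_design()


@pytest.fixture(scope="session")
def cal_known(cal_design):
    return cal_design.to_table("calibration")


@pytest.fixture(scope="session")
def D_noiseless(cal_design, pure, grid):
    return mq.simulate_mixtures(cal_design, pure, mq.NoiseModel(0.0, 0.0, 1), grid)


@pytest.fixture(scope="session")
def D_noisy(cal_design, pure, grid):
    return mq.simulate_mixtures(cal_design, pure, mq.NoiseModel(seed=1), grid)


@pytest.fixture(scope="session")
def fitted_model(D_noisy, cal_known):
    return mq.fit_calibration(D_noisy, cal_known)


@pytest.fixture(scope="session")
def two_component_system(grid):
    """Small two-drug system with known ground truth for oracle tests."""
    bands_a = [mq.GaussianBandSpec(226.0, 3.0, 0.05)]
    bands_b = [mq.GaussianBandSpec(234.0, 3.0, 0.04)]
    pure2 = np.vstack([
        mq.make_pure_spectrum(bands_a, grid),
        mq.make_pure_spectrum(bands_b, grid),
    ])
    rng = np.random.default_rng(7)
    conc = rng.uniform(0.5, 5.0, (10, 2))
    design = mq.DesignTable(("A", "B"), conc)
    D = mq.simulate_mixtures(design, pure2, mq.NoiseModel(0.0, 0.0, 1), grid)
    return D, design.to_table("calibration"), pure2, conc
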