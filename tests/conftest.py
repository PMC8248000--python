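import numpy as np
import pytest

from ramscreen.spectra_io import SampleMeta, SpectrumSet, default_grid
from ramscreen.synthetic import (NOISELESS_INSTRUMENT, Composition,
                                 builtin_compound_library, simulate_spectrum)
from ramscreen.workflow import (CaseSetConfig, ExperimentConfig,
                                InstrumentConfig, PanelConfig, train_models)

NOISELESS_INSTRUMENT_CONFIG = InstrumentConfig(
    gain_sigma=0.0, baseline_offset_range=(0.0, 0.0),
    baseline_slope_range=(0.0, 0.0), noise_sd=0.0)


@pytest.fixture(scope="session")
def grid():
    return default_grid()


@pytest.fixture(scope="session")
def library():
    return builtin_compound_library()


def pure_spectrum(name, library, grid, seed=7):
    """Noise-free scan of one pure compound."""
    return simulate_spectrum(Composition({name: 1.0}), library,
                             NOISELESS_INSTRUMENT, grid, seed=seed)


def single_spectrum_set(name, library, grid, cocaine_wt_pct=0.0,
                        cocaine_form="none", seed=7):
    sp = pure_spectrum(name, library, grid, seed=seed)
    meta = SampleMeta(sample_id=name, composition={name: 1.0},
                      cocaine_wt_pct=cocaine_wt_pct,
                      cocaine_form=cocaine_form)
    return SpectrumSet(grid, sp.intensities, [meta])


@pytest.fixture(scope="session")
def small_noiseless_config():
    """Scaled-down noiseless experiment used by several training tests."""
    return ExperimentConfig(
        seed=11,
        panel=PanelConfig(replicates=3),
        case_set=CaseSetConfig(n_hcl=12, n_base=8, n_negative=10,
                               replicates=2),
        instrument=NOISELESS_INSTRUMENT_CONFIG,
    )


@pytest.fixture(scope="session")
def noiseless_bundle(small_noiseless_config):
    return train_models(small_noiseless_config)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(42)
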