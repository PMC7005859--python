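import numpy as np
import pytest

from phosphodia.dia_extraction import build_window_scheme
from phosphodia.synthetic_data import (RosterEntry, SynthDIAConfig,
                                       simulate_dia_run)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def benchmark_scheme():
    """The instrument's DIA scheme: 48 windows of 14 Da, 1 Da overlap."""
    return build_window_scheme(350.0, 14.0, 1.0, 48)


@pytest.fixture(scope="session")
def single_analyte_run():
    """A noiseless run with one singly phosphorylated peptide, one isomer."""
    entry = RosterEntry(sequence="AASLSDTK", charge=2,
                        isomer_ratios={(3,): 1.0}, abundance=1e6, apex_rt=60.0)
    config = SynthDIAConfig(roster=[entry], seed=11, snr=np.inf,
                            interference_density=0.0, gradient_seconds=120.0,
                            isotope_peaks=0)
    run, truth, library = simulate_dia_run(config)
    return config, run, truth, library
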