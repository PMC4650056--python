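import numpy as np
import pytest

from difms import synthetic_data as syn


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def noise_free_experiment():
    """Small polar experiment with every noise term switched off.

    Peak m/z are exactly theoretical and intensities equal group means, so
    downstream stages can be checked for exact conservation.
    """
    library = syn.default_library()
    effects = syn.default_effect_model(library, seed=3, intensity_cv=0.0,
                                       dilution_sd=0.0, dropout_threshold=0.0)
    acq = syn.AcquisitionConfig(windows=syn.polar_windows(), ppm_error_sd=0.0,
                                n_tech_reps=3, seed=3)
    design = syn.build_design(n_reps=3, n_qc=1)
    return syn.simulate_peaklists(library, effects, acq, design, "polar")


@pytest.fixture(scope="session")
def noisy_experiment():
    """Small polar experiment with the default noise model, for pipeline tests."""
    library = syn.default_library()
    effects = syn.default_effect_model(library, seed=5)
    acq = syn.AcquisitionConfig(windows=syn.polar_windows(), seed=5)
    design = syn.build_design(n_reps=4, n_qc=2)
    return syn.simulate_peaklists(library, effects, acq, design, "polar")
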