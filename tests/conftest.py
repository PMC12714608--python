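import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from crbdia.gradients import RPLC, default_gradients
from crbdia.simulate import (
    AcquisitionConfig,
    make_compound_panel,
    make_study_design,
    simulate_dia_acquisition,
    variable_swath_windows,
)

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")

#: fast nine-gradient family (2-6 min ramps) for unit tests; G5 = 4 min ramp
SHORT_RAMPS = (2.0, 2.5, 3.0, 3.5, 4.0, 4.5, 5.0, 5.5, 6.0)


@pytest.fixture(scope="session")
def short_gradients():
    return {RPLC: default_gradients(RPLC, ramp_minutes=SHORT_RAMPS, hold_minutes=1.0)}


@pytest.fixture(scope="session")
def small_panel(short_gradients):
    compounds, pairs = make_compound_panel(
        30, seed=11, coelution_fraction=0.2, gradients=short_gradients
    )
    return compounds, pairs


@pytest.fixture(scope="session")
def small_bundle(short_gradients, small_panel):
    """QC + sample runs for a 30-compound RPLC study on the fast gradients."""
    compounds, pairs = small_panel
    design, roles = make_study_design(compounds, seed=12)
    prec = np.array([c.precursor_mz(c.modes[0]) for c in compounds])
    acq = AcquisitionConfig(swath_windows=variable_swath_windows(prec), seed=13)
    bundle = simulate_dia_acquisition(
        design, compounds, short_gradients, acq, columns=(RPLC,), coeluting_pairs=pairs
    )
    bundle.planted_roles = roles
    return bundle


@pytest.fixture(scope="session")
def noise_free_config():
    def make(windows, seed=0, **kwargs):
        return AcquisitionConfig(
            swath_windows=windows,
            mass_jitter_ppm=0.0,
            rt_jitter_min=0.0,
            intensity_cv=0.0,
            noise_peaks_per_scan=0.0,
            seed=seed,
            **kwargs,
        )

    return make
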