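import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

from odorpulse import synthetic as synth
from odorpulse.vm import prepare_cell


@pytest.fixture(scope="session")
def coupled_session():
    """A strongly 2 Hz-coupled synthetic cell with blanks and two odours."""
    spec = synth.SynthCellSpec(
        preferred_phase=90.0, osc_amp=2.0, coupling_gain_2hz=2.0,
        coupling_gain_20hz=1.0, response_amp=2.0, noise_sd=2.0, seed=101,
    )
    return synth.make_cell_session(spec, odours=("A", "B"), freqs=(2.0, 20.0), n_reps=6)


@pytest.fixture(scope="session")
def coupled_prep(coupled_session):
    return prepare_cell(coupled_session.cell)


@pytest.fixture(scope="session")
def tuned_unit_session():
    """Small tuned unit population over the full five-frequency design."""
    freqs = (2.0, 5.0, 10.0, 15.0, 20.0)
    rng = np.random.default_rng(7)
    prefs = [2.0, 10.0, 20.0, 5.0]
    tuning = [
        {f: 25.0 * np.exp(-(((f - fp) / 4.0) ** 2)) for f in freqs} for fp in prefs
    ]
    return synth.make_unit_session(
        n_units=4, odours=("EB",), freqs=freqs, n_reps=12,
        freq_tuning=tuning, seed=11,
    )
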