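import pytest

from boostcmr import RunConfig
from boostcmr.epg_engine import BLOOD, MYOCARDIUM, SCAR
from boostcmr.phantom import PhantomSpec, RespiratoryModel, Vial
from boostcmr.sequences import (boost_defaults, cmra_defaults,
                                conventional_psir_defaults,
                                simulate_sequence)

TISSUES = (MYOCARDIUM, SCAR, BLOOD)


@pytest.fixture(scope="session")
def tissues():
    return TISSUES


@pytest.fixture(scope="session")
def boost_result():
    return simulate_sequence(boost_defaults(), TISSUES)


@pytest.fixture(scope="session")
def psir_result():
    return simulate_sequence(conventional_psir_defaults(), TISSUES)


@pytest.fixture(scope="session")
def cmra_result():
    return simulate_sequence(cmra_defaults(), TISSUES)


def small_spec(n_slices=1, n=64):
    """Small 3-vial phantom for fast acquisition tests."""
    return PhantomSpec(
        matrix=(n_slices, n, n), fov_mm=(320.0, 320.0),
        vials=(Vial((-60.0, -60.0), 35.0, 1),
               Vial((-60.0, 60.0), 35.0, 2),
               Vial((60.0, 0.0), 40.0, 3)))


@pytest.fixture
def small_phantom():
    return small_spec()


@pytest.fixture(scope="session")
def small_config():
    cfg = RunConfig(seed=7)
    cfg.phantom = small_spec()
    cfg.n_lines_per_beat_acq = 32
    cfg.respiration = RespiratoryModel(
        amplitude_si_mm=5.0, amplitude_rl_mm=2.5, period_s=8.0,
        waveform="sinusoid")
    return cfg
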