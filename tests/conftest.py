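import numpy as np
import pytest

from lfpsync.synth import CouplingSpec, GenConfig, SWDSpec, gen_session, gen_swd_train


@pytest.fixture
def short_cfg():
    return GenConfig(fs=2000.0, duration_s=10.0, seed=42)


@pytest.fixture
def clean_train():
    """A jitter-free 6-Hz, 12-cycle spike-wave train and its ground truth."""
    cfg = GenConfig(fs=2000.0, duration_s=2.0, seed=0)
    spec = SWDSpec(cycle_freq=6.0, n_cycles=12, spike_amp=800.0, wave_amp=100.0,
                   spike_width_ms=60.0, jitter_ms=0.0)
    sig, truth = gen_swd_train(cfg, spec)
    return sig, truth, spec


@pytest.fixture(scope="session")
def theta_session():
    """60-s 8-channel session with a single strong inter-hippocampal theta coupling."""
    cfg = GenConfig(fs=2000.0, duration_s=60.0, seed=9)
    return gen_session(
        cfg,
        couplings={("LHC", "RHC"): CouplingSpec(band_center=10.0, band_width=10.0, kappa=4.0)},
    )


@pytest.fixture(scope="session")
def swd_session():
    """120-s session with two scheduled spike-wave trains on the screw channels."""
    cfg = GenConfig(fs=2000.0, duration_s=120.0, seed=5)
    spec = SWDSpec(cycle_freq=6.0, spike_amp=700.0, wave_amp=100.0, jitter_ms=3.0)
    schedule = [(20.0, 2.0), (80.0, 2.5)]
    rec, truth = gen_session(cfg, swd_spec=spec, swd_schedule=schedule)
    return rec, truth
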