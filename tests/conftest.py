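import numpy as np
import pytest

from hrrlab.preprocessing import BeatSeries
from hrrlab.synthetic import GeneratorConfig, GroupParams, generate_subject


def make_noiseless_config(
    hr_rest=75.0,
    hr_peak=150.0,
    hr_plateau=100.0,
    tau=60.0,
    lf_amp=0.0,
    hf_amp=0.0,
    noise_sd=0.0,
    **kwargs,
):
    gp = GroupParams(
        hr_rest=(hr_rest, 0.0),
        hr_peak=(hr_peak, 0.0),
        hr_plateau=(hr_plateau, 0.0),
        tau=(tau, 0.0),
    )
    return GeneratorConfig(
        groups={"control": gp},
        n_per_group={"control": 1},
        lf_amp_ms=lf_amp,
        hf_amp_ms=hf_amp,
        noise_sd_ms=noise_sd,
        seed=0,
        **kwargs,
    )


@pytest.fixture(scope="session")
def noiseless_subject():
    """Deterministic subject: rest 75, peak 150, plateau 100, tau 60 s."""
    return generate_subject(make_noiseless_config(), "control", 12345)


@pytest.fixture(scope="session")
def hf_only_subject():
    """Subject with pure HF (0.25 Hz) RR modulation, amplitude 30 ms."""
    cfg = make_noiseless_config(hf_amp=30.0)
    return generate_subject(cfg, "control", 54321)


def constant_rr_beats(rr_s=1.0, n=300, rest_frac=0.3, ex_frac=0.4):
    """Constant-RR beat series with all three phases (for windowing tests)."""
    times = np.arange(1, n + 1) * rr_s
    phases = np.empty(n, dtype=object)
    n_rest = int(n * rest_frac)
    n_ex = int(n * ex_frac)
    phases[:n_rest] = "rest"
    phases[n_rest : n_rest + n_ex] = "exercise"
    phases[n_rest + n_ex :] = "recovery"
    return BeatSeries(
        beat_times=times,
        phases=phases,
        recovery_onset=float(times[n_rest + n_ex]),
    )
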