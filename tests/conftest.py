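"""Shared fixtures: hand-built waveforms with analytically known features."""

from __future__ import annotations

import numpy as np
import pytest

from nphys.ephys_features import CurrentClampSweep


def make_sweep(voltage: np.ndarray, *, sampling_khz: float = 10.0,
               onset: float = 100.0, duration: float = 500.0,
               amplitude: float = 0.0, protocol: str = "") -> CurrentClampSweep:
    time = np.arange(voltage.size) / sampling_khz
    return CurrentClampSweep(time=time, voltage=voltage,
                             sampling_khz=sampling_khz,
                             stimulus_amplitude=amplitude,
                             stimulus_onset=onset,
                             stimulus_duration=duration,
                             protocol=protocol)


def flat_sweep(level: float = -65.0, *, n_ms: float = 700.0,
               sampling_khz: float = 10.0, **kw) -> CurrentClampSweep:
    n = int(n_ms * sampling_khz) + 1
    return make_sweep(np.full(n, level), sampling_khz=sampling_khz, **kw)


def add_triangular_spike(sweep: CurrentClampSweep, peak_time: float,
                         peak_v: float = 0.0, rise_ms: float = 1.0,
                         fall_ms: float = 1.0) -> CurrentClampSweep:
    """Superimpose a symmetric triangular spike on a sweep, in place."""
    khz = sweep.sampling_khz
    ip = sweep.index_at(peak_time)
    nr, nf = int(round(rise_ms * khz)), int(round(fall_ms * khz))
    base = sweep.voltage[ip - nr]
    sweep.voltage[ip - nr:ip + 1] = np.linspace(base, peak_v, nr + 1)
    sweep.voltage[ip:ip + nf + 1] = np.linspace(peak_v, base, nf + 1)
    return sweep


def rc_step_sweep(*, rmp: float = -70.0, r_mohm: float = 150.0,
                  tau_ms: float = 12.0, amplitude_pa: float = -30.0,
                  onset: float = 100.0, duration: float = 500.0,
                  post: float = 100.0, sampling_khz: float = 10.0,
                  noise_sigma: float = 0.0,
                  rng: np.random.Generator | None = None) -> CurrentClampSweep:
    """Analytic passive RC response to a current step (no spikes)."""
    n = int(round((onset + duration + post) * sampling_khz)) + 1
    t = np.arange(n) / sampling_khz
    dv_ss = r_mohm * amplitude_pa / 1000.0
    v = np.full(n, rmp, dtype=float)
    on = (t >= onset) & (t < onset + duration)
    v[on] = rmp + dv_ss * (1 - np.exp(-(t[on] - onset) / tau_ms))
    after = t >= onset + duration
    v_end = rmp + dv_ss * (1 - np.exp(-duration / tau_ms))
    v[after] = rmp + (v_end - rmp) * np.exp(-(t[after] - onset - duration)
                                            / tau_ms)
    if noise_sigma > 0:
        v += (rng or np.random.default_rng(0)).normal(0, noise_sigma, n)
    return make_sweep(v, sampling_khz=sampling_khz, onset=onset,
                      duration=duration, amplitude=amplitude_pa,
                      protocol="subthreshold_10pA")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
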