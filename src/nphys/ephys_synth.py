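"""Ground-truth current-clamp sweep generator.

A leaky integrate-and-fire (LIF) cell with a stereotyped rendered spike
waveform produces sweep sets matching the step protocols analysed by
:mod:`nphys.ephys_features`, together with a ground-truth record (Rin,
tau, Cm, rheobase, per-amplitude spike counts) so parameter recovery and
AP detection can be tested against known values.

The subthreshold dynamics ``tau dV/dt = -(V - E_L) + R I(t)`` are
advanced with the exact exponential solution, so the analytic step
response ``V(t) = E_L + R I (1 - exp(-t/tau))`` holds to machine
precision. Threshold crossing is detected with a small numerical
tolerance (1e-9 mV), which makes the closed-form rheobase
``I = (V_th - E_L)/R`` attainable at the boundary amplitude within a
500-ms step. Gaussian noise is recording noise added to the sampled
trace; it does not feed back into the dynamics, so the spike log is
exact for any noise level.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .ephys_features import CurrentClampSweep, StepProtocolSpec

V_TH_TOLERANCE_MV = 1e-9
SPIKE_RISE_MS = 1.0
SPIKE_FALL_MS = 1.0
NADIR_BELOW_RESET_MV = 5.0
PRE_STIMULUS_MS = 100.0
POST_STIMULUS_MS = 100.0


@dataclass
class LifParams:
    """LIF cell parameters; units mV, MOhm, ms, pA."""

    e_l: float = -70.0              # resting potential
    r_in: float = 200.0             # input resistance, MOhm
    tau: float = 15.0               # membrane time constant, ms
    v_th: float = -50.0             # spike threshold
    v_reset: float = -65.0          # post-spike reset
    refractory: float = 2.0         # hold at reset after the waveform, ms
    spike_peak: float = 30.0        # rendered AP peak
    noise_sigma: float = 0.0        # recording noise s.d., mV
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.v_th > self.e_l and self.v_reset <= self.v_th
                and self.tau > 0 and self.r_in > 0):
            raise ValueError("invalid LIF parameters")

    @property
    def rheobase_pa(self) -> float:
        """Closed-form threshold current (V_th - E_L)/R, in pA."""
        return (self.v_th - self.e_l) / self.r_in * 1000.0

    def grid_rheobase(self, amplitudes) -> float | None:
        """Smallest grid amplitude whose steady state reaches V_th."""
        ok = [a for a in amplitudes if a >= self.rheobase_pa - 1e-9]
        return min(ok) if ok else None


def simulate_sweep(params: LifParams, amplitude: float, *,
                   step_duration: float = 500.0,
                   sampling_khz: float = 10.0,
                   onset: float = PRE_STIMULUS_MS,
                   post: float = POST_STIMULUS_MS,
                   protocol: str = "",
                   rng: np.random.Generator | None = None
                   ) -> tuple[CurrentClampSweep, list[float]]:
    """Simulate one current step; returns the sweep and spike-peak times."""
    if sampling_khz < 5.0:
        raise ValueError("sampling rate < 5 kHz")
    dt = 1.0 / sampling_khz
    n = int(round((onset + step_duration + post) * sampling_khz)) + 1
    time = np.arange(n) * dt
    i_on = int(round(onset * sampling_khz))
    i_off = int(round((onset + step_duration) * sampling_khz))
    change_points = sorted({0, i_on, i_off, n})

    voltage = np.empty(n)
    rise_n = max(1, int(round(SPIKE_RISE_MS * sampling_khz)))
    fall_n = max(1, int(round(SPIKE_FALL_MS * sampling_khz)))
    refr_n = int(round(params.refractory * sampling_khz))
    nadir = params.v_reset - NADIR_BELOW_RESET_MV

    spike_times: list[float] = []
    v = params.e_l
    i = 0
    while i < n:
        j = next(cp for cp in change_points if cp > i)
        amp = amplitude if i_on <= i < i_off else 0.0
        v_ss = params.e_l + params.r_in * amp / 1000.0
        seg = v_ss + (v - v_ss) * np.exp(-(time[i:j] - time[i]) / params.tau)
        if v_ss >= params.v_th - V_TH_TOLERANCE_MV:
            above = seg >= params.v_th - V_TH_TOLERANCE_MV
            if above.any():
                k = i + int(np.argmax(above))      # crossing sample
                voltage[i:k + 1] = seg[:k + 1 - i]
                # stereotyped spike: linear rise to peak, fall to nadir,
                # then clamp at V_reset for the refractory period
                p = min(k + rise_n, n - 1)
                voltage[k:p + 1] = np.linspace(voltage[k], params.spike_peak,
                                               p - k + 1)
                if p == k + rise_n:
                    spike_times.append(float(time[p]))
                q = min(p + fall_n, n - 1)
                voltage[p:q + 1] = np.linspace(voltage[p], nadir, q - p + 1)
                r = min(q + 1 + refr_n, n)
                voltage[q + 1:r] = params.v_reset
                v = params.v_reset
                i = r
                continue
        voltage[i:j] = seg
        v = seg[-1]
        i = j

    if params.noise_sigma > 0:
        if rng is None:
            rng = np.random.default_rng(params.seed)
        voltage = voltage + rng.normal(0.0, params.noise_sigma, n)

    sweep = CurrentClampSweep(time=time, voltage=voltage,
                              sampling_khz=sampling_khz,
                              stimulus_amplitude=amplitude,
                              stimulus_onset=onset,
                              stimulus_duration=step_duration,
                              protocol=protocol)
    return sweep, spike_times


def simulate_protocol(params: LifParams, protocol: StepProtocolSpec, *,
                      sampling_khz: float = 10.0,
                      rng: np.random.Generator | None = None
                      ) -> tuple[list[CurrentClampSweep], dict[float, list[float]]]:
    """Simulate every amplitude of a protocol; returns sweeps and spike log."""
    if rng is None:
        rng = np.random.default_rng(params.seed)
    sweeps, log = [], {}
    for amp in protocol.amplitudes:
        sw, st = simulate_sweep(params, amp,
                                step_duration=protocol.step_duration,
                                sampling_khz=sampling_khz,
                                protocol=protocol.kind, rng=rng)
        sweeps.append(sw)
        log[float(amp)] = st
    return sweeps, log


def simulate_protocol_set(params: LifParams, out_dir: str | Path, *,
                          cell_id: str = "sim_cell", genotype: str = "WT",
                          sampling_khz: float = 10.0,
                          protocols: tuple[StepProtocolSpec, ...] | None = None
                          ) -> Path:
    """Write a full sweep set (CSVs + manifest) plus its ground truth.

    The manifest matches the :func:`nphys.ephys_features.load_sweep_set`
    format; ``ground_truth.json`` records R, tau, Cm, the grid rheobase,
    and the spike count at every simulated amplitude. Deterministic for a
    fixed seed.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if protocols is None:
        protocols = (StepProtocolSpec.subthreshold_10pa(),
                     StepProtocolSpec.excitability_20pa())
    rng = np.random.default_rng(params.seed)
    entries, counts = [], {}
    for proto in protocols:
        sweeps, log = simulate_protocol(params, proto,
                                        sampling_khz=sampling_khz, rng=rng)
        for sw, amp in zip(sweeps, proto.amplitudes):
            fname = f"{cell_id}_{proto.kind}_{amp:+.0f}pA.csv"
            with open(out_dir / fname, "w") as fh:
                fh.write("time_ms,voltage_mV\n")
                for t, v in zip(sw.time, sw.voltage):
                    fh.write(f"{t:.4f},{v:.6f}\n")
            entries.append({"file": fname, "amplitude_pA": float(amp),
                            "onset_ms": sw.stimulus_onset,
                            "duration_ms": sw.stimulus_duration,
                            "protocol": proto.kind, "holding_mV": None})
        if proto.kind == "excitability_20pA":
            counts = {f"{a:g}": len(log[float(a)]) for a in proto.amplitudes}
    manifest = {"cell_id": cell_id, "genotype": genotype,
                "sampling_khz": sampling_khz, "sweeps": entries}
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    exc_amps = StepProtocolSpec.excitability_20pa().amplitudes
    truth = {"params": asdict(params),
             "input_resistance_mohm": params.r_in,
             "tau_ms": params.tau,
             "capacitance_pf": params.tau / params.r_in * 1000.0,
             "rheobase_pa": params.grid_rheobase(exc_amps),
             "spike_counts": counts}
    (out_dir / "ground_truth.json").write_text(json.dumps(truth, indent=1))
    return out_dir / "manifest.json"
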