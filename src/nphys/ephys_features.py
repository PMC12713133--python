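"""Intrinsic-excitability feature extraction from current-clamp sweeps.

Implements the standard whole-cell current-clamp analysis chain for
step-protocol recordings: passive membrane properties (RMP, input
resistance, membrane time constant, capacitance), action-potential
detection and per-AP waveform features, input-output / rheobase
excitability measures, fast-spiking (FS) interneuron classification, and
per-cell quality-control verdicts.

Conventions
-----------
* time in milliseconds, voltage in millivolts, current in picoamps,
  resistance in megaohms, capacitance in picofarads.
* An AP is any local voltage maximum exceeding -10 mV, or rising at
  least 70 mV above the pre-stimulus baseline, with a 1-ms refractory
  deduplication.
* AP voltage threshold is the point where dV/dt first exceeds 5% of the
  maximal upstroke dV/dt of that AP (searched up to 5 ms before the peak).
* FS cells: membrane time constant < 15 ms and > 35 APs at the 400-pA,
  500-ms step (i.e. > 70 Hz).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, signal, stats

# --- analysis constants (defaults mirrored by pipeline.RunConfig) -----
AP_VOLTAGE_CUTOFF_MV = -10.0     # peak above this is an AP
AP_AMPLITUDE_CUTOFF_MV = 70.0    # or this far above pre-stimulus baseline
AP_MIN_SEPARATION_MS = 1.0       # peak deduplication refractory
THRESHOLD_DVDT_FRACTION = 0.05   # of maximal upstroke dV/dt
THRESHOLD_BACK_WINDOW_MS = 5.0
FAHP_SEARCH_WINDOW_MS = 10.0     # after peak, bounded by next AP threshold
STEADY_STATE_WINDOW_MS = 100.0   # tail of the step used for delta-V
TAU_FIT_MAX_MS = 200.0           # fit window cap after stimulus onset
TAU_BOUNDS_MS = (0.1, 200.0)
RMP_MIN_BASELINE_MS = 50.0
FS_TAU_MAX_MS = 15.0
FS_MIN_APS_400PA = 35
QC_RMP_MAX_MV = -55.0
QC_ACCESS_RESISTANCE_MAX_MOHM = 25.0
QC_ACCESS_RESISTANCE_MAX_VARIATION = 0.30
QC_INPUT_RESISTANCE_MAX_MOHM = 1000.0
QC_MIN_EVOKED_APS = 2            # "more than one AP evoked"


# ---------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------

@dataclass
class CurrentClampSweep:
    """One voltage trace with its step-current stimulus metadata."""

    time: np.ndarray                 # ms, uniform grid from 0
    voltage: np.ndarray              # mV
    sampling_khz: float
    stimulus_amplitude: float        # pA
    stimulus_onset: float            # ms
    stimulus_duration: float         # ms
    holding_mv: float | None = None
    protocol: str = ""               # e.g. subthreshold_10pA, excitability_20pA

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.voltage = np.asarray(self.voltage, dtype=float)
        if self.time.shape != self.voltage.shape or self.time.ndim != 1:
            raise ValueError("time and voltage must be matching 1-D arrays")
        if self.sampling_khz < 5.0:
            raise ValueError(f"sampling rate {self.sampling_khz} kHz < 5 kHz")
        dt = np.diff(self.time)
        if dt.size and (dt.min() <= 0 or
                        np.ptp(dt) > 1e-6 * np.abs(dt.mean())):
            raise ValueError("time grid must be strictly increasing and uniform")
        t_end = self.stimulus_onset + self.stimulus_duration
        if not (self.time[0] <= self.stimulus_onset and t_end <= self.time[-1]):
            raise ValueError("stimulus window must lie inside the trace")

    @property
    def dt_ms(self) -> float:
        return 1.0 / self.sampling_khz

    def index_at(self, t_ms: float) -> int:
        return int(round((t_ms - self.time[0]) / self.dt_ms))


@dataclass(frozen=True)
class StepProtocolSpec:
    """A family of current steps sharing a duration."""

    amplitudes: tuple[float, ...]
    step_duration: float            # ms
    kind: str

    @classmethod
    def subthreshold_10pa(cls) -> "StepProtocolSpec":
        # 6 steps of 10 pA starting at -30 pA, 500 ms
        return cls(tuple(-30.0 + 10.0 * i for i in range(6)), 500.0,
                   "subthreshold_10pA")

    @classmethod
    def excitability_20pa(cls) -> "StepProtocolSpec":
        # 0..400 pA in 20 pA increments, 500 ms
        return cls(tuple(20.0 * i for i in range(21)), 500.0,
                   "excitability_20pA")

    @classmethod
    def brief_5ms(cls, max_pa: float = 400.0) -> "StepProtocolSpec":
        return cls(tuple(np.arange(10.0, max_pa + 1, 10.0)), 5.0, "brief_5ms")


@dataclass
class PassiveProperties:
    rmp: float                      # mV
    input_resistance: float         # MOhm
    tau: float                      # ms
    capacitance: float              # pF


@dataclass
class ActionPotentialEvent:
    peak_time: float
    peak_voltage: float
    threshold_time: float | None = None
    threshold_voltage: float | None = None
    fahp_voltage: float | None = None
    amplitude: float | None = None
    half_width: float | None = None
    max_rise_slope: float | None = None
    max_decay_slope: float | None = None
    flags: list[str] = field(default_factory=list)


@dataclass
class ExcitabilityProfile:
    io_curve: dict[float, int]
    rheobase: float | None
    latency_first_ap: float | None = None
    first_isi: float | None = None
    fahp: float | None = None
    flags: list[str] = field(default_factory=list)


@dataclass
class NeuronSummary:
    cell_id: str
    genotype: str
    passive: PassiveProperties | None
    profile: ExcitabilityProfile | None
    class_label: str = "unclassified"          # FS | non_FS | unclassified
    qc_included: bool = True
    qc_reasons: list[str] = field(default_factory=list)
    access_resistance: float | None = None

    def as_row(self) -> dict:
        row: dict = {"cell_id": self.cell_id, "genotype": self.genotype,
                     "class_label": self.class_label,
                     "qc": "included" if self.qc_included else "excluded",
                     "qc_reasons": ";".join(self.qc_reasons),
                     "access_resistance_mohm": self.access_resistance}
        if self.passive is not None:
            row.update(rmp_mv=self.passive.rmp,
                       input_resistance_mohm=self.passive.input_resistance,
                       tau_ms=self.passive.tau,
                       capacitance_pf=self.passive.capacitance)
        if self.profile is not None:
            row.update(rheobase_pa=self.profile.rheobase,
                       latency_ms=self.profile.latency_first_ap,
                       first_isi_ms=self.profile.first_isi,
                       fahp_mv=self.profile.fahp,
                       max_ap_count=max(self.profile.io_curve.values())
                       if self.profile.io_curve else 0)
        return row


# ---------------------------------------------------------------------
# passive properties
# ---------------------------------------------------------------------

def measure_rmp(sweep: CurrentClampSweep) -> float:
    """Resting membrane potential: mean voltage before stimulus onset."""
    if sweep.stimulus_onset - sweep.time[0] < RMP_MIN_BASELINE_MS:
        raise ValueError(
            f"pre-stimulus baseline shorter than {RMP_MIN_BASELINE_MS} ms")
    pre = sweep.voltage[sweep.time < sweep.stimulus_onset]
    return float(pre.mean())


def _steady_state_delta_v(sweep: CurrentClampSweep) -> float:
    """Mean voltage over the last 100 ms of the step, minus the sweep RMP."""
    t_end = sweep.stimulus_onset + sweep.stimulus_duration
    t0 = t_end - min(STEADY_STATE_WINDOW_MS, sweep.stimulus_duration)
    win = (sweep.time >= t0) & (sweep.time < t_end)
    return float(sweep.voltage[win].mean() - measure_rmp(sweep))


def fit_input_resistance(sweeps: Sequence[CurrentClampSweep]) -> float:
    """Input resistance (MOhm) from the slope of the steady-state V-I relation.

    Ordinary least squares of steady-state delta-V (mV) on injected current
    (pA) over AP-free subthreshold sweeps; the slope in mV/pA equals GOhm,
    reported in MOhm (x1000).
    """
    clean = [s for s in sweeps if not detect_aps(s)]
    if len(clean) < 3:
        raise ValueError("need at least 3 AP-free subthreshold sweeps")
    amps = np.array([s.stimulus_amplitude for s in clean])
    if np.ptp(amps) == 0:
        raise ValueError("zero spread in injected current")
    dv = np.array([_steady_state_delta_v(s) for s in clean])
    slope = stats.linregress(amps, dv).slope       # mV/pA = GOhm
    return float(slope * 1000.0)


def fit_membrane_tau(sweeps: Sequence[CurrentClampSweep]) -> float:
    """Membrane time constant (ms) from exponential fits to the onset decay.

    Each hyperpolarizing sweep is fit with
    ``V(t) = V_ss + (V0 - V_ss) * exp(-(t - onset)/tau)`` over the first
    ``min(200 ms, step duration)`` after onset; the mean tau over sweeps
    that converge inside (0.1, 200) ms is returned.
    """
    hyper = [s for s in sweeps if s.stimulus_amplitude < 0]
    if not hyper:
        raise ValueError("need at least one hyperpolarizing sweep")
    taus = []
    for s in hyper:
        t_hi = s.stimulus_onset + min(TAU_FIT_MAX_MS, s.stimulus_duration)
        win = (s.time >= s.stimulus_onset) & (s.time <= t_hi)
        t = s.time[win] - s.stimulus_onset
        v = s.voltage[win]
        v0, v_ss = v[0], v[-len(v) // 4:].mean()
        try:
            popt, _ = optimize.curve_fit(
                lambda tt, vss, vv0, tau: vss + (vv0 - vss) * np.exp(-tt / tau),
                t, v, p0=(v_ss, v0, 20.0),
                bounds=([-150, -150, TAU_BOUNDS_MS[0]],
                        [50, 50, TAU_BOUNDS_MS[1]]), maxfev=2000)
        except RuntimeError:
            continue
        tau = popt[2]
        if TAU_BOUNDS_MS[0] < tau < TAU_BOUNDS_MS[1]:
            taus.append(tau)
    if not taus:
        raise ValueError("tau fit failed on every hyperpolarizing sweep")
    return float(np.mean(taus))


def compute_capacitance(input_resistance: float, tau: float) -> float:
    """Membrane capacitance Cm = tau / Rin (ms / MOhm = nF), in pF."""
    if input_resistance <= 0 or tau <= 0:
        raise ValueError("input resistance and tau must be positive")
    return tau / input_resistance * 1000.0


# ---------------------------------------------------------------------
# action potentials
# ---------------------------------------------------------------------

def detect_aps(sweep: CurrentClampSweep) -> list[ActionPotentialEvent]:
    """Detect AP peaks: local maxima above -10 mV or >= 70 mV over baseline.

    Peaks closer than 1 ms are deduplicated (the higher one wins, via the
    peak-finder distance constraint). Returns events carrying peak
    position only; use :func:`ap_features` / :func:`ap_train` to fill the
    waveform features.
    """
    baseline = float(
        sweep.voltage[sweep.time < sweep.stimulus_onset].mean()
    ) if sweep.stimulus_onset > sweep.time[0] else float(sweep.voltage[0])
    min_dist = max(1, int(round(AP_MIN_SEPARATION_MS * sweep.sampling_khz)))
    height = min(AP_VOLTAGE_CUTOFF_MV, baseline + AP_AMPLITUDE_CUTOFF_MV)
    peaks, _ = signal.find_peaks(sweep.voltage, height=height,
                                 distance=min_dist)
    return [ActionPotentialEvent(peak_time=float(sweep.time[i]),
                                 peak_voltage=float(sweep.voltage[i]))
            for i in peaks]


def _dvdt(sweep: CurrentClampSweep) -> np.ndarray:
    """dV/dt (mV/ms) by central differences; 3-point smoothing below 10 kHz."""
    v = sweep.voltage
    if sweep.sampling_khz < 10.0:
        v = np.convolve(v, np.ones(3) / 3.0, mode="same")
    return np.gradient(v, sweep.dt_ms)


def _interp_crossing(t: np.ndarray, v: np.ndarray, level: float,
                     rising: bool) -> float | None:
    """Linearly interpolated time of the first crossing of `level`."""
    above = v >= level
    idx = np.flatnonzero(above[1:] != above[:-1])
    for i in idx:
        if (rising and above[i + 1]) or (not rising and above[i]):
            frac = (level - v[i]) / (v[i + 1] - v[i])
            return float(t[i] + frac * (t[i + 1] - t[i]))
    return None


def ap_features(sweep: CurrentClampSweep, peak_time: float, *,
                next_threshold_time: float | None = None,
                dvdt: np.ndarray | None = None) -> ActionPotentialEvent:
    """Full waveform features for one AP identified by its peak time.

    The fAHP search window ends at the following AP's threshold when
    provided (pass it from :func:`ap_train`), else 10 ms after the peak.
    """
    if dvdt is None:
        dvdt = _dvdt(sweep)
    ip = sweep.index_at(peak_time)
    ev = ActionPotentialEvent(peak_time=float(sweep.time[ip]),
                              peak_voltage=float(sweep.voltage[ip]))

    lo = max(0, ip - int(round(THRESHOLD_BACK_WINDOW_MS * sweep.sampling_khz)))
    up = dvdt[lo:ip + 1]
    if up.size < 2:
        ev.flags.append("threshold_undefined")
        return ev
    level = THRESHOLD_DVDT_FRACTION * up.max()
    j = lo + int(np.argmax(up))              # maximal upstroke sample
    while j > lo and dvdt[j - 1] >= level:
        j -= 1
    if j == lo and dvdt[j] >= level:
        # dV/dt never dropped below 5% inside the back-window: the
        # crossing lies before it, so the threshold is undefined
        ev.flags.append("threshold_undefined")
        return ev
    ev.threshold_time = float(sweep.time[j])
    ev.threshold_voltage = float(sweep.voltage[j])

    # fAHP nadir in (peak, next threshold or peak + 10 ms]
    t_hi = peak_time + FAHP_SEARCH_WINDOW_MS
    if next_threshold_time is not None:
        t_hi = min(t_hi, next_threshold_time)
    ihi = min(sweep.voltage.size, sweep.index_at(t_hi) + 1)
    if ihi <= ip + 1:
        ev.flags.append("fahp_undefined")
        return ev
    seg = sweep.voltage[ip + 1:ihi]
    inad = ip + 1 + int(np.argmin(seg))
    ev.fahp_voltage = float(sweep.voltage[inad])
    ev.amplitude = ev.peak_voltage - ev.fahp_voltage

    # width at half-height between threshold and peak levels
    half = 0.5 * (ev.peak_voltage + ev.threshold_voltage)
    t_rise = _interp_crossing(sweep.time[j:ip + 1], sweep.voltage[j:ip + 1],
                              half, rising=True)
    t_fall = _interp_crossing(sweep.time[ip:inad + 1],
                              sweep.voltage[ip:inad + 1], half, rising=False)
    if t_rise is not None and t_fall is not None:
        ev.half_width = t_fall - t_rise
    else:
        ev.flags.append("half_width_undefined")

    ev.max_rise_slope = float(dvdt[j:ip + 1].max())
    ev.max_decay_slope = float(dvdt[ip:inad + 1].min())
    return ev


def ap_train(sweep: CurrentClampSweep) -> list[ActionPotentialEvent]:
    """All APs in a sweep with full features.

    Thresholds are located in a first pass so each AP's fAHP window can be
    bounded by the next AP's threshold.
    """
    peaks = detect_aps(sweep)
    if not peaks:
        return []
    dvdt = _dvdt(sweep)
    prelim = [ap_features(sweep, p.peak_time, dvdt=dvdt) for p in peaks]
    out = []
    for i, p in enumerate(peaks):
        nxt = None
        if i + 1 < len(prelim) and prelim[i + 1].threshold_time is not None:
            nxt = prelim[i + 1].threshold_time
        out.append(ap_features(sweep, p.peak_time,
                               next_threshold_time=nxt, dvdt=dvdt))
    return out


# ---------------------------------------------------------------------
# excitability
# ---------------------------------------------------------------------

def excitability_profile(
        sweeps: Sequence[CurrentClampSweep]) -> ExcitabilityProfile:
    """Input-output curve, rheobase, and rheobase+100 pA spike-timing features.

    Latency, first ISI, and fAHP (averaged over the first 5 APs) are
    measured on the sweep at rheobase + 100 pA; they are left absent when
    that amplitude is beyond the protocol or the sweep has < 2 APs.
    """
    by_amp = {float(s.stimulus_amplitude): s for s in sweeps}
    io_curve = {a: len(detect_aps(by_amp[a])) for a in sorted(by_amp)}
    prof = ExcitabilityProfile(io_curve=io_curve, rheobase=None)
    spiking = [a for a, k in io_curve.items() if k >= 1]
    if not spiking:
        prof.flags.append("no_aps")
        return prof
    prof.rheobase = min(spiking)

    target = prof.rheobase + 100.0
    if target not in by_amp:
        prof.flags.append("rheobase_plus_100_unavailable")
        return prof
    sw = by_amp[target]
    aps = ap_train(sw)
    if len(aps) < 2:
        prof.flags.append("fewer_than_2_aps_at_rheobase_plus_100")
        return prof
    prof.latency_first_ap = aps[0].peak_time - sw.stimulus_onset
    prof.first_isi = aps[1].peak_time - aps[0].peak_time
    fahps = [ap.threshold_voltage - ap.fahp_voltage for ap in aps[:5]
             if ap.threshold_voltage is not None and ap.fahp_voltage is not None]
    if fahps:
        prof.fahp = float(np.mean(fahps))
        if len(fahps) < 5:
            prof.flags.append("fahp_fewer_than_5_aps")
    return prof


def classify_fs(tau: float | None, ap_count_400pa: int | None, *,
                tau_max_ms: float = FS_TAU_MAX_MS,
                min_aps: int = FS_MIN_APS_400PA) -> str:
    """FS iff tau < 15 ms and more than 35 APs at the 400-pA step (> 70 Hz)."""
    if tau is None or ap_count_400pa is None:
        return "unclassified"
    return "FS" if (tau < tau_max_ms and ap_count_400pa > min_aps) \
        else "non_FS"


def qc_neuron(summary: NeuronSummary, *,
              access_resistance_end: float | None = None) -> NeuronSummary:
    """Apply the per-cell inclusion criteria; sets qc verdict in place.

    Excluded when RMP >= -55 mV, access resistance >= 25 MOhm (with
    end-of-recording variation >= 30% when both endpoints are given),
    input resistance >= 1000 MOhm, or at most one AP evoked across the
    0-400 pA steps.
    """
    reasons = []
    if summary.passive is not None:
        if summary.passive.rmp >= QC_RMP_MAX_MV:
            reasons.append("RMP")
        if summary.passive.input_resistance >= QC_INPUT_RESISTANCE_MAX_MOHM:
            reasons.append("input resistance")
    ra = summary.access_resistance
    if ra is not None:
        ra_bad = ra >= QC_ACCESS_RESISTANCE_MAX_MOHM
        if ra_bad and access_resistance_end is not None:
            ra_bad = abs(access_resistance_end - ra) / ra \
                >= QC_ACCESS_RESISTANCE_MAX_VARIATION
        if ra_bad:
            reasons.append("access resistance")
    if summary.profile is not None and summary.profile.io_curve:
        if max(summary.profile.io_curve.values()) < QC_MIN_EVOKED_APS:
            reasons.append("evoked APs")
    summary.qc_reasons = reasons
    summary.qc_included = not reasons
    return summary


# ---------------------------------------------------------------------
# file I/O (CSV sweeps + JSON manifest, TSV outputs)
# ---------------------------------------------------------------------

def load_sweep_set(manifest_path: str | Path) -> tuple[dict, list[CurrentClampSweep]]:
    """Read a sweep-set manifest and its CSV traces.

    Manifest: ``{cell_id, genotype, sampling_khz, sweeps: [{file,
    amplitude_pA, onset_ms, duration_ms, protocol, holding_mV}]}``; each
    CSV has columns ``time_ms,voltage_mV``.
    """
    manifest_path = Path(manifest_path)
    meta = json.loads(manifest_path.read_text())
    sweeps = []
    for entry in meta["sweeps"]:
        df = pd.read_csv(manifest_path.parent / entry["file"])
        sweeps.append(CurrentClampSweep(
            time=df["time_ms"].to_numpy(),
            voltage=df["voltage_mV"].to_numpy(),
            sampling_khz=meta["sampling_khz"],
            stimulus_amplitude=entry["amplitude_pA"],
            stimulus_onset=entry["onset_ms"],
            stimulus_duration=entry["duration_ms"],
            holding_mv=entry.get("holding_mV"),
            protocol=entry.get("protocol", "")))
    return meta, sweeps


def summarize_cell(meta: dict,
                   sweeps: Sequence[CurrentClampSweep]) -> NeuronSummary:
    """Run the full extraction chain for one cell's sweep set."""
    sub = [s for s in sweeps if s.protocol == "subthreshold_10pA"]
    exc = [s for s in sweeps if s.protocol == "excitability_20pA"]
    passive = None
    if sub:
        rmp = measure_rmp(sub[0])
        rin = fit_input_resistance(sub)
        tau = fit_membrane_tau(sub)
        passive = PassiveProperties(rmp, rin, tau,
                                    compute_capacitance(rin, tau))
    profile = excitability_profile(exc) if exc else None
    count_400 = profile.io_curve.get(400.0) if profile else None
    label = classify_fs(passive.tau if passive else None, count_400)
    summary = NeuronSummary(cell_id=meta["cell_id"],
                            genotype=meta.get("genotype", ""),
                            passive=passive, profile=profile,
                            class_label=label,
                            access_resistance=meta.get("access_resistance_mohm"))
    return qc_neuron(summary,
                     access_resistance_end=meta.get("access_resistance_end_mohm"))


def write_summary_table(summaries: Iterable[NeuronSummary],
                        path: str | Path) -> pd.DataFrame:
    df = pd.DataFrame([s.as_row() for s in summaries])
    df.to_csv(path, sep="\t", index=False)
    return df


def write_ap_table(cell_id: str, sweeps: Sequence[CurrentClampSweep],
                   path: str | Path) -> pd.DataFrame:
    rows = []
    for s in sweeps:
        for k, ev in enumerate(ap_train(s)):
            d = asdict(ev)
            d["flags"] = ";".join(d["flags"])
            rows.append({"cell_id": cell_id,
                         "amplitude_pa": s.stimulus_amplitude,
                         "ap_index": k, **d})
    df = pd.DataFrame(rows)
    df.to_csv(path, sep="\t", index=False)
    return df
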