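"""Somatic calcium-activity quantification from ROI fluorescence.

Pipeline: ROI trace extraction (mean ROI pixel intensity minus mean
background), dF/F0 with F0 the minimal-mean 3.5-s window, event
detection at 3x the baseline standard deviation, and the four per-cell
summary statistics: AUC per 35-s window, mean event peak amplitude, mean
event full width, and event frequency per minute.

The dF/F0 readout is invariant to rescaling the raw fluorescence (F0
scales with F) but not to additive offsets — background subtraction
matters and is applied upstream in :func:`extract_roi_trace`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

BASELINE_SECONDS = 3.5
EVENT_SIGMA_MULTIPLE = 3.0
AUC_WINDOW_SECONDS = 35.0
MIN_EVENT_FRAMES = 2
DEFAULT_FRAME_RATE_HZ = 1.7
SIGMA_FLOOR = 1e-4


@dataclass
class FluorescenceTrace:
    """Raw ROI fluorescence time series (background already subtracted)."""

    frame_times: np.ndarray          # s
    f: np.ndarray                    # a.u.
    roi_id: str = ""
    cell_class: str = "unknown"      # interneuron | pyramidal | unknown

    def __post_init__(self) -> None:
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        self.f = np.asarray(self.f, dtype=float)
        if self.frame_times.shape != self.f.shape:
            raise ValueError("frame_times and f must match")

    @property
    def frame_interval(self) -> float:
        return float(np.median(np.diff(self.frame_times)))

    @property
    def frame_rate(self) -> float:
        return 1.0 / self.frame_interval


@dataclass
class DffTrace:
    frame_times: np.ndarray
    dff: np.ndarray
    f0: float
    baseline_window: tuple[float, float]     # (start, end) s
    baseline_sigma: float
    roi_id: str = ""
    cell_class: str = "unknown"

    @property
    def frame_interval(self) -> float:
        return float(np.median(np.diff(self.frame_times)))


@dataclass
class CalciumEvent:
    onset: float
    offset: float
    peak_dff: float
    duration: float


@dataclass
class CellCalciumSummary:
    roi_id: str
    cell_class: str
    auc: float                  # dF/F0 * s per 35-s window (mean over windows)
    amplitude: float            # mean event peak dF/F0
    duration: float             # mean event full width, s
    frequency: float            # events / min
    n_events: int
    flags: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------

def extract_roi_trace(stack: np.ndarray, roi_mask: np.ndarray,
                      background_mask: np.ndarray, *,
                      frame_times: np.ndarray | None = None,
                      frame_rate: float = DEFAULT_FRAME_RATE_HZ,
                      roi_id: str = "", cell_class: str = "unknown"
                      ) -> FluorescenceTrace:
    """Per frame, mean(ROI pixels) minus mean(background pixels)."""
    roi_mask = np.asarray(roi_mask, dtype=bool)
    background_mask = np.asarray(background_mask, dtype=bool)
    if not roi_mask.any() or not background_mask.any():
        raise ValueError("ROI and background masks must be nonempty")
    if roi_mask.shape != stack.shape[1:]:
        raise ValueError("mask shape must match frame shape")
    f = stack[:, roi_mask].mean(axis=1) - stack[:, background_mask].mean(axis=1)
    if frame_times is None:
        frame_times = np.arange(stack.shape[0]) / frame_rate
    return FluorescenceTrace(frame_times, f, roi_id=roi_id,
                             cell_class=cell_class)


def apply_exclusion_mask(trace: FluorescenceTrace,
                         keep: np.ndarray) -> FluorescenceTrace:
    """Excise frames flagged by a motion/struggle exclusion mask.

    ``keep`` is boolean per frame; excluded frames are removed before any
    downstream computation (times are kept, so gaps remain visible).
    """
    keep = np.asarray(keep, dtype=bool)
    return FluorescenceTrace(trace.frame_times[keep], trace.f[keep],
                             roi_id=trace.roi_id, cell_class=trace.cell_class)


MAD_TO_SD = 1.4826      # consistency factor for Gaussian noise


def compute_dff(trace: FluorescenceTrace,
                baseline_seconds: float = BASELINE_SECONDS) -> DffTrace:
    """dF/F0 with F0 = minimum over all contiguous baseline-length windows.

    The window length is ``round(baseline_seconds * frame_rate)`` frames;
    F0 is the smallest window mean (the quietest stretch of the
    recording). The baseline noise sigma is estimated robustly as the
    median-absolute-deviation s.d. of dF/F0 over the whole recording
    (transients are sparse, so the MAD tracks the baseline noise; the
    handful of frames inside a 3.5-s window would give an estimate too
    unstable to threshold against), floored at 1e-4 so noiseless
    synthetic traces stay finite.
    """
    n = trace.f.size
    w = max(1, int(round(baseline_seconds * trace.frame_rate)))
    if n <= w:
        raise ValueError("trace shorter than the baseline window")
    means = np.lib.stride_tricks.sliding_window_view(trace.f, w).mean(axis=1)
    i0 = int(np.argmin(means))
    f0 = float(means[i0])
    if f0 <= 0:
        raise ValueError("baseline F0 <= 0: trace not background-valid")
    dff = (trace.f - f0) / f0
    mad = np.median(np.abs(dff - np.median(dff)))
    sigma = float(max(MAD_TO_SD * mad, SIGMA_FLOOR))
    window = (float(trace.frame_times[i0]), float(trace.frame_times[i0 + w - 1]))
    return DffTrace(trace.frame_times, dff, f0, window, sigma,
                    roi_id=trace.roi_id, cell_class=trace.cell_class)


def detect_events(dff: DffTrace,
                  k: float = EVENT_SIGMA_MULTIPLE) -> list[CalciumEvent]:
    """Maximal contiguous segments with dF/F0 > k * baseline sigma.

    Segments shorter than 2 frames are discarded as single-frame noise
    crossings. Duration is the segment width plus one frame interval.
    """
    above = dff.dff > k * dff.baseline_sigma
    padded = np.diff(np.concatenate(([0], above.view(np.int8), [0])))
    starts = np.flatnonzero(padded == 1)
    ends = np.flatnonzero(padded == -1)           # exclusive
    dt = dff.frame_interval
    events = []
    for s, e in zip(starts, ends):
        if e - s < MIN_EVENT_FRAMES:
            continue
        onset = float(dff.frame_times[s])
        offset = float(dff.frame_times[e - 1])
        events.append(CalciumEvent(onset=onset, offset=offset,
                                   peak_dff=float(dff.dff[s:e].max()),
                                   duration=offset - onset + dt))
    return events


def summarize_cell(dff: DffTrace, events: list[CalciumEvent] | None = None, *,
                   auc_window_seconds: float = AUC_WINDOW_SECONDS
                   ) -> CellCalciumSummary:
    """The four per-cell statistics: AUC, amplitude, duration, frequency.

    AUC is the trapezoidal integral of dF/F0 over each complete
    35-s window, averaged across windows; partial tail windows are
    dropped. A trace shorter than one window is integrated whole and
    flagged partial. Frequency is events per minute over the whole trace.
    """
    if events is None:
        events = detect_events(dff)
    dt = dff.frame_interval
    n = dff.dff.size
    length_s = n * dt
    w = int(round(auc_window_seconds / dt))
    flags = []
    if n < w:
        auc = float(np.trapezoid(dff.dff, dx=dt))
        flags.append("partial_auc_window")
    else:
        aucs = [np.trapezoid(dff.dff[i:i + w], dx=dt)
                for i in range(0, n - w + 1, w)]
        auc = float(np.mean(aucs))
    amplitude = float(np.mean([e.peak_dff for e in events])) if events else 0.0
    duration = float(np.mean([e.duration for e in events])) if events else 0.0
    frequency = len(events) / length_s * 60.0
    return CellCalciumSummary(roi_id=dff.roi_id, cell_class=dff.cell_class,
                              auc=auc, amplitude=amplitude, duration=duration,
                              frequency=frequency, n_events=len(events),
                              flags=flags)


# ---------------------------------------------------------------------
# tabular I/O
# ---------------------------------------------------------------------

def load_trace_table(path, *, frame_rate: float | None = None,
                     classes: dict[str, str] | None = None
                     ) -> list[FluorescenceTrace]:
    """Read a trace table CSV: ``frame,time_s,roi_1,roi_2,...``."""
    df = pd.read_csv(path, float_precision="round_trip")
    if "time_s" in df.columns:
        times = df["time_s"].to_numpy(float)
    else:
        if frame_rate is None:
            frame_rate = DEFAULT_FRAME_RATE_HZ
        times = df["frame"].to_numpy(float) / frame_rate
    traces = []
    for col in df.columns:
        if col in ("frame", "time_s"):
            continue
        cls = (classes or {}).get(col, "unknown")
        traces.append(FluorescenceTrace(times, df[col].to_numpy(float),
                                        roi_id=col, cell_class=cls))
    return traces


def write_summary_table(summaries, path) -> pd.DataFrame:
    df = pd.DataFrame([{"roi_id": s.roi_id, "cell_class": s.cell_class,
                        "auc": s.auc, "amplitude": s.amplitude,
                        "duration": s.duration, "frequency": s.frequency,
                        "n_events": s.n_events} for s in summaries])
    df.to_csv(path, sep="\t", index=False)
    return df


def write_event_table(roi_events: dict[str, list[CalciumEvent]],
                      path) -> pd.DataFrame:
    rows = [{"roi_id": roi, "onset_s": e.onset, "offset_s": e.offset,
             "peak_dff": e.peak_dff, "duration_s": e.duration}
            for roi, evs in roi_events.items() for e in evs]
    df = pd.DataFrame(rows)
    df.to_csv(path, sep="\t", index=False)
    return df
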