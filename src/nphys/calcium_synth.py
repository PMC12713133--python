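"""Synthetic ROI fluorescence with known calcium-event ground truth.

Generates GCaMP6s-like traces: a homogeneous Poisson train of transients
with a short linear rise and exponential decay (default decay 1.5 s),
rendered additively on a multiplicative baseline so the generator's
dF/F0 equals the injected kernel sum exactly, plus white Gaussian
recording noise. Optionally renders image stacks with disk ROIs so the
ROI-extraction path can be tested end to end.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .calcium_quant import DEFAULT_FRAME_RATE_HZ, FluorescenceTrace


@dataclass
class CaSimParams:
    frame_rate: float = DEFAULT_FRAME_RATE_HZ   # Hz
    length: float = 105.0                       # s
    event_rate: float = 1.0                     # events / min
    amplitude: float = 8.0       # event peak, in multiples of the dF/F noise
    #   s.d. (noise_sigma/baseline_f); taken directly as dF/F when noise is 0
    decay_tau: float = 1.5                      # s, GCaMP6s-like
    rise_frames: int = 1
    baseline_f: float = 100.0                   # a.u.
    noise_sigma: float = 2.0                    # a.u.
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.frame_rate, self.length, self.decay_tau,
               self.baseline_f) <= 0 or self.amplitude <= 0:
            raise ValueError("CaSimParams fields must be positive")

    @property
    def peak_dff(self) -> float:
        """Event peak on the dF/F scale implied by the amplitude setting."""
        if self.noise_sigma > 0:
            return self.amplitude * self.noise_sigma / self.baseline_f
        return self.amplitude


def event_kernel(params: CaSimParams, n_frames: int) -> np.ndarray:
    """Unit-peak transient: linear rise over rise_frames, then exp decay."""
    dt = 1.0 / params.frame_rate
    rise = np.linspace(0.0, 1.0, params.rise_frames + 1)[1:]
    decay_len = max(0, n_frames - params.rise_frames)
    decay = np.exp(-np.arange(1, decay_len + 1) * dt / params.decay_tau)
    return np.concatenate([rise, decay])[:n_frames]


def simulate_trace(params: CaSimParams, *,
                   rng: np.random.Generator | None = None,
                   roi_id: str = "", cell_class: str = "unknown"
                   ) -> tuple[FluorescenceTrace, list[dict]]:
    """One ROI trace plus its event log (true times and dF/F peaks)."""
    if rng is None:
        rng = np.random.default_rng(params.seed)
    n = int(round(params.length * params.frame_rate))
    times = np.arange(n) / params.frame_rate
    n_events = rng.poisson(params.event_rate * params.length / 60.0)
    event_times = np.sort(rng.uniform(0.0, params.length, n_events))
    kernel = event_kernel(params, n)
    signal = np.zeros(n)
    log = []
    for te in event_times:
        i0 = int(np.floor(te * params.frame_rate))
        if i0 >= n:
            continue
        m = n - i0
        signal[i0:] += params.peak_dff * kernel[:m]
        log.append({"time_s": float(te), "peak_dff": params.peak_dff})
    f = params.baseline_f * (1.0 + signal)
    if params.noise_sigma > 0:
        f = f + rng.normal(0.0, params.noise_sigma, n)
    return FluorescenceTrace(times, f, roi_id=roi_id,
                             cell_class=cell_class), log


def simulate_population(params: CaSimParams, n_cells: int, *,
                        seed: int | None = None, cell_class: str = "unknown",
                        roi_prefix: str = "roi"
                        ) -> tuple[list[FluorescenceTrace], list[list[dict]]]:
    """Independent traces for a population of cells (one substream each)."""
    root = np.random.default_rng(params.seed if seed is None else seed)
    traces, logs = [], []
    for i in range(n_cells):
        tr, log = simulate_trace(params, rng=np.random.default_rng(
            root.integers(0, 2**31)), roi_id=f"{roi_prefix}_{i}",
            cell_class=cell_class)
        traces.append(tr)
        logs.append(log)
    return traces, logs


def render_stack(traces: list[FluorescenceTrace],
                 centers: list[tuple[float, float]], radius: float, *,
                 shape: tuple[int, int] = (64, 64),
                 background: float = 20.0, pixel_noise: float = 1.0,
                 seed: int = 0
                 ) -> tuple[np.ndarray, list[np.ndarray], np.ndarray]:
    """Render traces into an image stack with disk ROIs.

    Each ROI's pixels emit its trace value plus the background constant
    plus per-pixel Gaussian noise; non-ROI pixels emit background plus
    noise. Returns (stack, roi_masks, background_mask). Overlapping ROIs
    are rejected.
    """
    yy, xx = np.mgrid[:shape[0], :shape[1]]
    masks = []
    for cy, cx in centers:
        m = (yy - cy) ** 2 + (xx - cx) ** 2 <= radius ** 2
        if not m.any():
            raise ValueError("ROI disk lies outside the frame")
        masks.append(m)
    union = np.zeros(shape, dtype=int)
    for m in masks:
        union += m
    if (union > 1).any():
        raise ValueError("overlapping ROIs")
    n_frames = traces[0].f.size
    rng = np.random.default_rng(seed)
    stack = np.full((n_frames, *shape), background, dtype=float)
    for tr, m in zip(traces, masks):
        stack[:, m] += tr.f[:, None]
    stack += rng.normal(0.0, pixel_noise, stack.shape)
    return stack, masks, union == 0


def write_stack(stack: np.ndarray, path: str | Path) -> None:
    import tifffile
    tifffile.imwrite(str(path), stack.astype(np.float32))


def write_trace_table(traces: list[FluorescenceTrace], path: str | Path,
                      float_format: str = "%.6f") -> None:
    """Write the CSV trace-table format read by calcium_quant.

    Use ``float_format="%.17g"`` for a lossless float64 round trip.
    """
    import pandas as pd
    data = {"frame": np.arange(traces[0].f.size),
            "time_s": traces[0].frame_times}
    for tr in traces:
        data[tr.roi_id] = tr.f
    pd.DataFrame(data).to_csv(path, index=False, float_format=float_format)
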