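"""Calcium transient detection and kinetics measurement.

Reference detector: per cell, baseline is the trace median and the noise
scale is 1.4826 x MAD (consistent with a Gaussian SD).  An event is a
maximal run of frames with dF/F above baseline + k x noise lasting at least
``min_duration_s``; runs separated by sub-threshold gaps are distinct
events.  Amplitude is the run maximum minus baseline; the half-width is the
full width at half maximum around the peak, with the two half-level
crossings located by linear interpolation between samples (searching the
whole trace outward from the peak, not just the supra-threshold run).
Events whose half-level crossings run off either session edge get a missing
half-width rather than an extrapolated one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocess import DffMatrix

__all__ = [
    "DetectionParams",
    "TransientEvent",
    "detect_events",
    "detect_events_trace",
    "summarize_kinetics",
    "events_to_frame",
]


@dataclass(frozen=True)
class DetectionParams:
    threshold_k: float = 3.0  # multiples of the robust noise SD
    min_duration_s: float = 1.0

    def __post_init__(self):
        if self.threshold_k <= 0:
            raise ValueError("threshold_k must be positive")
        if self.min_duration_s <= 0:
            raise ValueError("min_duration_s must be positive")


@dataclass(frozen=True)
class TransientEvent:
    cell_id: str
    population: str
    onset_s: float
    peak_s: float
    amplitude: float  # dF/F, peak minus baseline
    half_width_s: float | None  # None when truncated by a session edge


def _interp_crossing(t0, t1, y0, y1, level):
    """Time where the segment (t0,y0)-(t1,y1) crosses ``level``."""
    if y1 == y0:
        return t0
    return t0 + (level - y0) * (t1 - t0) / (y1 - y0)


def _half_width(trace, times, peak_idx, baseline, amplitude):
    """FWHM around ``peak_idx`` at level baseline + amplitude/2, or None at edges."""
    level = baseline + amplitude / 2.0
    # walk left
    i = peak_idx
    while i > 0 and trace[i - 1] > level:
        i -= 1
    if i == 0 and trace[0] > level:
        return None
    left = _interp_crossing(times[i - 1], times[i], trace[i - 1], trace[i], level)
    # walk right
    j = peak_idx
    n = len(trace)
    while j < n - 1 and trace[j + 1] > level:
        j += 1
    if j == n - 1 and trace[n - 1] > level:
        return None
    right = _interp_crossing(times[j], times[j + 1], trace[j], trace[j + 1], level)
    return float(right - left)


def detect_events_trace(
    trace: np.ndarray,
    fs: float,
    params: DetectionParams = DetectionParams(),
    cell_id: str = "cell",
    population: str = "",
) -> list[TransientEvent]:
    """Detect transients on a single dF/F trace."""
    trace = np.asarray(trace, dtype=float)
    if not np.all(np.isfinite(trace)):
        raise ValueError("dF/F trace contains non-finite values")
    baseline = float(np.median(trace))
    noise = 1.4826 * float(np.median(np.abs(trace - baseline)))
    if noise == 0 and np.all(trace == trace[0]):
        warnings.warn(f"constant trace for {cell_id}: no noise scale, no events")
        return []
    # noise-free non-constant traces (>=half the samples at baseline) degrade
    # to a strict above-baseline criterion
    threshold = baseline + params.threshold_k * noise
    above = trace > threshold
    if not above.any():
        return []
    min_frames = max(int(np.ceil(params.min_duration_s * fs)), 1)
    times = np.arange(len(trace)) / fs

    events: list[TransientEvent] = []
    edges = np.flatnonzero(np.diff(above.astype(int)))
    starts = list(edges[~above[edges]] + 1) if len(edges) else []
    ends = list(edges[above[edges]] + 1) if len(edges) else []
    if above[0]:
        starts = [0] + starts
    if above[-1]:
        ends = ends + [len(trace)]
    for s, e in zip(starts, ends):
        if e - s < min_frames:
            continue
        seg = trace[s:e]
        peak_rel = int(np.argmax(seg))
        peak_idx = s + peak_rel
        amplitude = float(seg[peak_rel] - baseline)
        hw = _half_width(trace, times, peak_idx, baseline, amplitude)
        # onset: last crossing of the threshold before the run (run start)
        onset = (
            _interp_crossing(times[s - 1], times[s], trace[s - 1], trace[s], threshold)
            if s > 0
            else times[0]
        )
        events.append(
            TransientEvent(
                cell_id=cell_id,
                population=population,
                onset_s=float(onset),
                peak_s=float(times[peak_idx]),
                amplitude=amplitude,
                half_width_s=hw,
            )
        )
    return events


def detect_events(
    dff: DffMatrix, params: DetectionParams = DetectionParams()
) -> list[TransientEvent]:
    """Detect transients on every cell of a dF/F matrix."""
    events: list[TransientEvent] = []
    for j, cell in enumerate(dff.cell_ids):
        events.extend(
            detect_events_trace(
                dff.values[:, j],
                dff.sampling_frequency,
                params,
                cell_id=cell,
                population=dff.population_of[cell],
            )
        )
    return events


def events_to_frame(events: list[TransientEvent]) -> pd.DataFrame:
    """Tidy table: one row per event."""
    return pd.DataFrame(
        [
            {
                "cell_id": e.cell_id,
                "population": e.population,
                "onset_s": e.onset_s,
                "peak_s": e.peak_s,
                "amplitude": e.amplitude,
                "half_width_s": np.nan if e.half_width_s is None else e.half_width_s,
            }
            for e in events
        ],
        columns=["cell_id", "population", "onset_s", "peak_s", "amplitude", "half_width_s"],
    )


def summarize_kinetics(
    events: list[TransientEvent],
    populations: dict[str, list[str]],
    session_minutes: float | None = None,
) -> pd.DataFrame:
    """Per-population mean amplitude, mean half-width and events per cell.

    ``populations`` maps population label -> list of cell ids in the session
    (so silent cells count in the per-cell rate).  Populations without events
    yield missing means, not zeros.  Half-width means skip truncated events.
    """
    rows = []
    for pop, cells in populations.items():
        pop_events = [e for e in events if e.population == pop]
        n_cells = len(cells)
        amps = [e.amplitude for e in pop_events]
        hws = [e.half_width_s for e in pop_events if e.half_width_s is not None]
        row = {
            "population": pop,
            "n_cells": n_cells,
            "n_events": len(pop_events),
            "mean_amplitude": float(np.mean(amps)) if amps else np.nan,
            "mean_half_width_s": float(np.mean(hws)) if hws else np.nan,
            "events_per_cell": len(pop_events) / n_cells if n_cells else np.nan,
        }
        if session_minutes:
            row["events_per_cell_per_10min"] = row["events_per_cell"] * 10.0 / session_minutes
        rows.append(row)
    return pd.DataFrame(rows)
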