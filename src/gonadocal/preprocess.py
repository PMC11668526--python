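"""dF/F normalization and conditional low-pass filtering.

The baseline F0 of each cell is the *lowest of the block means*: the trace
is cut into consecutive non-overlapping blocks of N = round(fs x 5 s)
frames, each block is averaged, and F0 is the minimum of those means.  Then
dF/F(t) = F(t)/F0 - 1.  A trailing partial block participates iff it holds
at least N/2 frames.  When the sampling rate exceeds 4 Hz the dF/F traces
are low-pass filtered at 2 Hz with a zero-phase 4th-order Butterworth
(forward-backward), so event timing used downstream is not biased.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.signal import butter, filtfilt

from .trace_io import TraceMatrix

__all__ = ["DffParams", "DffMatrix", "compute_dff", "lowpass_if_needed", "preprocess"]


@dataclass(frozen=True)
class DffParams:
    block_seconds: float = 5.0
    filter_threshold_hz: float = 4.0
    filter_cutoff_hz: float = 2.0
    filter_order: int = 4

    def __post_init__(self):
        if self.block_seconds <= 0:
            raise ValueError("block_seconds must be positive")
        if self.filter_threshold_hz <= 0 or self.filter_cutoff_hz <= 0:
            raise ValueError("filter frequencies must be positive")


@dataclass
class DffMatrix:
    """dF/F traces (frames x cells) with per-cell F0 and provenance."""

    values: np.ndarray
    sampling_frequency: float
    cell_ids: list[str]
    population_of: dict[str, str]
    f0_per_cell: np.ndarray
    filtered: bool
    params: DffParams
    session_role: str = "basal"

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.sampling_frequency

    def populations(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.cell_ids:
            seen.setdefault(self.population_of[c], None)
        return list(seen)

    def cells_of(self, population: str) -> list[str]:
        return [c for c in self.cell_ids if self.population_of[c] == population]

    def column(self, cell_id: str) -> np.ndarray:
        return self.values[:, self.cell_ids.index(cell_id)]


def block_means(trace: np.ndarray, n_block: int) -> np.ndarray:
    """Means of consecutive non-overlapping blocks; trailing block iff >= N/2 frames."""
    n = len(trace)
    n_full = n // n_block
    means = trace[: n_full * n_block].reshape(n_full, n_block).mean(axis=1)
    tail = n - n_full * n_block
    if tail >= n_block / 2:
        means = np.append(means, trace[n_full * n_block :].mean())
    return means


def compute_dff(traces: TraceMatrix, params: DffParams = DffParams()) -> DffMatrix:
    """Block-minimum F0 normalization: dF/F = F/F0 - 1 per cell."""
    n_block = int(round(traces.sampling_frequency * params.block_seconds))
    if traces.n_frames < n_block:
        raise ValueError(
            f"trace of {traces.n_frames} frames shorter than one {n_block}-frame block"
        )
    f0 = np.empty(traces.n_cells)
    for j in range(traces.n_cells):
        f0[j] = block_means(traces.values[:, j], n_block).min()
        if f0[j] <= 0:
            raise ValueError(
                f"non-positive F0 for cell {traces.cell_ids[j]}: raw trace is not "
                "strictly positive fluorescence"
            )
    values = traces.values / f0[None, :] - 1.0
    return DffMatrix(
        values=values,
        sampling_frequency=traces.sampling_frequency,
        cell_ids=list(traces.cell_ids),
        population_of=dict(traces.population_of),
        f0_per_cell=f0,
        filtered=False,
        params=params,
        session_role=traces.session_role,
    )


def lowpass_if_needed(dff: DffMatrix, params: DffParams | None = None) -> DffMatrix:
    """Zero-phase low-pass the dF/F traces iff fs exceeds the threshold.

    At or below ``filter_threshold_hz`` (default 4 Hz) the input is returned
    unchanged (same object).  Above it, a Butterworth of order
    ``filter_order`` with normalized cutoff ``filter_cutoff_hz/(fs/2)`` is
    applied forward-backward; DC gain is 1 to well under 1e-3.
    """
    params = params or dff.params
    fs = dff.sampling_frequency
    if fs <= params.filter_threshold_hz:
        return dff
    nyquist = fs / 2.0
    if params.filter_cutoff_hz >= nyquist:
        raise ValueError(
            f"cutoff {params.filter_cutoff_hz} Hz not below Nyquist {nyquist} Hz"
        )
    b, a = butter(params.filter_order, params.filter_cutoff_hz / nyquist, btype="low")
    filtered = filtfilt(b, a, dff.values, axis=0)
    return replace(dff, values=filtered, filtered=True, params=params)


def preprocess(traces: TraceMatrix, params: DffParams = DffParams()) -> DffMatrix:
    """compute_dff followed by the conditional low-pass — the pipeline order."""
    return lowpass_if_needed(compute_dff(traces, params))
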