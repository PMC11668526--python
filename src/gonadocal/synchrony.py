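"""Lag-maximized cross-correlation synchrony.

For every cell pair the traces are mean-subtracted, cross-correlated over
lags -L..L (L = round(maxlag_s x fs)) and normalized by the geometric mean
of the two zero-lag autocorrelations, so a trace against itself scores
exactly 1 at lag 0.  The reported coefficient is the maximum over lags (by
Cauchy-Schwarz it lies in [-1, 1]); its arg-max lag is kept alongside.
Zero-variance traces have no defined coefficient: their rows/columns are
missing and they are excluded from population means, with a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import fftconvolve

from .preprocess import DffMatrix

__all__ = [
    "CorrelationParams",
    "CorrelationResult",
    "max_crosscorr",
    "reference_vector",
    "correlations_to_frame",
]


@dataclass(frozen=True)
class CorrelationParams:
    maxlag_s: float = 30.0

    def __post_init__(self):
        if self.maxlag_s < 0:
            raise ValueError("maxlag_s must be nonnegative")


@dataclass
class CorrelationResult:
    """All-pairs max cross-correlation coefficients and their lags."""

    max_coeff: np.ndarray  # (n, n) symmetric, diag 1; NaN for undefined cells
    argmax_lag_s: np.ndarray  # (n, n) antisymmetric
    cell_ids: list[str]
    population_of: dict[str, str]
    params: CorrelationParams
    reference_cell: str | None = None

    def coefficient(self, cell_i: str, cell_j: str) -> float:
        i = self.cell_ids.index(cell_i)
        j = self.cell_ids.index(cell_j)
        return float(self.max_coeff[i, j])

    def population_mean(self, population: str) -> float:
        """Mean max coefficient over unordered off-diagonal pairs within a population."""
        idx = [i for i, c in enumerate(self.cell_ids) if self.population_of[c] == population]
        if len(idx) < 2:
            return float("nan")
        sub = self.max_coeff[np.ix_(idx, idx)]
        iu = np.triu_indices(len(idx), k=1)
        vals = sub[iu]
        vals = vals[~np.isnan(vals)]
        return float(vals.mean()) if len(vals) else float("nan")

    def per_population_mean(self) -> dict[str, float]:
        pops: dict[str, None] = {}
        for c in self.cell_ids:
            pops.setdefault(self.population_of[c], None)
        return {p: self.population_mean(p) for p in pops}

    def per_cell_mean(self, population: str | None = None) -> dict[str, float]:
        """Per-cell mean of off-diagonal max coefficients (within a population if given)."""
        if population is None:
            idx = list(range(len(self.cell_ids)))
        else:
            idx = [i for i, c in enumerate(self.cell_ids) if self.population_of[c] == population]
        out: dict[str, float] = {}
        for i in idx:
            others = [j for j in idx if j != i]
            vals = self.max_coeff[i, others]
            vals = vals[~np.isnan(vals)]
            out[self.cell_ids[i]] = float(vals.mean()) if len(vals) else float("nan")
        return out


def _lag_window(n_frames: int, fs: float, params: CorrelationParams) -> int:
    lag = int(round(params.maxlag_s * fs))
    return min(lag, n_frames - 1)


def max_crosscorr(dff: DffMatrix, params: CorrelationParams = CorrelationParams()) -> CorrelationResult:
    """All-pairs maximum normalized cross-correlation over +/- maxlag."""
    n = dff.n_cells
    if n < 2:
        raise ValueError("need at least 2 cells")
    fs = dff.sampling_frequency
    lag = _lag_window(dff.n_frames, fs, params)
    x = dff.values - dff.values.mean(axis=0, keepdims=True)
    energy = (x**2).sum(axis=0)
    dead = energy == 0
    if dead.any():
        warnings.warn(
            f"zero-variance trace(s) excluded: {[dff.cell_ids[i] for i in np.flatnonzero(dead)]}"
        )
    lags = np.arange(-lag, lag + 1) / fs
    max_coeff = np.full((n, n), np.nan)
    argmax_lag = np.full((n, n), np.nan)
    np.fill_diagonal(max_coeff, 1.0)
    np.fill_diagonal(argmax_lag, 0.0)
    max_coeff[dead, :] = np.nan
    max_coeff[:, dead] = np.nan
    argmax_lag[dead, :] = np.nan
    argmax_lag[:, dead] = np.nan
    for i in range(n):
        if dead[i]:
            continue
        for j in range(i + 1, n):
            if dead[j]:
                continue
            # full cross-correlation of x_i with x_j; index n-1+k holds lag k,
            # where positive k means x_j lags behind x_i by k frames
            cc = fftconvolve(x[:, j], x[:, i][::-1], mode="full")
            center = dff.n_frames - 1
            window = cc[center - lag : center + lag + 1]
            window = window / np.sqrt(energy[i] * energy[j])
            # among ties prefer the smallest |lag|
            best = np.flatnonzero(window == window.max())
            k = best[np.argmin(np.abs(lags[best]))]
            max_coeff[i, j] = max_coeff[j, i] = float(window[k])
            argmax_lag[i, j] = float(lags[k])
            argmax_lag[j, i] = -float(lags[k])
    return CorrelationResult(
        max_coeff=max_coeff,
        argmax_lag_s=argmax_lag,
        cell_ids=list(dff.cell_ids),
        population_of=dict(dff.population_of),
        params=params,
    )


def reference_vector(
    dff: DffMatrix,
    reference: str = "auto",
    params: CorrelationParams = CorrelationParams(),
    population: str | None = None,
) -> tuple[str, dict[str, float]]:
    """Max coefficient of every cell versus one reference cell.

    ``reference='auto'`` picks the highest-variance cell (within
    ``population`` when given — "the population of interest").  The vector
    covers the cells of that population (all cells when none given); the
    reference's own entry is 1.  Returns ``(reference_cell, {cell: coeff})``.
    """
    cells = dff.cells_of(population) if population is not None else list(dff.cell_ids)
    if not cells:
        raise ValueError(f"no cells in population {population!r}")
    if reference == "auto":
        variances = {c: dff.column(c).var() for c in cells}
        reference = max(variances, key=variances.get)
    elif reference not in dff.cell_ids:
        raise ValueError(f"reference cell {reference!r} not present")
    ref_trace = dff.column(reference)
    xr = ref_trace - ref_trace.mean()
    er = float((xr**2).sum())
    if er == 0:
        raise ValueError(f"reference cell {reference!r} has a constant trace")
    fs = dff.sampling_frequency
    lag = _lag_window(dff.n_frames, fs, params)
    center = dff.n_frames - 1
    out: dict[str, float] = {}
    for c in cells:
        if c == reference:
            out[c] = 1.0
            continue
        xc = dff.column(c)
        xc = xc - xc.mean()
        ec = float((xc**2).sum())
        if ec == 0:
            out[c] = float("nan")
            continue
        cc = fftconvolve(xc, xr[::-1], mode="full")
        window = cc[center - lag : center + lag + 1] / np.sqrt(er * ec)
        out[c] = float(window.max())
    return reference, out


def correlations_to_frame(result: CorrelationResult) -> pd.DataFrame:
    """Long-format table: one row per unordered cell pair."""
    rows = []
    n = len(result.cell_ids)
    for i in range(n):
        for j in range(i + 1, n):
            ci, cj = result.cell_ids[i], result.cell_ids[j]
            pop_i, pop_j = result.population_of[ci], result.population_of[cj]
            rows.append(
                {
                    "cell_i": ci,
                    "cell_j": cj,
                    "population": pop_i if pop_i == pop_j else f"{pop_i}|{pop_j}",
                    "max_coeff": result.max_coeff[i, j],
                    "lag_s": result.argmax_lag_s[i, j],
                }
            )
    return pd.DataFrame(rows, columns=["cell_i", "cell_j", "population", "max_coeff", "lag_s"])
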