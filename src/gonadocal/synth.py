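"""Ground-truthed synthetic gonadotroph recordings.

Two labelled cell populations (LH-like and FSH-like) are simulated as raw
fluorescence traces.  Each cell's trace is

    F(t) = B * (1 + sum_events w(t)) * exp(-bleach * t) + B * noise(t)

where ``B`` is a per-cell log-normal baseline, ``w`` the product-of-
exponentials transient profile (see :mod:`gonadocal.waveform`), and the
noise term combines white photon noise with an optional slow baseline
drift.  Event placement covers three regimes the real recordings show:

* independent Poisson bursts per cell (sparse, disorganized basal FSH
  activity), with a refractory gap so bursts do not pile up;
* shared population events (gap-junction-coupled LH cells), with per-cell
  participation, onset jitter and amplitude scatter;
* stimulus-evoked events given to a random responder subset of each
  population, with a per-cell latency jitter.

Every placed event and every responder flag is logged to a
:class:`GroundTruth`, the oracle for recovery tests.  All randomness flows
from one ``numpy.random.Generator`` seeded at the top; identical specs and
seed reproduce bit-identical output.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .trace_io import RoiTable, TraceMatrix
from .waveform import event_profile, mass_quantile_time, solve_decay_tau, unit_waveform

__all__ = [
    "RecordingSpec",
    "KineticsPreset",
    "PopulationSpec",
    "CouplingSpec",
    "StimulusSpec",
    "NoiseSpec",
    "GroundTruthEvent",
    "GroundTruth",
    "simulate_population",
    "render_movie",
]

#: raw traces are floored at this fraction of the cell baseline (positivity)
_POSITIVITY_FLOOR = 0.01


@dataclass(frozen=True)
class RecordingSpec:
    """Session geometry: sampling frequency (Hz) and duration (s)."""

    sampling_frequency: float = 10.0
    duration_s: float = 600.0

    def __post_init__(self):
        if self.sampling_frequency <= 0:
            raise ValueError("sampling_frequency must be positive")
        if self.n_frames < 2:
            raise ValueError("recording must span at least 2 frames")

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_s * self.sampling_frequency))

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.sampling_frequency


@dataclass(frozen=True)
class KineticsPreset:
    """Transient statistics for one event class of one population.

    ``event_rate`` is events per cell per session; amplitudes (dF/F) and
    half-widths (s) are log-normal with the stated mean and coefficient of
    variation; ``rise_fraction`` sets the rise time constant as a fraction
    of the drawn half-width.
    """

    event_rate: float = 0.0
    amplitude_mean: float = 0.6
    amplitude_cv: float = 0.0
    halfwidth_mean_s: float = 10.0
    halfwidth_cv: float = 0.0
    rise_fraction: float = 0.1

    def __post_init__(self):
        if self.event_rate < 0 or self.amplitude_cv < 0 or self.halfwidth_cv < 0:
            raise ValueError("rates and cv values must be nonnegative")
        if self.amplitude_mean <= 0 or self.halfwidth_mean_s <= 0:
            raise ValueError("amplitude_mean and halfwidth_mean_s must be positive")
        if not 0 < self.rise_fraction < 1:
            raise ValueError("rise_fraction must lie in (0, 1)")


@dataclass(frozen=True)
class PopulationSpec:
    """Cell count plus transient kinetics for one labelled population.

    ``background`` is an optional second, low-amplitude event class modelling
    the sub-detection-scale calcium fluctuations that keep real pairwise
    coefficients below 1; it contributes independent per-cell variance and is
    logged separately in the ground truth (``kind='background'``).
    ``shared_kinetics`` overrides the amplitude/half-width statistics used
    for population-wide shared events when those differ from the spontaneous
    bursts (e.g. a long follow-event on top of short basal bursts); when
    None, shared events draw from ``kinetics``.
    """

    n_cells: int
    kinetics: KineticsPreset
    background: KineticsPreset | None = None
    shared_kinetics: KineticsPreset | None = None

    def __post_init__(self):
        if self.n_cells <= 0:
            raise ValueError("n_cells must be positive")


@dataclass(frozen=True)
class CouplingSpec:
    """Shared population events: times, participation, jitter and scatter.

    ``amplitude_scatter_cv`` and ``halfwidth_scatter_cv`` give each
    participating cell its own amplitude / duration for the common event
    (cell-specific calcium handling); with participation 1 and all jitter
    and scatter 0, every participating cell receives an identical event.
    """

    shared_event_times_s: tuple[float, ...] = ()
    participation: float = 1.0
    jitter_sd_s: float = 0.0
    amplitude_scatter_cv: float = 0.0
    halfwidth_scatter_cv: float = 0.0

    def __post_init__(self):
        if not 0 <= self.participation <= 1:
            raise ValueError("participation must lie in [0, 1]")
        if self.jitter_sd_s < 0 or self.amplitude_scatter_cv < 0 or self.halfwidth_scatter_cv < 0:
            raise ValueError("jitter and scatter must be nonnegative")


@dataclass(frozen=True)
class StimulusSpec:
    """One stimulus pulse: onset, per-population responder fractions and kinetics."""

    label: str
    onset_s: float
    responder_fraction_by_population: dict[str, float]
    response_kinetics_by_population: dict[str, KineticsPreset]
    evoked_jitter_sd_s: float = 0.0

    def __post_init__(self):
        for pop, f in self.responder_fraction_by_population.items():
            if not 0 <= f <= 1:
                raise ValueError(f"responder fraction for {pop} outside [0, 1]")
        if self.evoked_jitter_sd_s < 0:
            raise ValueError("evoked_jitter_sd_s must be nonnegative")


@dataclass(frozen=True)
class NoiseSpec:
    """Baseline heterogeneity, photon noise, bleaching and slow drift.

    ``additive_noise_sd`` and ``drift_sd`` are fractions of the per-cell
    baseline; drift is a Gaussian process with correlation time
    ``drift_timescale_s`` entering the multiplicative baseline.
    """

    baseline_mean: float = 100.0
    baseline_cell_cv: float = 0.2
    additive_noise_sd: float = 0.04
    bleach_rate_per_s: float = 0.0
    drift_sd: float = 0.0
    drift_timescale_s: float = 60.0

    def __post_init__(self):
        for name in (
            "baseline_mean",
            "baseline_cell_cv",
            "additive_noise_sd",
            "bleach_rate_per_s",
            "drift_sd",
            "drift_timescale_s",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.baseline_mean <= 0:
            raise ValueError("baseline_mean must be positive")


@dataclass(frozen=True)
class GroundTruthEvent:
    cell_id: str
    population: str
    onset_s: float
    peak_s: float
    amplitude: float
    half_width_s: float
    kind: str  # 'spontaneous' | 'background' | 'shared' | 'evoked'
    shared_event_id: int | None = None


@dataclass
class GroundTruth:
    """Generator event log and responder flags — the oracle for recovery tests."""

    events: list[GroundTruthEvent]
    responder_flags: dict[str, bool]  # cell_id -> responded to the stimulus
    seed: int

    def events_of(self, cell_id: str | None = None, kind: str | None = None):
        out = self.events
        if cell_id is not None:
            out = [e for e in out if e.cell_id == cell_id]
        if kind is not None:
            out = [e for e in out if e.kind == kind]
        return out


def _lognormal(rng, mean, cv, size=None):
    """Log-normal draws with the stated arithmetic mean and cv."""
    if cv == 0:
        return np.full(size, float(mean)) if size is not None else float(mean)
    sigma2 = np.log1p(cv**2)
    mu = np.log(mean) - sigma2 / 2
    return rng.lognormal(mu, np.sqrt(sigma2), size=size)


def _poisson_onsets(rng, rate, duration_s, kinetics: KineticsPreset) -> list[tuple[float, float, float]]:
    """Poisson event placement with a refractory gap of one half-width.

    Returns (onset, amplitude, half_width) triples.  Consecutive onsets are
    forced at least ``span + gap`` apart, span being the previous event's
    drawn half-width and gap one half-width more; violating draws are
    dropped (slightly thinning the realized rate).
    """
    n = rng.poisson(rate)
    if n == 0:
        return []
    onsets = np.sort(rng.uniform(0.0, duration_s, size=n))
    amps = _lognormal(rng, kinetics.amplitude_mean, kinetics.amplitude_cv, n)
    hws = _lognormal(rng, kinetics.halfwidth_mean_s, kinetics.halfwidth_cv, n)
    kept: list[tuple[float, float, float]] = []
    last_end = -np.inf
    for onset, amp, hw in zip(onsets, amps, hws):
        if onset >= last_end:
            kept.append((float(onset), float(amp), float(hw)))
            last_end = onset + 2.0 * hw  # event span + one half-width refractory gap
    return kept


def _drift(rng, n_frames, fs, sd, timescale_s):
    """Unit-free slow drift: white noise smoothed by a Gaussian kernel, sd-scaled."""
    if sd == 0:
        return np.zeros(n_frames)
    white = rng.standard_normal(n_frames)
    sigma_frames = max(timescale_s * fs, 1.0)
    half = int(np.ceil(4 * sigma_frames))
    kernel = np.exp(-0.5 * (np.arange(-half, half + 1) / sigma_frames) ** 2)
    kernel /= kernel.sum()
    padded = np.pad(white, half, mode="reflect")
    smooth = np.convolve(padded, kernel, mode="valid")
    s = smooth.std()
    if s == 0:
        return np.zeros(n_frames)
    return sd * smooth / s


def simulate_population(
    recording: RecordingSpec,
    populations: dict[str, PopulationSpec],
    coupling: dict[str, CouplingSpec] | None = None,
    stimulus: StimulusSpec | None = None,
    noise: NoiseSpec = NoiseSpec(),
    seed: int = 0,
    session_role: str | None = None,
) -> tuple[TraceMatrix, GroundTruth]:
    """Simulate raw fluorescence traces for labelled populations, with ground truth.

    Cell ids are ``c000, c001, ...`` across populations in the order given.
    ``session_role`` defaults to ``stimulation`` when a stimulus is present,
    else ``basal``.
    """
    coupling = coupling or {}
    if len(set(populations)) != len(populations):
        raise ValueError("population labels must be unique")
    times = recording.times_s
    fs = recording.sampling_frequency
    rng = np.random.default_rng(seed)

    if stimulus is not None:
        if not 0 <= stimulus.onset_s < recording.duration_s:
            raise ValueError("stimulus onset outside the session")
        for pop, kin in stimulus.response_kinetics_by_population.items():
            tau_r, tau_d = solve_decay_tau(kin.halfwidth_mean_s, kin.rise_fraction)
            if stimulus.onset_s + mass_quantile_time(tau_r, tau_d, 0.99) > recording.duration_s:
                raise ValueError(
                    f"evoked {pop} event (half-width {kin.halfwidth_mean_s} s) does not "
                    f"fit the session: >1% of its mass extends past the last frame"
                )

    cell_ids: list[str] = []
    population_of: dict[str, str] = {}
    events: list[GroundTruthEvent] = []
    responder_flags: dict[str, bool] = {}
    dff_signal: dict[str, np.ndarray] = {}

    idx = 0
    for pop_label, pop in populations.items():
        pop_cells = [f"c{idx + j:03d}" for j in range(pop.n_cells)]
        idx += pop.n_cells
        cell_ids.extend(pop_cells)
        for c in pop_cells:
            population_of[c] = pop_label
            dff_signal[c] = np.zeros(recording.n_frames)

        # shared population events: one kinetics draw per event, shared by joiners
        cpl = coupling.get(pop_label)
        if cpl is not None:
            kin_sh = pop.shared_kinetics or pop.kinetics
            for ev_id, t0 in enumerate(cpl.shared_event_times_s):
                base_amp = _lognormal(rng, kin_sh.amplitude_mean, kin_sh.amplitude_cv)
                base_hw = _lognormal(rng, kin_sh.halfwidth_mean_s, kin_sh.halfwidth_cv)
                joins = rng.random(pop.n_cells) < cpl.participation
                jitters = rng.normal(0.0, cpl.jitter_sd_s, pop.n_cells) if cpl.jitter_sd_s else np.zeros(pop.n_cells)
                amp_sc = _lognormal(rng, 1.0, cpl.amplitude_scatter_cv, pop.n_cells)
                hw_sc = _lognormal(rng, 1.0, cpl.halfwidth_scatter_cv, pop.n_cells)
                for c, join, jit, a_sc, h_sc in zip(pop_cells, joins, jitters, amp_sc, hw_sc):
                    if not join:
                        continue
                    onset = float(t0 + jit)
                    amp = float(base_amp * a_sc)
                    hw = float(base_hw * h_sc)
                    tau_r, tau_d = solve_decay_tau(hw, kin_sh.rise_fraction)
                    dff_signal[c] += amp * unit_waveform(times - onset, tau_r, tau_d)
                    events.append(
                        GroundTruthEvent(
                            c, pop_label, onset, onset + float(tau_r * np.log1p(tau_d / tau_r)),
                            amp, hw, "shared", ev_id,
                        )
                    )

        # independent Poisson bursts (main + optional background class)
        for kin, kind in ((pop.kinetics, "spontaneous"), (pop.background, "background")):
            if kin is None or kin.event_rate == 0:
                continue
            for c in pop_cells:
                for onset, amp, hw in _poisson_onsets(rng, kin.event_rate, recording.duration_s, kin):
                    dff_signal[c] += event_profile(times, onset, amp, hw, kin.rise_fraction)
                    tau_r, tau_d = solve_decay_tau(hw, kin.rise_fraction)
                    events.append(
                        GroundTruthEvent(
                            c, pop_label, onset, onset + float(tau_r * np.log1p(tau_d / tau_r)),
                            amp, hw, kind, None,
                        )
                    )

        # stimulus-evoked events for a responder subset
        if stimulus is not None:
            f = stimulus.responder_fraction_by_population.get(pop_label, 0.0)
            kin = stimulus.response_kinetics_by_population.get(pop_label)
            responds = rng.random(pop.n_cells) < f
            for c, resp in zip(pop_cells, responds):
                responder_flags[c] = bool(resp and kin is not None)
                if not responder_flags[c]:
                    continue
                latency = abs(rng.normal(0.0, stimulus.evoked_jitter_sd_s)) if stimulus.evoked_jitter_sd_s else 0.0
                onset = float(stimulus.onset_s + latency)
                amp = float(_lognormal(rng, kin.amplitude_mean, kin.amplitude_cv))
                hw = float(_lognormal(rng, kin.halfwidth_mean_s, kin.halfwidth_cv))
                dff_signal[c] += event_profile(times, onset, amp, hw, kin.rise_fraction)
                tau_r, tau_d = solve_decay_tau(hw, kin.rise_fraction)
                events.append(
                    GroundTruthEvent(
                        c, pop_label, onset, onset + float(tau_r * np.log1p(tau_d / tau_r)),
                        amp, hw, "evoked", None,
                    )
                )

    # assemble raw fluorescence
    baselines = _lognormal(rng, noise.baseline_mean, noise.baseline_cell_cv, len(cell_ids))
    bleach = np.exp(-noise.bleach_rate_per_s * times)
    values = np.empty((recording.n_frames, len(cell_ids)))
    for j, c in enumerate(cell_ids):
        drift = _drift(rng, recording.n_frames, fs, noise.drift_sd, noise.drift_timescale_s)
        photon = (
            rng.standard_normal(recording.n_frames) * noise.additive_noise_sd
            if noise.additive_noise_sd
            else 0.0
        )
        raw = baselines[j] * (1.0 + dff_signal[c] + drift) * bleach + baselines[j] * photon
        values[:, j] = np.maximum(raw, _POSITIVITY_FLOOR * baselines[j])

    role = session_role or ("stimulation" if stimulus is not None else "basal")
    traces = TraceMatrix(
        values=values,
        sampling_frequency=fs,
        cell_ids=cell_ids,
        population_of=population_of,
        session_role=role,
    )
    return traces, GroundTruth(events=events, responder_flags=responder_flags, seed=seed)


def render_movie(
    traces: TraceMatrix,
    centroids,
    cell_radius_px: float,
    image_size: tuple[int, int],
) -> np.ndarray:
    """Render traces as an image stack of Gaussian-profile disks.

    Each cell is a disk of radius ``cell_radius_px`` around its centroid with
    a 2-D Gaussian intensity profile scaled so the mean over the disk mask
    equals the cell's trace value at that frame — extraction round-trips.
    """
    if cell_radius_px <= 0:
        raise ValueError("cell_radius_px must be positive")
    h, w = image_size
    centroids = np.asarray(centroids, dtype=float)
    if centroids.shape != (traces.n_cells, 2):
        raise ValueError("need one (x, y) centroid per cell")
    for (cx, cy), cell in zip(centroids, traces.cell_ids):
        if not (0 <= cx < w and 0 <= cy < h):
            raise ValueError(f"centroid of {cell} outside image")
    d2 = ((centroids[None, :, 0] - centroids[:, 0, None]) ** 2
          + (centroids[None, :, 1] - centroids[:, 1, None]) ** 2)
    np.fill_diagonal(d2, np.inf)
    if (d2 < (2 * cell_radius_px) ** 2).any():
        warnings.warn("overlapping ROI disks; extraction means will mix cells")

    yy, xx = np.mgrid[0:h, 0:w]
    stack = np.zeros((traces.n_frames, h, w))
    sigma = cell_radius_px / 2.0
    for j, (cx, cy) in enumerate(centroids):
        r2 = (xx - cx) ** 2 + (yy - cy) ** 2
        mask = r2 < cell_radius_px**2
        profile = np.where(mask, np.exp(-r2 / (2 * sigma**2)), 0.0)
        profile /= profile[mask].mean()  # unit mask-mean
        stack += traces.values[:, j][:, None, None] * profile[None, :, :]
    return stack


def roi_table_for(traces: TraceMatrix, centroids) -> RoiTable:
    """Convenience: build the RoiTable matching a rendered movie."""
    return RoiTable(
        cell_ids=list(traces.cell_ids),
        centroids=np.asarray(centroids, dtype=float),
        population_of=dict(traces.population_of),
    )
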