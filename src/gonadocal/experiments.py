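"""Canned synthetic experiments mirroring the published recordings.

Each function simulates recordings from a shipped preset, runs the full
pipeline (dF/F -> conditional low-pass -> detection / synchrony ->
classification) and returns the recovered summary numbers.  These are the
entry points used by the acceptance script and the ``analysis/`` drivers.

Seeds: every experiment derives per-replicate seeds as
``master_seed * 1009 + replicate`` (kept well under 2**31 for small master
seeds), so distinct replicates and distinct experiments decouple.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .presets import ExperimentPreset, get_preset
from .preprocess import DffParams, preprocess
from .response import ResponseParams, classify_responsive, session_coefficients
from .synchrony import CorrelationParams, max_crosscorr
from .synth import GroundTruth, simulate_population
from .transients import DetectionParams, TransientEvent, detect_events

__all__ = [
    "simulate_preset",
    "match_events",
    "basal_fsh_experiment",
    "lh_sync_experiment",
    "stimulation_experiment",
    "acceptance_metrics",
]


def _seeds(master_seed: int, n: int) -> list[int]:
    return [master_seed * 1009 + i for i in range(n)]


def simulate_preset(preset: ExperimentPreset | str, seed: int, n_cells: int | None = None):
    """Simulate one recording from a preset; optionally override every population's n_cells."""
    if isinstance(preset, str):
        preset = get_preset(preset)
    populations = preset.populations
    if n_cells is not None:
        from dataclasses import replace

        populations = {k: replace(p, n_cells=n_cells) for k, p in populations.items()}
    return simulate_population(
        preset.recording,
        populations,
        preset.coupling,
        preset.stimulus,
        preset.noise,
        seed=seed,
    )


def match_events(
    detected: list[TransientEvent],
    truth: GroundTruth,
    kind: str,
    tolerance_s: float | None = None,
) -> pd.DataFrame:
    """Pair ground-truth events of one kind with the nearest detected event.

    Matching is per cell on peak time; a pair counts when the detected peak
    lies within ``tolerance_s`` (default: the true half-width) of the true
    peak.  Each detected event is used at most once.  Returns one row per
    ground-truth event with the matched measurement (NaN when missed).
    """
    by_cell: dict[str, list[TransientEvent]] = {}
    for e in detected:
        by_cell.setdefault(e.cell_id, []).append(e)
    rows = []
    used: set[int] = set()
    for gt in truth.events_of(kind=kind):
        candidates = [
            (abs(e.peak_s - gt.peak_s), i, e)
            for i, e in enumerate(by_cell.get(gt.cell_id, []))
            if id(e) not in used
        ]
        tol = tolerance_s if tolerance_s is not None else gt.half_width_s
        match = min(candidates, default=None)
        row = {
            "cell_id": gt.cell_id,
            "population": gt.population,
            "true_peak_s": gt.peak_s,
            "true_amplitude": gt.amplitude,
            "true_half_width_s": gt.half_width_s,
            "amplitude": np.nan,
            "half_width_s": np.nan,
            "detected": False,
        }
        if match is not None and match[0] <= tol:
            e = match[2]
            used.add(id(e))
            row.update(
                amplitude=e.amplitude,
                half_width_s=np.nan if e.half_width_s is None else e.half_width_s,
                detected=True,
            )
        rows.append(row)
    return pd.DataFrame(rows)


def basal_fsh_experiment(
    master_seed: int,
    n_seeds: int = 5,
    n_cells: int = 20,
    detection: DetectionParams = DetectionParams(),
) -> dict:
    """Basal in vivo FSH recordings: detected burst kinetics, all events pooled."""
    amps, hws, counts = [], [], []
    for seed in _seeds(master_seed, n_seeds):
        traces, _ = simulate_preset("basal-fsh", seed, n_cells=n_cells)
        dff = preprocess(traces)
        events = detect_events(dff, detection)
        amps += [e.amplitude for e in events]
        hws += [e.half_width_s for e in events if e.half_width_s is not None]
        counts.append(len(events) / n_cells)
    return {
        "mean_half_width_s": float(np.mean(hws)),
        "mean_amplitude": float(np.mean(amps)),
        "events_per_cell": float(np.mean(counts)),
        "n_events": len(amps),
        "n_seeds": n_seeds,
        "n_cells": n_cells,
    }


def lh_sync_experiment(
    master_seed: int,
    n_seeds: int = 5,
    n_cells: int = 20,
    detection: DetectionParams = DetectionParams(),
    corr_params: CorrelationParams = CorrelationParams(),
) -> dict:
    """The in vivo synchronized LH event plus the trailing FSH follow-event.

    Recovers the population event's kinetics from detection (matched per
    cell against the ground-truth shared event) and the per-population mean
    max cross-correlation, averaged over replicate fish.
    """
    amps, hws = [], []
    lh_coeffs, fsh_coeffs = [], []
    for seed in _seeds(master_seed, n_seeds):
        traces, truth = simulate_preset("lh-sync-event", seed, n_cells=n_cells)
        dff = preprocess(traces)
        events = detect_events(dff, detection)
        matched = match_events(
            [e for e in events if e.population == "LH"], truth, kind="shared"
        )
        matched = matched[matched.population == "LH"]
        amps += list(matched.amplitude.dropna())
        hws += list(matched.half_width_s.dropna())
        corr = max_crosscorr(dff, corr_params)
        lh_coeffs.append(corr.population_mean("LH"))
        fsh_coeffs.append(corr.population_mean("FSH"))
    return {
        "mean_half_width_s": float(np.mean(hws)),
        "mean_amplitude": float(np.mean(amps)),
        "lh_mean_max_crosscorr": float(np.mean(lh_coeffs)),
        "fsh_mean_max_crosscorr": float(np.mean(fsh_coeffs)),
        "n_events": len(amps),
        "n_seeds": n_seeds,
        "n_cells": n_cells,
    }


def stimulation_experiment(
    stimulus_preset: str,
    master_seed: int,
    n_seeds: int = 5,
    n_cells: int = 20,
    detection: DetectionParams = DetectionParams(),
    corr_params: CorrelationParams = CorrelationParams(),
    response_params: ResponseParams = ResponseParams(),
) -> dict:
    """Basal + stimulation session pair per replicate fish, full pipeline.

    Per fish: simulate the shared basal ex vivo preset and the stimulation
    preset for the same cell layout, classify responsive cells with the
    percentile rule, measure evoked kinetics of true responders (ground-
    truth matched), and the stimulation-session all-pairs per-population
    mean max cross-correlation.
    """
    preset = get_preset(stimulus_preset)
    pops = list(preset.populations)
    frac = {p: [] for p in pops}
    coeff = {p: [] for p in pops}
    evoked_amp = {p: [] for p in pops}
    evoked_hw = {p: [] for p in pops}
    for seed in _seeds(master_seed, n_seeds):
        basal_traces, _ = simulate_preset("basal-exvivo", seed, n_cells=n_cells)
        stim_traces, truth = simulate_preset(stimulus_preset, seed + 500_000_000, n_cells=n_cells)
        basal_dff = preprocess(basal_traces)
        stim_dff = preprocess(stim_traces)
        basal_coeffs = session_coefficients(basal_dff, response_params, corr_params)
        stim_coeffs = session_coefficients(stim_dff, response_params, corr_params)
        summary = classify_responsive(
            basal_coeffs, stim_coeffs, stim_traces.population_of, response_params
        )
        events = detect_events(stim_dff, detection)
        matched = match_events(events, truth, kind="evoked")
        corr = max_crosscorr(stim_dff, corr_params)
        for p in pops:
            frac[p].append(summary.fraction_responsive_pct[p])
            coeff[p].append(corr.population_mean(p))
            sub = matched[matched.population == p]
            evoked_amp[p] += list(sub.amplitude.dropna())
            evoked_hw[p] += list(sub.half_width_s.dropna())
    out = {"n_seeds": n_seeds, "n_cells": n_cells, "stimulus": stimulus_preset}
    for p in pops:
        out[f"{p}_pct_responsive"] = float(np.mean(frac[p]))
        out[f"{p}_mean_max_crosscorr"] = float(np.mean(coeff[p]))
        out[f"{p}_evoked_mean_amplitude"] = (
            float(np.mean(evoked_amp[p])) if evoked_amp[p] else float("nan")
        )
        out[f"{p}_evoked_mean_half_width_s"] = (
            float(np.mean(evoked_hw[p])) if evoked_hw[p] else float("nan")
        )
    return out


def acceptance_metrics(master_seed: int) -> dict[str, dict]:
    """All acceptance quantities, recomputed from scratch at desk scale.

    Returns ``{target_id: {"value": ..., "n": ...}}`` where ``n`` is the
    number of cells per population per replicate.
    """
    basal = basal_fsh_experiment(master_seed, n_seeds=5, n_cells=20)
    sync = lh_sync_experiment(master_seed + 11, n_seeds=5, n_cells=20)
    gnrh = stimulation_experiment("gnrh-response", master_seed + 23, n_seeds=10, n_cells=40)
    cck = stimulation_experiment("cck-response", master_seed + 37, n_seeds=5, n_cells=20)
    return {
        "t1": {"value": basal["mean_half_width_s"], "n": basal["n_cells"]},
        "t2": {"value": basal["mean_amplitude"], "n": basal["n_cells"]},
        "t3": {"value": sync["mean_half_width_s"], "n": sync["n_cells"]},
        "t4": {"value": sync["mean_amplitude"], "n": sync["n_cells"]},
        "t5": {"value": sync["lh_mean_max_crosscorr"], "n": sync["n_cells"]},
        "t6": {"value": sync["fsh_mean_max_crosscorr"], "n": sync["n_cells"]},
        "t7": {"value": gnrh["LH_pct_responsive"], "n": gnrh["n_cells"]},
        "t8": {"value": gnrh["FSH_pct_responsive"], "n": gnrh["n_cells"]},
        "t9": {"value": cck["FSH_mean_max_crosscorr"], "n": cck["n_cells"]},
        "t10": {"value": cck["LH_mean_max_crosscorr"], "n": cck["n_cells"]},
        "t11": {"value": gnrh["LH_evoked_mean_half_width_s"], "n": gnrh["n_cells"]},
        "t12": {"value": gnrh["LH_evoked_mean_amplitude"], "n": gnrh["n_cells"]},
    }
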