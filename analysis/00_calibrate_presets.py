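#!/usr/bin/env python
"""Calibration record for the free preset fields.

The anchored preset fields (transient kinetics, responder fractions,
population coefficients) come straight from the published in vivo / ex vivo
observations.  The remaining fields — photon-noise and drift levels, event
timing dispersion (jitter), and per-cell event-duration scatter — are not
printed anywhere and were fixed ONCE by the sweeps reproduced here: each
sweep simulates recordings, runs the full pipeline, and reports the
recovered kinetics and population coefficients next to their anchors.  The
values shipped in ``src/gonadocal/presets.yaml`` are the outcome; this
script exists so the choice is reproducible and inspectable, and is not
re-run as part of analysis.

Run:  python analysis/00_calibrate_presets.py  (writes results/calibration_sweeps.csv)
"""

from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd

from gonadocal.experiments import match_events
from gonadocal.presets import get_preset
from gonadocal.preprocess import preprocess
from gonadocal.synchrony import max_crosscorr
from gonadocal.synth import simulate_population
from gonadocal.transients import detect_events

OUT = Path("results")


def lh_sync_sweep():
    """Jitter x width-scatter sweep for the synchronized LH event.

    Anchors: half-width 75.55 s, amplitude 1.5 dF/F, population coefficient
    0.89 at maxlag 30 s.  Timing jitter decorrelates only once pairwise
    offsets exceed the 30 s lag cap, leaving the detected kinetics intact,
    which is why the shipped preset uses jitter 24 s + scatter 0.2.
    """
    p = get_preset("lh-sync-event")
    rows = []
    for jitter in (0.5, 12.0, 24.0):
        for scatter in (0.0, 0.2, 0.4):
            cpl = dict(p.coupling)
            cpl["LH"] = replace(cpl["LH"], jitter_sd_s=jitter, halfwidth_scatter_cv=scatter)
            rs, hws, amps = [], [], []
            for seed in range(5):
                traces, truth = simulate_population(
                    p.recording, p.populations, cpl, None, p.noise, seed=seed
                )
                dff = preprocess(traces)
                events = detect_events(dff)
                m = match_events([e for e in events if e.population == "LH"], truth, "shared")
                m = m[m.population == "LH"].dropna(subset=["half_width_s"])
                hws += list(m.half_width_s)
                amps += list(m.amplitude)
                rs.append(max_crosscorr(dff).population_mean("LH"))
            rows.append(
                {
                    "sweep": "lh-sync",
                    "jitter_sd_s": jitter,
                    "halfwidth_scatter_cv": scatter,
                    "mean_max_crosscorr": np.mean(rs),
                    "mean_half_width_s": np.mean(hws),
                    "mean_amplitude": np.mean(amps),
                }
            )
    return pd.DataFrame(rows)


def cck_fsh_sweep():
    """Evoked-width heterogeneity sweep for the CCK response.

    Anchor: FSH population coefficient 0.7.  The published per-fish
    half-width range (40.3-172 s) motivates a wide per-cell duration
    distribution; cv 0.7 lands the coefficient on its anchor.
    """
    p = get_preset("cck-response")
    rows = []
    for hw_cv in (0.3, 0.5, 0.7, 0.9):
        rk = dict(p.stimulus.response_kinetics_by_population)
        rk["FSH"] = replace(rk["FSH"], halfwidth_cv=hw_cv)
        stim = replace(p.stimulus, response_kinetics_by_population=rk)
        vals = []
        for seed in range(5):
            traces, _ = simulate_population(
                p.recording, p.populations, p.coupling, stim, p.noise, seed=seed
            )
            vals.append(max_crosscorr(preprocess(traces)).population_mean("FSH"))
        rows.append(
            {"sweep": "cck-fsh", "evoked_halfwidth_cv": hw_cv, "mean_max_crosscorr": np.mean(vals)}
        )
    return pd.DataFrame(rows)


def main():
    OUT.mkdir(exist_ok=True)
    table = pd.concat([lh_sync_sweep(), cck_fsh_sweep()], ignore_index=True)
    table.to_csv(OUT / "calibration_sweeps.csv", index=False)
    print(table.to_string(index=False))
    print(
        "\nShipped choices: LH jitter 24 s + width scatter 0.2 (coefficient ~0.89,"
        " kinetics within tolerance); CCK FSH evoked width cv 0.7 (coefficient ~0.70)."
    )


if __name__ == "__main__":
    main()
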