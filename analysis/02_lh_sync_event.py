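#!/usr/bin/env python
"""The synchronized LH population event and its trailing FSH follow-event.

Simulates five recordings of the lh-sync-event preset (20 LH-like + 20
FSH-like cells): one long high-amplitude event shared by every LH cell,
followed 40 s later by a less synchronized FSH rise.  Recovers the event
kinetics by detection and the per-population mean max cross-correlation
(maxlag 30 s).  Anchors: 75.55 s / 1.5 dF/F; coefficients 0.89 (LH) and
0.66 (FSH).

Writes results/lh_sync_event.csv (per-replicate coefficients) and prints the summary.
"""

from pathlib import Path

import pandas as pd

from gonadocal.experiments import lh_sync_experiment, simulate_preset, _seeds
from gonadocal.preprocess import preprocess
from gonadocal.synchrony import max_crosscorr

SEED = 12
OUT = Path("results")


def main():
    OUT.mkdir(exist_ok=True)
    summary = lh_sync_experiment(SEED, n_seeds=5, n_cells=20)
    rows = []
    for i, seed in enumerate(_seeds(SEED, 5)):
        traces, _ = simulate_preset("lh-sync-event", seed)
        corr = max_crosscorr(preprocess(traces))
        rows.append(
            {
                "replicate": i,
                "lh_mean_max_crosscorr": corr.population_mean("LH"),
                "fsh_mean_max_crosscorr": corr.population_mean("FSH"),
            }
        )
    pd.DataFrame(rows).to_csv(OUT / "lh_sync_event.csv", index=False)
    print("Synchronized LH event over 5 replicate fish (20+20 cells, 10 min, 10 Hz):")
    print(f"  event half-width:   {summary['mean_half_width_s']:.1f} s   (anchor 75.55 s)")
    print(f"  event amplitude:    {summary['mean_amplitude']:.3f} dF/F (anchor 1.5)")
    print(f"  LH mean max corr:   {summary['lh_mean_max_crosscorr']:.3f}  (anchor 0.89)")
    print(f"  FSH mean max corr:  {summary['fsh_mean_max_crosscorr']:.3f}  (anchor 0.66)")


if __name__ == "__main__":
    main()
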