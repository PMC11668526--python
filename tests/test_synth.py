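"""Generator contracts: determinism, coupling degeneracy, Poisson counts,
positivity, evoked-event bookkeeping, rendering round trips, and the
jitter/synchrony monotonicity property."""

import numpy as np
import pytest

from gonadocal.experiments import simulate_preset
from gonadocal.presets import get_preset, load_presets
from gonadocal.preprocess import preprocess
from gonadocal.synchrony import max_crosscorr
from gonadocal.synth import (
    CouplingSpec,
    KineticsPreset,
    NoiseSpec,
    PopulationSpec,
    RecordingSpec,
    render_movie,
    roi_table_for,
    simulate_population,
)
from gonadocal.trace_io import extract_traces

REC = RecordingSpec(10.0, 600.0)
QUIET = NoiseSpec(100.0, 0.0, 0.0, 0.0, 0.0, 60.0)


def test_single_event_noise_free_max_dff():
    """One cell, one event of amplitude 0.8: max(F/baseline - 1) = 0.8 +/- 2%."""
    kin = KineticsPreset(0.0, 0.8, 0.0, 10.0, 0.0, 0.1)
    traces, _ = simulate_population(
        REC,
        {"LH": PopulationSpec(1, kin)},
        {"LH": CouplingSpec((60.0,))},
        noise=QUIET,
        seed=0,
    )
    rel = traces.values[:, 0] / 100.0 - 1.0
    assert rel.max() == pytest.approx(0.8, rel=0.02)


def test_degenerate_coupling_identical_traces():
    kin = KineticsPreset(0.0, 1.0, 0.0, 20.0, 0.0, 0.1)
    traces, _ = simulate_population(
        REC,
        {"LH": PopulationSpec(2, kin)},
        {"LH": CouplingSpec((100.0,), participation=1.0, jitter_sd_s=0.0,
                            amplitude_scatter_cv=0.0, halfwidth_scatter_cv=0.0)},
        noise=QUIET,
        seed=3,
    )
    np.testing.assert_array_equal(traces.values[:, 0], traces.values[:, 1])


def test_determinism_bit_identical():
    for preset in ("basal-fsh", "lh-sync-event", "gnrh-response"):
        t1, g1 = simulate_preset(preset, 42)
        t2, g2 = simulate_preset(preset, 42)
        np.testing.assert_array_equal(t1.values, t2.values)
        assert g1.events == g2.events
        assert g1.responder_flags == g2.responder_flags
        t3, _ = simulate_preset(preset, 43)
        assert not np.array_equal(t1.values, t3.values)


def test_poisson_event_count_within_3sd():
    """Rate 4/cell/session over 20 cells: count within 3 SD of the Poisson mean 80."""
    kin = KineticsPreset(4.0, 0.6, 0.25, 10.08, 0.2, 0.1)
    _, truth = simulate_population(REC, {"FSH": PopulationSpec(20, kin)}, noise=QUIET, seed=11)
    n = len(truth.events)
    assert abs(n - 80) <= 3 * np.sqrt(80)


def test_refractory_gap_enforced():
    kin = KineticsPreset(12.0, 0.6, 0.0, 10.0, 0.0, 0.1)
    _, truth = simulate_population(REC, {"FSH": PopulationSpec(10, kin)}, noise=QUIET, seed=5)
    for cell in {e.cell_id for e in truth.events}:
        onsets = sorted(e.onset_s for e in truth.events_of(cell_id=cell))
        gaps = np.diff(onsets)
        assert (gaps >= 2 * 10.0 - 1e-9).all()


def test_all_shipped_presets_strictly_positive():
    for name, preset in load_presets().items():
        traces, _ = simulate_preset(name, 1)
        assert (traces.values > 0).all(), name


def test_evoked_bookkeeping_and_flags():
    traces, truth = simulate_preset("gnrh-response", 9)
    evoked_cells = [e.cell_id for e in truth.events_of(kind="evoked")]
    assert len(evoked_cells) == len(set(evoked_cells)), "one evoked event per responder"
    for cell, flag in truth.responder_flags.items():
        n_evoked = len(truth.events_of(cell_id=cell, kind="evoked"))
        assert n_evoked == (1 if flag else 0)


def test_stimulus_validation_errors():
    preset = get_preset("gnrh-response")
    from dataclasses import replace

    late = replace(preset.stimulus, onset_s=700.0)
    with pytest.raises(ValueError, match="onset"):
        simulate_population(REC, preset.populations, preset.coupling, late, preset.noise, 0)
    tail_heavy = replace(preset.stimulus, onset_s=500.0)
    with pytest.raises(ValueError, match="mass|fit"):
        simulate_population(REC, preset.populations, preset.coupling, tail_heavy, preset.noise, 0)


def test_jitter_does_not_increase_synchrony():
    """Population mean max cross-correlation is non-increasing in jitter_sd."""
    kin = KineticsPreset(0.0, 1.5, 0.0, 20.0, 0.0, 0.1)
    noise = NoiseSpec(100.0, 0.1, 0.03, 0.0, 0.0, 60.0)
    means = []
    for jitter in (0.0, 1.0, 3.0, 10.0):
        vals = []
        for seed in range(5):
            traces, _ = simulate_population(
                RecordingSpec(10.0, 300.0),
                {"LH": PopulationSpec(20, kin)},
                {"LH": CouplingSpec((60.0,), 1.0, jitter_sd_s=jitter)},
                noise=noise,
                seed=seed,
            )
            vals.append(max_crosscorr(preprocess(traces)).population_mean("LH"))
        means.append(np.mean(vals))
    for lo, hi in zip(means[1:], means[:-1]):
        assert lo <= hi + 0.01  # Monte-Carlo tolerance on the 5-seed means


def test_render_constant_field_mask_mean():
    from conftest import make_traces

    traces = make_traces(np.full((5, 1), 100.0))
    stack = render_movie(traces, [(16.0, 16.0)], 4.0, (32, 32))
    rois = roi_table_for(traces, [(16.0, 16.0)])
    recovered = extract_traces(stack, rois, 4.0, traces.sampling_frequency)
    np.testing.assert_allclose(recovered.values, 100.0, rtol=0.01)


def test_render_two_cells_distinct_constants():
    from conftest import make_traces

    traces = make_traces(np.column_stack([np.full(4, 50.0), np.full(4, 200.0)]))
    centroids = [(10.0, 10.0), (30.0, 30.0)]
    stack = render_movie(traces, centroids, 3.5, (40, 40))
    recovered = extract_traces(stack, roi_table_for(traces, centroids), 3.5, 10.0)
    np.testing.assert_allclose(recovered.values[:, 0], 50.0, rtol=0.01)
    np.testing.assert_allclose(recovered.values[:, 1], 200.0, rtol=0.01)


def test_simulate_render_extract_round_trip():
    """Recovered ROI traces correlate > 0.99 with the simulated input."""
    kin = KineticsPreset(3.0, 0.8, 0.2, 8.0, 0.2, 0.1)
    traces, _ = simulate_population(
        RecordingSpec(5.0, 120.0),
        {"FSH": PopulationSpec(3, kin)},
        noise=NoiseSpec(200.0, 0.2, 0.02, 0.0, 0.0, 60.0),
        seed=2,
    )
    centroids = [(12.0, 12.0), (36.0, 12.0), (24.0, 36.0)]
    stack = render_movie(traces, centroids, 4.0, (48, 48))
    recovered = extract_traces(stack, roi_table_for(traces, centroids), 4.0, 5.0)
    for j in range(3):
        r = np.corrcoef(traces.values[:, j], recovered.values[:, j])[0, 1]
        assert r > 0.99
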