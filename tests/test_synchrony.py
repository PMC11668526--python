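"""Synchrony contracts: brute-force oracle equivalence, identity/shift cases,
white-noise null, affine invariance, matrix structure, reference vectors."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_traces
from gonadocal.preprocess import compute_dff
from gonadocal.synchrony import (
    CorrelationParams,
    correlations_to_frame,
    max_crosscorr,
    reference_vector,
)


def dff_from(values, fs=10.0, population="LH"):
    """Wrap plain signal arrays as a DffMatrix, bypassing normalization."""
    from gonadocal.preprocess import DffMatrix, DffParams

    values = np.asarray(values, dtype=float)
    cells = [f"c{j}" for j in range(values.shape[1])]
    return DffMatrix(
        values=values,
        sampling_frequency=fs,
        cell_ids=cells,
        population_of={c: population for c in cells},
        f0_per_cell=np.ones(values.shape[1]),
        filtered=False,
        params=DffParams(),
    )


def brute_force_max_crosscorr(values, fs, maxlag_s):
    """Direct O(n_cells^2 x lags x frames) sum — the independent oracle."""
    n_frames, n_cells = values.shape
    lag = min(int(round(maxlag_s * fs)), n_frames - 1)
    x = values - values.mean(axis=0, keepdims=True)
    energy = (x**2).sum(axis=0)
    coeff = np.eye(n_cells)
    for i in range(n_cells):
        for j in range(i + 1, n_cells):
            best = -np.inf
            for k in range(-lag, lag + 1):
                s = 0.0
                for t in range(n_frames):
                    if 0 <= t + k < n_frames:
                        s += x[t, i] * x[t + k, j]
                best = max(best, s / np.sqrt(energy[i] * energy[j]))
            coeff[i, j] = coeff[j, i] = best
    return coeff


def test_equals_brute_force_oracle():
    rng = np.random.default_rng(0)
    values = rng.standard_normal((200, 5)).cumsum(axis=0) * 0.1
    values -= values.min() - 1.0
    dff = dff_from(values, fs=2.0)
    params = CorrelationParams(maxlag_s=10.0)
    fast = max_crosscorr(dff, params).max_coeff
    slow = brute_force_max_crosscorr(dff.values, 2.0, 10.0)
    assert np.max(np.abs(fast - slow)) < 1e-8


def test_identical_traces_score_one_at_lag_zero():
    rng = np.random.default_rng(1)
    x = rng.standard_normal(500)
    dff = dff_from(np.column_stack([x, x]))
    result = max_crosscorr(dff)
    assert result.max_coeff[0, 1] == pytest.approx(1.0, abs=1e-12)
    assert result.argmax_lag_s[0, 1] == 0.0


def test_shifted_trace_recovers_shift_lag():
    """A trace against itself delayed by 5 samples peaks at lag 5/fs."""
    t = np.arange(1000) / 10.0
    x = np.sin(2 * np.pi * 0.3 * t) + 0.5 * np.sin(2 * np.pi * 0.07 * t)
    y = np.roll(x, 5)
    dff = dff_from(np.column_stack([x, y]))
    result = max_crosscorr(dff, CorrelationParams(maxlag_s=3.0))
    assert result.max_coeff[0, 1] == pytest.approx(1.0, abs=0.01)
    assert abs(result.argmax_lag_s[0, 1]) == pytest.approx(0.5, abs=1e-9)
    assert result.argmax_lag_s[0, 1] == -result.argmax_lag_s[1, 0]


def test_white_noise_null_stays_low():
    """Independent white-noise pairs: max coefficient < 0.15 (6000 frames, L=300)."""
    rng = np.random.default_rng(2)
    for _ in range(20):
        dff = dff_from(rng.standard_normal((6000, 2)))
        r = max_crosscorr(dff, CorrelationParams(maxlag_s=30.0)).max_coeff[0, 1]
        assert r < 0.15


@settings(max_examples=15, deadline=None, derandomize=True)
@given(a=st.floats(0.1, 50.0), b=st.floats(-5.0, 5.0), seed=st.integers(0, 1000))
def test_affine_invariance(a, b, seed):
    rng = np.random.default_rng(seed)
    base = rng.standard_normal((300, 3))
    r1 = max_crosscorr(dff_from(base), CorrelationParams(5.0)).max_coeff
    scaled = base.copy()
    scaled[:, 1] = a * scaled[:, 1] + b
    r2 = max_crosscorr(dff_from(scaled), CorrelationParams(5.0)).max_coeff
    np.testing.assert_allclose(r1, r2, atol=1e-9)


def test_matrix_structure_and_bounds():
    rng = np.random.default_rng(3)
    dff = dff_from(rng.standard_normal((400, 6)))
    result = max_crosscorr(dff, CorrelationParams(10.0))
    m = result.max_coeff
    np.testing.assert_allclose(m, m.T, atol=1e-10)
    np.testing.assert_array_equal(np.diag(m), 1.0)
    assert (m <= 1.0 + 1e-12).all() and (m >= -1.0 - 1e-12).all()
    np.testing.assert_allclose(result.argmax_lag_s, -result.argmax_lag_s.T, atol=1e-12)


def test_zero_variance_trace_excluded_with_warning():
    rng = np.random.default_rng(4)
    values = rng.standard_normal((300, 3))
    values[:, 2] = 0.0
    with pytest.warns(UserWarning, match="zero-variance"):
        result = max_crosscorr(dff_from(values))
    assert np.isnan(result.max_coeff[2, 0]) and np.isnan(result.max_coeff[0, 2])
    assert np.isfinite(result.max_coeff[0, 1])
    assert np.isfinite(result.population_mean("LH"))


def test_population_mean_uses_unordered_pairs():
    rng = np.random.default_rng(5)
    dff = dff_from(rng.standard_normal((300, 4)))
    result = max_crosscorr(dff, CorrelationParams(5.0))
    iu = np.triu_indices(4, k=1)
    assert result.population_mean("LH") == pytest.approx(result.max_coeff[iu].mean())


def test_reference_vector_consistency_with_matrix():
    rng = np.random.default_rng(6)
    dff = dff_from(rng.standard_normal((400, 5)))
    params = CorrelationParams(10.0)
    matrix = max_crosscorr(dff, params)
    ref, vec = reference_vector(dff, dff.cell_ids[2], params)
    assert ref == dff.cell_ids[2]
    assert vec[dff.cell_ids[2]] == 1.0
    for j, cell in enumerate(dff.cell_ids):
        if j != 2:
            assert vec[cell] == pytest.approx(matrix.max_coeff[2, j], abs=1e-10)


def test_reference_auto_picks_highest_variance():
    rng = np.random.default_rng(7)
    values = rng.standard_normal((300, 3))
    values[:, 1] *= 10.0
    dff = dff_from(values)
    ref, _ = reference_vector(dff, "auto")
    assert ref == dff.cell_ids[1]


def test_constant_reference_rejected():
    values = np.random.default_rng(8).standard_normal((300, 2))
    values[:, 0] = 0.0
    with pytest.raises(ValueError, match="constant"):
        reference_vector(dff_from(values), "c0")


def test_perfectly_coupled_population_all_ones():
    from gonadocal.synth import (
        CouplingSpec,
        KineticsPreset,
        NoiseSpec,
        PopulationSpec,
        RecordingSpec,
        simulate_population,
    )

    traces, _ = simulate_population(
        RecordingSpec(10.0, 300.0),
        {"LH": PopulationSpec(4, KineticsPreset(0.0, 1.0, 0.0, 15.0, 0.0, 0.1))},
        {"LH": CouplingSpec((80.0,))},
        noise=NoiseSpec(100.0, 0.3, 0.0, 0.0, 0.0, 60.0),
        seed=1,
    )
    dff = compute_dff(make_traces(traces.values, fs=10.0))
    _, vec = reference_vector(dff, "auto")
    for v in vec.values():
        assert v == pytest.approx(1.0, abs=1e-9)


def test_long_format_table():
    rng = np.random.default_rng(9)
    dff = dff_from(rng.standard_normal((200, 3)))
    table = correlations_to_frame(max_crosscorr(dff, CorrelationParams(5.0)))
    assert len(table) == 3
    assert set(table.columns) == {"cell_i", "cell_j", "population", "max_coeff", "lag_s"}
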