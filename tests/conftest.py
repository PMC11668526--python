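import numpy as np
import pytest

from gonadocal.trace_io import TraceMatrix


@pytest.fixture
def small_traces():
    """3 cells x 120 frames at 2 Hz, strictly positive, two populations."""
    rng = np.random.default_rng(7)
    values = 100.0 + rng.random((120, 3)) * 5.0
    return TraceMatrix(
        values=values,
        sampling_frequency=2.0,
        cell_ids=["a", "b", "c"],
        population_of={"a": "LH", "b": "LH", "c": "FSH"},
        session_role="basal",
    )


def make_traces(values, fs=10.0, population="LH", role="basal"):
    values = np.asarray(values, dtype=float)
    cells = [f"c{j}" for j in range(values.shape[1])]
    return TraceMatrix(
        values=values,
        sampling_frequency=fs,
        cell_ids=cells,
        population_of={c: population for c in cells},
        session_role=role,
    )
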