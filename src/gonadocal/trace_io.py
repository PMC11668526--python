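"""Reading and writing the pipeline's artefacts.

Trace CSV dialect: first column ``frame`` (0-based integer), one column per
cell named ``<population>_<cell_id>`` (e.g. ``LH_c003``).  Time carries no
column of its own; it derives from the session's sampling frequency.  ROI
tables, results tables and run manifests are plain CSV/JSON; image stacks are
multi-page grayscale TIFF.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import tifffile
import yaml

__all__ = [
    "TraceMatrix",
    "RoiTable",
    "SessionConfig",
    "read_traces",
    "write_traces",
    "read_roi_table",
    "write_roi_table",
    "extract_traces",
    "read_stack",
    "write_stack",
    "write_results",
    "write_ground_truth",
    "read_config",
    "write_config",
]

SESSION_ROLES = ("basal", "stimulation", "post")

#: decimal places kept when writing trace CSVs (round-trip precision contract)
TRACE_DECIMALS = 6


@dataclass
class TraceMatrix:
    """Raw fluorescence time series, frames x cells, at a fixed sampling rate."""

    values: np.ndarray  # (n_frames, n_cells), arbitrary fluorescence units
    sampling_frequency: float  # Hz
    cell_ids: list[str]
    population_of: dict[str, str]
    session_role: str = "basal"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("trace values must be a 2-D frames x cells array")
        if self.sampling_frequency <= 0:
            raise ValueError("sampling_frequency must be positive")
        if len(self.cell_ids) != self.values.shape[1]:
            raise ValueError(
                f"{len(self.cell_ids)} cell ids for {self.values.shape[1]} columns"
            )
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise ValueError("cell_ids must be unique")
        if self.session_role not in SESSION_ROLES:
            raise ValueError(f"session_role must be one of {SESSION_ROLES}")
        missing = [c for c in self.cell_ids if c not in self.population_of]
        if missing:
            raise ValueError(f"cells without population label: {missing}")

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


@dataclass
class RoiTable:
    """One centroid (x, y; 0-based pixels, origin top-left) per cell."""

    cell_ids: list[str]
    centroids: np.ndarray  # (n_cells, 2) as (x, y)
    population_of: dict[str, str]

    def __post_init__(self):
        self.centroids = np.asarray(self.centroids, dtype=float)
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise ValueError("duplicate cell_id in ROI table")
        if self.centroids.shape != (len(self.cell_ids), 2):
            raise ValueError("centroids must be (n_cells, 2)")
        if not np.all(np.isfinite(self.centroids)):
            raise ValueError("non-finite centroid")


@dataclass
class SessionConfig:
    """Everything one imaging session needs to be analyzed reproducibly."""

    sampling_frequency: float
    session_role: str = "basal"
    stimulus_label: str | None = None
    stimulus_onset_s: float | None = None
    trace_path: str | None = None
    roi_path: str | None = None
    # analysis parameters (defaults mirror the Methods' conventions)
    block_seconds: float = 5.0
    filter_threshold_hz: float = 4.0
    filter_cutoff_hz: float = 2.0
    maxlag_s: float = 30.0
    detection_threshold_k: float = 3.0
    min_duration_s: float = 1.0
    responsiveness_percentile: float = 80.0
    seed: int = 0

    def __post_init__(self):
        if self.sampling_frequency <= 0:
            raise ValueError("sampling_frequency must be positive")
        if self.session_role not in SESSION_ROLES:
            raise ValueError(f"session_role must be one of {SESSION_ROLES}")
        for name in (
            "block_seconds",
            "filter_threshold_hz",
            "filter_cutoff_hz",
            "maxlag_s",
            "detection_threshold_k",
            "min_duration_s",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.responsiveness_percentile < 100:
            raise ValueError("responsiveness_percentile must lie in (0, 100)")
        if self.session_role == "stimulation" and self.stimulus_onset_s is None:
            raise ValueError("stimulation session requires stimulus_onset_s")


def _column_name(population: str, cell_id: str) -> str:
    return f"{population}_{cell_id}"


def write_traces(traces: TraceMatrix, path: str | Path) -> Path:
    """Write the trace CSV dialect (frame column + one column per cell)."""
    path = Path(path)
    df = pd.DataFrame(
        np.round(traces.values, TRACE_DECIMALS),
        columns=[
            _column_name(traces.population_of[c], c) for c in traces.cell_ids
        ],
    )
    df.insert(0, "frame", np.arange(traces.n_frames))
    df.to_csv(path, index=False)
    return path


def read_traces(path: str | Path, config: SessionConfig) -> TraceMatrix:
    """Read a trace CSV; populations resolve from the column-name prefix."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path) as fh:
        header_line = fh.readline().strip()
    # pandas mangles duplicate headers; check the raw line
    cols = [c.strip() for c in header_line.split(",")] if header_line else []
    dupes = sorted({c for c in cols if cols.count(c) > 1})
    if dupes:
        raise ValueError(f"duplicate column header(s) in {path.name}: {dupes}")
    df = pd.read_csv(path)
    if df.empty:
        raise ValueError(f"{path.name}: no data rows")
    value_cols = [c for c in df.columns if c != "frame"]
    cell_ids, population_of = [], {}
    for col in value_cols:
        if "_" not in col:
            raise ValueError(
                f"{path.name}: column {col!r} is not '<population>_<cell_id>'"
            )
        pop, cell = col.split("_", 1)
        cell_ids.append(cell)
        population_of[cell] = pop
    if len(set(cell_ids)) != len(cell_ids):
        dupes = sorted({c for c in cell_ids if cell_ids.count(c) > 1})
        raise ValueError(f"{path.name}: duplicate cell id(s): {dupes}")
    values = np.empty((len(df), len(value_cols)))
    for j, col in enumerate(value_cols):
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = numeric.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(
                f"{path.name}: non-numeric value in column {col!r}, row {row}"
            )
        if numeric.isna().any():
            row = int(np.flatnonzero(numeric.isna().to_numpy())[0])
            raise ValueError(f"{path.name}: missing value in column {col!r}, row {row}")
        values[:, j] = numeric.to_numpy()
    return TraceMatrix(
        values=values,
        sampling_frequency=config.sampling_frequency,
        cell_ids=cell_ids,
        population_of=population_of,
        session_role=config.session_role,
    )


def write_roi_table(rois: RoiTable, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame(
        {
            "cell_id": rois.cell_ids,
            "x": rois.centroids[:, 0],
            "y": rois.centroids[:, 1],
            "population": [rois.population_of[c] for c in rois.cell_ids],
        }
    ).to_csv(path, index=False)
    return path


def read_roi_table(path: str | Path) -> RoiTable:
    df = pd.read_csv(path)
    required = {"cell_id", "x", "y", "population"}
    if not required.issubset(df.columns):
        raise ValueError(f"ROI table {path} missing columns {required - set(df.columns)}")
    cell_ids = [str(c) for c in df["cell_id"]]
    return RoiTable(
        cell_ids=cell_ids,
        centroids=df[["x", "y"]].to_numpy(float),
        population_of=dict(zip(cell_ids, (str(p) for p in df["population"]))),
    )


# ---------------------------------------------------------------------------
# image stacks and ROI extraction


def read_stack(path: str | Path) -> np.ndarray:
    """Read a multi-page grayscale TIFF as float (frames, H, W)."""
    stack = tifffile.imread(str(path)).astype(float)
    if stack.ndim == 2:
        stack = stack[None]
    if stack.ndim != 3:
        raise ValueError(f"expected a grayscale stack, got shape {stack.shape}")
    return stack


def write_stack(stack: np.ndarray, path: str | Path) -> Path:
    """Write a float stack as 16-bit multi-page TIFF (values clipped to uint16)."""
    path = Path(path)
    arr = np.clip(np.round(stack), 0, np.iinfo(np.uint16).max).astype(np.uint16)
    tifffile.imwrite(str(path), arr, photometric="minisblack")
    return path


def disk_mask(shape_hw: tuple[int, int], centroid_xy, radius_px: float) -> np.ndarray:
    """Boolean mask of pixels whose centre lies strictly within ``radius_px``."""
    h, w = shape_hw
    cx, cy = centroid_xy
    yy, xx = np.mgrid[0:h, 0:w]
    return (xx - cx) ** 2 + (yy - cy) ** 2 < radius_px**2


def extract_traces(
    stack: np.ndarray,
    rois: RoiTable,
    radius_px: float,
    sampling_frequency: float,
    session_role: str = "basal",
) -> TraceMatrix:
    """Mean gray value per ROI disk per frame — ROI-manager style extraction."""
    if radius_px <= 0:
        raise ValueError("radius_px must be positive")
    stack = np.asarray(stack, dtype=float)
    n_frames, h, w = stack.shape
    flat = stack.reshape(n_frames, -1)
    values = np.empty((n_frames, len(rois.cell_ids)))
    for j, cell in enumerate(rois.cell_ids):
        cx, cy = rois.centroids[j]
        if not (0 <= cx < w and 0 <= cy < h):
            raise ValueError(f"ROI centroid of {cell} outside image bounds")
        mask = disk_mask((h, w), (cx, cy), radius_px)
        if not mask.any():
            raise ValueError(f"empty ROI mask for cell {cell}")
        values[:, j] = flat[:, mask.ravel()].mean(axis=1)
    return TraceMatrix(
        values=values,
        sampling_frequency=sampling_frequency,
        cell_ids=list(rois.cell_ids),
        population_of=dict(rois.population_of),
        session_role=session_role,
    )


# ---------------------------------------------------------------------------
# results, ground truth, configs


def write_results(
    out_dir: str | Path,
    events: pd.DataFrame | None = None,
    correlations: pd.DataFrame | None = None,
    responses: pd.DataFrame | None = None,
    manifest: Mapping | None = None,
) -> dict[str, Path]:
    """Write tidy result tables plus a JSON run manifest; returns written paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    event_cols = ["cell_id", "population", "onset_s", "peak_s", "amplitude", "half_width_s"]
    corr_cols = ["cell_i", "cell_j", "population", "max_coeff", "lag_s"]
    resp_cols = [
        "cell_id", "population", "basal_coeff", "stim_coeff", "threshold", "responsive",
    ]
    for name, df, cols in (
        ("events", events, event_cols),
        ("correlations", correlations, corr_cols),
        ("responses", responses, resp_cols),
    ):
        if df is None:
            continue
        if df.empty:
            df = pd.DataFrame(columns=cols)
        written[name] = out_dir / f"{name}.csv"
        df.to_csv(written[name], index=False)
    if manifest is not None:
        written["manifest"] = out_dir / "manifest.json"
        with open(written["manifest"], "w") as fh:
            json.dump(_jsonable(manifest), fh, indent=2, sort_keys=True)
    return written


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def write_ground_truth(truth, path: str | Path) -> Path:
    """Serialize a GroundTruth (events array + responder flags + seed) to JSON."""
    path = Path(path)
    with open(path, "w") as fh:
        json.dump(_jsonable(truth), fh, indent=2, sort_keys=True)
    return path


def write_config(config: SessionConfig, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        yaml.safe_dump(dataclasses.asdict(config), fh, sort_keys=True)
    return path


def read_config(path: str | Path) -> SessionConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    known = {f.name for f in dataclasses.fields(SessionConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return SessionConfig(**raw)
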