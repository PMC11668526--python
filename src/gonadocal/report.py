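"""Per-fish pipeline orchestration and plot-ready summary tables.

``run_pipeline`` takes the ordered sessions of one fish (basal, optionally
stimulation and post), runs dF/F -> conditional low-pass -> transient
detection -> synchrony on each, classifies stimulus-responsive cells when a
basal/stimulation pair is present, and writes every intermediate table plus
a JSON manifest.  ``make_figure_tables`` reduces a FishAnalysis to tidy
one-row-per-fish-per-population-per-metric tables ready for violin/dot
plotting; plotting itself stays outside the library.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import DffMatrix, DffParams, preprocess
from .response import ResponseParams, ResponseSummary, classify_responsive, session_coefficients
from .synchrony import CorrelationParams, CorrelationResult, correlations_to_frame, max_crosscorr
from .trace_io import SessionConfig, TraceMatrix, read_traces, write_results
from .transients import DetectionParams, TransientEvent, detect_events, events_to_frame, summarize_kinetics

logger = logging.getLogger("gonadocal")

__all__ = ["SessionOutput", "FishAnalysis", "run_pipeline", "make_figure_tables"]


@dataclass
class SessionOutput:
    config: SessionConfig
    dff: DffMatrix
    events: list[TransientEvent]
    correlation: CorrelationResult

    @property
    def role(self) -> str:
        return self.config.session_role


@dataclass
class FishAnalysis:
    fish_id: str
    sessions: list[SessionOutput]
    response: ResponseSummary | None
    manifest: dict = field(default_factory=dict)

    def session(self, role: str) -> SessionOutput:
        for s in self.sessions:
            if s.role == role:
                return s
        raise KeyError(f"no {role!r} session in fish {self.fish_id}")


def _params_from(config: SessionConfig):
    dff_params = DffParams(
        block_seconds=config.block_seconds,
        filter_threshold_hz=config.filter_threshold_hz,
        filter_cutoff_hz=config.filter_cutoff_hz,
    )
    det_params = DetectionParams(
        threshold_k=config.detection_threshold_k,
        min_duration_s=config.min_duration_s,
    )
    corr_params = CorrelationParams(maxlag_s=config.maxlag_s)
    resp_params = ResponseParams(percentile=config.responsiveness_percentile)
    return dff_params, det_params, corr_params, resp_params


def run_pipeline(
    sessions: list[tuple[SessionConfig, TraceMatrix | None]],
    fish_id: str = "fish",
    out_dir: str | Path | None = None,
) -> FishAnalysis:
    """Run the full analysis for one fish.

    ``sessions`` pairs each SessionConfig with its TraceMatrix; a None
    matrix is read from ``config.trace_path``.  All sessions of a fish must
    share cells and sampling frequency.  Deterministic given inputs; every
    stage error is re-raised with the stage name attached.
    """
    if not sessions:
        raise ValueError("no sessions given")
    loaded: list[tuple[SessionConfig, TraceMatrix]] = []
    for config, traces in sessions:
        if traces is None:
            if config.trace_path is None:
                raise ValueError("session without traces or trace_path")
            traces = read_traces(config.trace_path, config)
        loaded.append((config, traces))
    first = loaded[0][1]
    for config, traces in loaded[1:]:
        if traces.cell_ids != first.cell_ids:
            raise ValueError(f"fish {fish_id}: sessions do not share cells")
        if traces.sampling_frequency != first.sampling_frequency:
            raise ValueError(f"fish {fish_id}: sessions do not share sampling frequency")

    outputs: list[SessionOutput] = []
    warnings_log: list[str] = []
    for config, traces in loaded:
        dff_params, det_params, corr_params, _ = _params_from(config)
        try:
            dff = preprocess(traces, dff_params)
        except Exception as err:
            raise RuntimeError(f"[preprocess/{config.session_role}] {err}") from err
        try:
            events = detect_events(dff, det_params)
        except Exception as err:
            raise RuntimeError(f"[transients/{config.session_role}] {err}") from err
        try:
            corr = max_crosscorr(dff, corr_params)
        except Exception as err:
            raise RuntimeError(f"[synchrony/{config.session_role}] {err}") from err
        truncated = sum(1 for e in events if e.half_width_s is None)
        if truncated:
            warnings_log.append(
                f"{config.session_role}: {truncated} event(s) truncated at session edge"
            )
        logger.info(
            "%s/%s: %d cells, %d events, populations %s",
            fish_id, config.session_role, dff.n_cells, len(events), dff.populations(),
        )
        outputs.append(SessionOutput(config, dff, events, corr))

    response = None
    roles = [o.role for o in outputs]
    if "basal" in roles and "stimulation" in roles:
        basal = next(o for o in outputs if o.role == "basal")
        stim = next(o for o in outputs if o.role == "stimulation")
        _, _, corr_params, resp_params = _params_from(stim.config)
        try:
            basal_coeffs = session_coefficients(basal.dff, resp_params, corr_params)
            stim_coeffs = session_coefficients(stim.dff, resp_params, corr_params)
            response = classify_responsive(
                basal_coeffs, stim_coeffs, stim.dff.population_of, resp_params
            )
        except Exception as err:
            raise RuntimeError(f"[response] {err}") from err

    manifest = {
        "fish_id": fish_id,
        "sessions": [dataclasses.asdict(c) for c, _ in loaded],
        "warnings": warnings_log,
        "software": "gonadocal",
    }
    analysis = FishAnalysis(fish_id=fish_id, sessions=outputs, response=response, manifest=manifest)

    if out_dir is not None:
        out_dir = Path(out_dir)
        for o in outputs:
            write_results(
                out_dir / o.role,
                events=events_to_frame(o.events),
                correlations=correlations_to_frame(o.correlation),
                responses=response.per_cell if (response and o.role == "stimulation") else None,
                manifest=manifest,
            )
    return analysis


def make_figure_tables(analysis: FishAnalysis) -> pd.DataFrame:
    """Tidy per-fish summary: one row per session, population and metric.

    Metrics: mean amplitude, mean half-width, events per cell, mean max
    cross-correlation, and (stimulation sessions with a classification)
    percent responsive.  Populations without cells are omitted, not
    zero-filled.
    """
    rows = []
    for o in analysis.sessions:
        pops = {p: o.dff.cells_of(p) for p in o.dff.populations()}
        kin = summarize_kinetics(o.events, pops).set_index("population")
        for pop in pops:
            k = kin.loc[pop]
            metrics = {
                "mean_amplitude": k.mean_amplitude,
                "mean_half_width_s": k.mean_half_width_s,
                "events_per_cell": k.events_per_cell,
                "mean_max_crosscorr": o.correlation.population_mean(pop),
            }
            if o.role == "stimulation" and analysis.response is not None:
                metrics["pct_responsive"] = analysis.response.fraction_responsive_pct.get(
                    pop, np.nan
                )
            for metric, value in metrics.items():
                rows.append(
                    {
                        "fish_id": analysis.fish_id,
                        "session_role": o.role,
                        "population": pop,
                        "metric": metric,
                        "value": value,
                    }
                )
    return pd.DataFrame(rows, columns=["fish_id", "session_role", "population", "metric", "value"])
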