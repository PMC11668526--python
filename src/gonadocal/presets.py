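"""Shipped simulation presets, loaded from ``presets.yaml``.

Each experiment preset bundles recording geometry, population kinetics,
coupling, noise and (for stimulation experiments) the stimulus spec.  The
values anchored to published observations are listed in the YAML header;
free fields were fixed once by ``analysis/00_calibrate_presets.py``.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import yaml

from .synth import (
    CouplingSpec,
    KineticsPreset,
    NoiseSpec,
    PopulationSpec,
    RecordingSpec,
    StimulusSpec,
)

__all__ = ["ExperimentPreset", "load_presets", "get_preset", "preset_names"]


@dataclass(frozen=True)
class ExperimentPreset:
    name: str
    description: str
    recording: RecordingSpec
    populations: dict[str, PopulationSpec]
    coupling: dict[str, CouplingSpec]
    noise: NoiseSpec
    stimulus: StimulusSpec | None = None


def _kinetics(d: dict) -> KineticsPreset:
    return KineticsPreset(
        event_rate=d["event_rate"],
        amplitude_mean=d["amplitude_mean"],
        amplitude_cv=d["amplitude_cv"],
        halfwidth_mean_s=d["halfwidth_mean_s"],
        halfwidth_cv=d["halfwidth_cv"],
        rise_fraction=d["rise_fraction"],
    )


def _raw() -> dict:
    text = resources.files("gonadocal").joinpath("presets.yaml").read_text()
    return yaml.safe_load(text)


def _build(name: str, raw: dict) -> ExperimentPreset:
    exp = raw["experiments"][name]
    base = raw["experiments"][exp["base"]] if "base" in exp else exp
    recording = RecordingSpec(**raw["recording"])
    populations = {
        label: PopulationSpec(
            n_cells=p["n_cells"],
            kinetics=_kinetics(p["kinetics"]),
            background=_kinetics(p["background"]) if p.get("background") else None,
            shared_kinetics=_kinetics(p["shared_kinetics"]) if p.get("shared_kinetics") else None,
        )
        for label, p in base["populations"].items()
    }
    coupling = {
        label: CouplingSpec(
            shared_event_times_s=tuple(c["shared_event_times_s"]),
            participation=c["participation"],
            jitter_sd_s=c["jitter_sd_s"],
            amplitude_scatter_cv=c["amplitude_scatter_cv"],
            halfwidth_scatter_cv=c.get("halfwidth_scatter_cv", 0.0),
        )
        for label, c in (base.get("coupling") or {}).items()
    }
    stimulus = None
    if "stimulus" in exp:
        s = exp["stimulus"]
        stimulus = StimulusSpec(
            label=s["label"],
            onset_s=s["onset_s"],
            responder_fraction_by_population=dict(s["responder_fraction_by_population"]),
            response_kinetics_by_population={
                pop: _kinetics(k) for pop, k in s["response_kinetics_by_population"].items()
            },
            evoked_jitter_sd_s=s["evoked_jitter_sd_s"],
        )
    return ExperimentPreset(
        name=name,
        description=str(exp.get("description", "")).strip(),
        recording=recording,
        populations=populations,
        coupling=coupling,
        noise=NoiseSpec(**base.get("noise", exp.get("noise", {}))),
        stimulus=stimulus,
    )


def load_presets() -> dict[str, ExperimentPreset]:
    raw = _raw()
    return {name: _build(name, raw) for name in raw["experiments"]}


def preset_names() -> list[str]:
    return list(_raw()["experiments"])


def get_preset(name: str) -> ExperimentPreset:
    raw = _raw()
    if name not in raw["experiments"]:
        raise KeyError(f"unknown preset {name!r}; available: {list(raw['experiments'])}")
    return _build(name, raw)
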