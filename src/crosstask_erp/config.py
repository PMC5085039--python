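"""Structured run configuration (YAML or JSON).

One document with per-stage sections; every analysis constant of the study
(0.5-40 Hz band, 100-800 ms feature window, 20 Hz downsampling, 10 folds,
100/200 uV rejection thresholds, 1000 shuffles, 68% CIs) appears here as a
named default rather than being hard-coded at call sites.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .events import SequenceDesign
from .simulate import (
    BlinkSpec,
    ConditionSpec,
    ErpComponentSpec,
    NoiseSpec,
    SimulationConfig,
    SubjectVariabilitySpec,
    default_conditions,
)


@dataclass(frozen=True)
class PreprocessParams:
    band_low_hz: float = 0.5
    band_high_hz: float = 40.0
    epoch_tmin_ms: float = -100.0
    epoch_tmax_ms: float = 900.0
    discard_first_n: int = 8
    baseline_ms: tuple[float, float] = (-100.0, 0.0)
    reject_eeg_uV: float = 100.0
    reject_eog_uV: float = 200.0
    feature_window_ms: tuple[float, float] = (100.0, 800.0)
    feature_rate_hz: float = 20.0
    downsample: str = "mean"  # mean | pick


@dataclass(frozen=True)
class ClassifyParams:
    n_folds: int = 10
    learning_curve_draws: int = 20
    n_comparisons: int = 9
    chance_auc: float = 0.5


@dataclass(frozen=True)
class StatsParams:
    n_shuffles: int = 1000
    n_boot: int = 1000
    ci_level: float = 0.68
    alpha: float = 0.05


@dataclass(frozen=True)
class RunConfig:
    simulation: SimulationConfig
    preprocess: PreprocessParams = field(default_factory=PreprocessParams)
    classify: ClassifyParams = field(default_factory=ClassifyParams)
    stats: StatsParams = field(default_factory=StatsParams)


def default_run_config(master_seed: int = 0) -> RunConfig:
    return RunConfig(simulation=SimulationConfig(conditions=default_conditions(),
                                                 master_seed=master_seed))


# ---------------------------------------------------------------------------
# (de)serialization

def _component_from_dict(d: dict) -> ErpComponentSpec:
    return ErpComponentSpec(
        peak_latency_ms=float(d["peak_latency_ms"]),
        peak_amplitude_uV=float(d["peak_amplitude_uV"]),
        temporal_sd_ms=float(d["temporal_sd_ms"]),
        latency_jitter_sd_ms=float(d.get("latency_jitter_sd_ms", 0.0)),
        topography={str(k): float(v) for k, v in d.get("topography", {}).items()},
    )


def _merge_dataclass(cls, base, d: dict | None):
    if not d:
        return base
    fields = {f.name for f in dataclasses.fields(cls)}
    unknown = set(d) - fields
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    kwargs = {k: (tuple(v) if isinstance(v, list) else v) for k, v in d.items()}
    return dataclasses.replace(base, **kwargs)


def load_config(path: str | Path) -> RunConfig:
    """Load a YAML/JSON run configuration; unspecified values fall back to
    the study defaults.  Condition specs may be overridden per condition
    with explicit component dictionaries."""
    path = Path(path)
    text = path.read_text()
    doc = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    doc = doc or {}

    sim = doc.get("simulation", {})
    conditions = default_conditions()
    for cond, spec in (sim.pop("conditions", None) or {}).items():
        base = conditions.get(cond)
        shared = base.shared if base else ()
        conditions[cond] = ConditionSpec(
            target=_component_from_dict(spec["target"]),
            distractor=_component_from_dict(spec["distractor"]),
            shared=shared,
        )
    design = _merge_dataclass(SequenceDesign, SequenceDesign(), sim.pop("sequence_design", None))
    noise = _merge_dataclass(NoiseSpec, NoiseSpec(), sim.pop("noise", None))
    blink = _merge_dataclass(BlinkSpec, BlinkSpec(), sim.pop("blink", None))
    sv = _merge_dataclass(SubjectVariabilitySpec, SubjectVariabilitySpec(),
                          sim.pop("subject_variability", None))
    simulation = SimulationConfig(
        conditions=conditions, sequence_design=design, noise=noise, blink=blink,
        subject_variability=sv,
        **{k: v for k, v in sim.items()},
    )
    simulation.validate()
    return RunConfig(
        simulation=simulation,
        preprocess=_merge_dataclass(PreprocessParams, PreprocessParams(),
                                    doc.get("preprocess")),
        classify=_merge_dataclass(ClassifyParams, ClassifyParams(), doc.get("classify")),
        stats=_merge_dataclass(StatsParams, StatsParams(), doc.get("stats")),
    )


def config_to_dict(cfg: RunConfig) -> dict:
    """JSON-serializable snapshot of a run configuration."""

    def enc(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, dict):
            return {k: enc(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [enc(v) for v in obj]
        return obj

    return enc(cfg)


def dump_config(cfg: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config_to_dict(cfg), sort_keys=False))
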