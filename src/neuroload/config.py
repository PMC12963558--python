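"""TOML pipeline configuration with strict key validation.

Every parameter has a documented default; unknown keys are rejected so a
typo cannot silently fall back to a default.  The seed is mandatory (via the
``seed`` key or a CLI flag) because every stage of the pipeline is seeded.
"""

from __future__ import annotations

import tomllib
from dataclasses import dataclass, field, fields
from pathlib import Path

from .synthetic import EffectSpec, StudyConfig


class ConfigError(ValueError):
    """Invalid or unknown configuration."""


@dataclass(frozen=True)
class PreprocessConfig:
    low: float = 2.0                 # band-pass low edge, Hz
    high: float = 30.0               # band-pass high edge, Hz
    order: int = 5                   # Butterworth order
    epoch_length: float = 1.0        # s
    threshold_uv: float = 80.0       # absolute amplitude rejection threshold
    blink_mode: str = "correct"      # "correct" | "reject"
    blink_threshold_uv: float = 40.0  # detection threshold on filtered AFz


@dataclass(frozen=True)
class NeurometricsConfig:
    gfp_mode: str = "subset-mean"    # | "spatial-variance"
    wl_aggregate: str = "ratio-of-means"   # | "mean-of-ratios"
    aw_scale: str = "power"          # | "log"
    wl_frontal: tuple = ("AFz", "AF3", "AF4", "AF7", "AF8")
    wl_parietal: tuple = ("Pz", "P3", "P4")
    aw_right: tuple = ("AF4", "AF8")
    aw_left: tuple = ("AF3", "AF7")
    iaf_search: tuple = (7.0, 13.0)  # Hz


@dataclass(frozen=True)
class QuestionnaireConfig:
    alpha: float = 0.001             # merge-screen significance threshold
    method: str = "mean"             # composite: "mean" | "sum" | "zmean"
    force_merge: bool = False        # build composites even if screen fails


@dataclass(frozen=True)
class StatsConfig:
    alpha: float = 0.05              # post-hoc trigger / Duncan level
    eta_convention: str = "partial"  # formatted-table eta column


@dataclass(frozen=True)
class PipelineConfig:
    seed: int
    output_dir: str = "neuroload_out"
    simulate: StudyConfig = field(default_factory=StudyConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    neurometrics: NeurometricsConfig = field(
        default_factory=NeurometricsConfig)
    questionnaire: QuestionnaireConfig = field(
        default_factory=QuestionnaireConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)


_EFFECT_KEYS = {"theta_gain", "alpha_gain", "asym_shift", "likert_shift",
                "item_loading", "default_loading", "item_noise_sd"}


def _build(cls, section: dict, name: str):
    known = {f.name for f in fields(cls)}
    unknown = set(section) - known
    if unknown:
        raise ConfigError(f"unknown key(s) in [{name}]: {sorted(unknown)}")
    kwargs = {}
    for f in fields(cls):
        if f.name in section:
            value = section[f.name]
            if isinstance(value, list):
                value = tuple(value)
            kwargs[f.name] = value
    return cls(**kwargs)


def _build_effects(section: dict) -> EffectSpec:
    unknown = set(section) - _EFFECT_KEYS
    if unknown:
        raise ConfigError(
            f"unknown key(s) in [simulate.effects]: {sorted(unknown)}")
    kwargs = dict(section)
    # TOML cannot express tuple keys: group-specific asymmetry shifts are
    # written as "group/condition" (e.g. "student/HM"); plain condition keys
    # pass through.  Likert shifts use "construct/group/condition".
    for name, depth in (("asym_shift", 2), ("likert_shift", 3)):
        if name in kwargs:
            parsed = {}
            for key, value in kwargs[name].items():
                parts = tuple(key.split("/"))
                parsed[parts if len(parts) == depth else key] = value
            kwargs[name] = parsed
    return EffectSpec(**kwargs)


def config_from_dict(data: dict, seed: int | None = None) -> PipelineConfig:
    """Build a validated PipelineConfig from a (TOML-shaped) dict.

    ``seed`` overrides any seed in the dict; one of the two must be given.
    """
    data = dict(data)
    top_known = {"seed", "output_dir", "simulate", "preprocess",
                 "neurometrics", "questionnaire", "stats"}
    unknown = set(data) - top_known
    if unknown:
        raise ConfigError(f"unknown top-level key(s): {sorted(unknown)}")
    if seed is None:
        seed = data.get("seed")
    if seed is None:
        raise ConfigError("a seed is required (config key 'seed' or CLI "
                          "--seed)")
    sim_section = dict(data.get("simulate", {}))
    effects = _build_effects(sim_section.pop("effects", {}))
    sim_section.pop("seed", None)
    sim = _build(StudyConfig, {**sim_section, "effects": effects,
                               "seed": int(seed)}, "simulate")
    return PipelineConfig(
        seed=int(seed),
        output_dir=data.get("output_dir", "neuroload_out"),
        simulate=sim,
        preprocess=_build(cls=PreprocessConfig,
                          section=data.get("preprocess", {}),
                          name="preprocess"),
        neurometrics=_build(NeurometricsConfig,
                            data.get("neurometrics", {}), "neurometrics"),
        questionnaire=_build(QuestionnaireConfig,
                             data.get("questionnaire", {}), "questionnaire"),
        stats=_build(StatsConfig, data.get("stats", {}), "stats"),
    )


def load_config(path, seed: int | None = None) -> PipelineConfig:
    """Load and validate a TOML pipeline configuration file."""
    with open(Path(path), "rb") as fh:
        data = tomllib.load(fh)
    return config_from_dict(data, seed=seed)
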