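"""Run configuration: nested blocks, YAML round-trip, validation, profiles."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace
from pathlib import Path

import yaml

from .model import ModelConfig, desk_config, paper_full_config
from .preprocess import PreprocessConfig
from .scalogram import ScalogramConfig, WaveletSpec
from .synth import NoiseConfig
from .train_eval import TrainConfig

__all__ = ["SimulateConfig", "RunConfig", "load_config", "dump_config",
           "validate_config", "ConfigError"]


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class SimulateConfig:
    n_identities: int = 8
    records_per_identity: int = 60
    duration_s: float = 5.0
    fs: float = 250.0
    spread: float = 1.0
    separated: bool = True
    noise: NoiseConfig = field(default_factory=NoiseConfig)


@dataclass(frozen=True)
class RunConfig:
    profile: str = "desk"
    seed: int = 0
    out_dir: str = "runs"
    simulate: SimulateConfig = field(default_factory=SimulateConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    scalogram: ScalogramConfig = field(default_factory=lambda: ScalogramConfig(
        n_freq_bins=64, freq_min_hz=0.5, freq_max_hz=25.0, image_side=64))
    wavelet: WaveletSpec = field(default_factory=WaveletSpec)
    model: ModelConfig = field(default_factory=ModelConfig)
    train: TrainConfig = field(default_factory=TrainConfig)


_PROFILE_FACTORIES = {"desk": desk_config, "paper-full": paper_full_config}


def _default_run_config(profile: str, seed: int = 0) -> RunConfig:
    if profile not in _PROFILE_FACTORIES:
        raise ConfigError(f"unknown profile '{profile}' (use desk or paper-full)")
    if profile == "paper-full":
        model = paper_full_config(seed=seed)
        scal = ScalogramConfig(n_freq_bins=128, freq_min_hz=0.5,
                               freq_max_hz=100.0, image_side=128)
        return RunConfig(profile=profile, seed=seed, model=model, scalogram=scal,
                         train=TrainConfig(max_epochs=100, early_stop_patience=50))
    return RunConfig(profile=profile, seed=seed,
                     model=desk_config(seed=seed))


def _build(cls, data: dict, path: str):
    fields = {f.name: f for f in dataclasses.fields(cls)}
    kwargs = {}
    for key, value in data.items():
        if key not in fields:
            raise ConfigError(f"unknown key '{path}{key}'")
        ftype = fields[key].type
        if isinstance(value, dict):
            sub = _NESTED.get((cls, key))
            if sub is None:
                raise ConfigError(f"'{path}{key}' does not take a mapping")
            kwargs[key] = _build(sub, value, f"{path}{key}.")
        else:
            if isinstance(value, list):
                value = tuple(value)
            kwargs[key] = value
    return kwargs  # merged later onto defaults


_NESTED = {
    (RunConfig, "simulate"): SimulateConfig,
    (RunConfig, "preprocess"): PreprocessConfig,
    (RunConfig, "scalogram"): ScalogramConfig,
    (RunConfig, "wavelet"): WaveletSpec,
    (RunConfig, "model"): ModelConfig,
    (RunConfig, "train"): TrainConfig,
    (SimulateConfig, "noise"): NoiseConfig,
}


def _merge(default, overrides: dict):
    direct, nested = {}, {}
    for k, v in overrides.items():
        if isinstance(v, dict):
            nested[k] = v
        else:
            direct[k] = tuple(v) if isinstance(v, list) else v
    out = replace(default, **direct) if direct else default
    for k, v in nested.items():
        sub_default = getattr(out, k)
        sub_cls = type(sub_default)
        sub_kwargs = _build(sub_cls, v, f"{k}.")
        out = replace(out, **{k: _merge(sub_default, {
            kk: vv for kk, vv in v.items()})})
    return out


def load_config(path=None, profile: str | None = None, seed: int | None = None) -> RunConfig:
    """Load a YAML config; missing file/empty file means full defaults.

    Unknown keys are rejected.  ``profile`` and ``seed`` arguments override
    the file's values.
    """
    data = {}
    if path is not None:
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
        if not isinstance(data, dict):
            raise ConfigError("config root must be a mapping")
    prof = profile or data.get("profile", "desk")
    sd = seed if seed is not None else int(data.get("seed", 0))
    cfg = _default_run_config(prof, sd)
    # validate keys at every level, then merge onto profile defaults
    _build(RunConfig, data, "")
    data.pop("profile", None)
    data.pop("seed", None)
    cfg = _merge(cfg, data)
    cfg = replace(cfg, profile=prof, seed=sd)
    # keep the model's own seed in sync with the run seed
    cfg = replace(cfg, model=replace(cfg.model, seed=sd),
                  train=replace(cfg.train, seed=sd))
    return cfg


def dump_config(cfg: RunConfig, path=None) -> str:
    text = yaml.safe_dump(dataclasses.asdict(cfg), sort_keys=True)
    if path is not None:
        Path(path).write_text(text)
    return text


def validate_config(cfg: RunConfig) -> list[str]:
    """Cross-field consistency checks; an empty list means runnable."""
    problems = []
    nyq = cfg.preprocess.target_fs / 2
    if cfg.scalogram.freq_max_hz > nyq:
        problems.append(
            f"scalogram.freq_max_hz={cfg.scalogram.freq_max_hz} exceeds the "
            f"target-rate Nyquist frequency {nyq}"
        )
    if cfg.model.image_side != cfg.scalogram.image_side:
        problems.append(
            f"model.image_side={cfg.model.image_side} differs from "
            f"scalogram.image_side={cfg.scalogram.image_side}"
        )
    if cfg.simulate.n_identities < 2:
        problems.append("simulate.n_identities must be >= 2")
    if cfg.model.n_classes != cfg.simulate.n_identities:
        problems.append(
            f"model.n_classes={cfg.model.n_classes} differs from "
            f"simulate.n_identities={cfg.simulate.n_identities}"
        )
    if cfg.simulate.fs < 2 * cfg.preprocess.band_high_hz:
        problems.append("simulate.fs below twice the band-pass upper edge")
    return problems
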