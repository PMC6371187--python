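"""YAML/JSON pipeline configuration with schema validation."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .spectral import DEFAULT_ARTIFACT_THRESHOLD, DEFAULT_WINDOW
from .synth import (
    EEGGenParams,
    StudyConfig,
    compact_montage,
    standard_montage,
)
from .tasks import Task

__all__ = ["PipelineConfig", "ConfigError", "load_config"]


class ConfigError(ValueError):
    """Configuration file failed validation; message names the keys."""


_KNOWN_KEYS = {
    "version", "seed", "cohort_dir", "outdir", "groups", "tasks", "montage",
    "r", "theta_band", "alpha_band", "filter_band", "window",
    "artifact_threshold", "alpha_level", "tar_method", "noise_amplitude",
    "artifact_prob", "sampling_rate",
}


@dataclass
class PipelineConfig:
    """Validated run configuration for all CLI commands."""

    cohort_dir: Path = Path("cohort")
    outdir: Path = Path("out")
    seed: int = 0
    groups: dict = field(default_factory=lambda: {"A": 6, "B": 6, "C": 6})
    tasks: tuple[Task, ...] = (Task.STROOP, Task.NEGATIVE_PRIMING, Task.FLANKER)
    montage: list[str] = field(default_factory=compact_montage)
    r: float = 0.7
    theta_band: tuple[float, float] = (4.0, 8.0)
    alpha_band: tuple[float, float] = (8.0, 12.0)
    filter_band: tuple[float, float] = (0.1, 30.0)
    window: tuple[float, float] = DEFAULT_WINDOW
    artifact_threshold: float = DEFAULT_ARTIFACT_THRESHOLD
    alpha_level: float = 0.05
    tar_method: str = "ratio_of_means"
    sampling_rate: float = 500.0
    noise_amplitude: float = 3.0
    artifact_prob: float = 0.05

    def study_config(self) -> StudyConfig:
        eeg = EEGGenParams(
            sampling_rate=self.sampling_rate,
            channel_labels=tuple(self.montage),
            noise_amplitude=self.noise_amplitude,
            artifact_prob=self.artifact_prob,
        )
        return StudyConfig(
            group_sizes=dict(self.groups),
            tasks=tuple(self.tasks),
            pre_post_r=self.r,
            eeg=eeg,
            master_seed=self.seed,
        )


def _require(cond: bool, key: str, message: str, errors: list[str]) -> None:
    if not cond:
        errors.append(f"{key}: {message}")


def load_config(path: str | Path | None = None, **overrides) -> PipelineConfig:
    """Load and validate a config file; ``overrides`` win over file values."""
    raw: dict = {}
    if path is not None:
        path = Path(path)
        if not path.exists():
            raise ConfigError(f"config file not found: {path}")
        loaded = yaml.safe_load(path.read_text())
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ConfigError(f"config root must be a mapping, got {type(loaded).__name__}")
        raw.update(loaded)
    raw.update({k: v for k, v in overrides.items() if v is not None})

    unknown = sorted(set(raw) - _KNOWN_KEYS)
    errors: list[str] = []
    if unknown:
        errors.append(f"unknown keys: {unknown}")

    cfg = PipelineConfig()
    if "seed" in raw:
        _require(isinstance(raw["seed"], int), "seed", "must be an integer", errors)
        cfg.seed = int(raw["seed"]) if isinstance(raw["seed"], int) else cfg.seed
    for key in ("cohort_dir", "outdir"):
        if key in raw:
            setattr(cfg, key, Path(raw[key]))
    if "groups" in raw:
        g = raw["groups"]
        ok = isinstance(g, dict) and set(g) <= {"A", "B", "C"} and all(
            isinstance(v, int) and v >= 2 for v in g.values()
        )
        _require(ok, "groups", "must map A/B/C to integer sizes >= 2", errors)
        if ok:
            cfg.groups = dict(g)
    if "tasks" in raw:
        try:
            cfg.tasks = tuple(Task(t) for t in raw["tasks"])
        except ValueError:
            errors.append(f"tasks: unknown task in {raw['tasks']}")
    if "montage" in raw:
        m = raw["montage"]
        if m == "compact":
            cfg.montage = compact_montage()
        elif m == "standard":
            cfg.montage = standard_montage()
        elif isinstance(m, list) and all(isinstance(x, str) for x in m):
            _require("Fz" in m and "Pz" in m, "montage", "must include Fz and Pz", errors)
            cfg.montage = list(m)
        else:
            errors.append("montage: must be 'compact', 'standard' or a label list")
    if "r" in raw:
        _require(
            isinstance(raw["r"], (int, float)) and -1 < raw["r"] < 1,
            "r", "must lie in (-1, 1)", errors,
        )
        if not errors or not errors[-1].startswith("r:"):
            cfg.r = float(raw["r"])
    for key in ("theta_band", "alpha_band", "filter_band", "window"):
        if key in raw:
            v = raw[key]
            ok = (
                isinstance(v, (list, tuple)) and len(v) == 2
                and all(isinstance(x, (int, float)) for x in v) and v[0] < v[1]
            )
            _require(ok, key, "must be [lo, hi] with lo < hi", errors)
            if ok:
                setattr(cfg, key, (float(v[0]), float(v[1])))
    for key, lo in (("artifact_threshold", 0.0), ("sampling_rate", 64.0),
                    ("noise_amplitude", -1e-12)):
        if key in raw:
            v = raw[key]
            ok = isinstance(v, (int, float)) and v > lo
            _require(ok, key, f"must be a number > {lo}", errors)
            if ok:
                setattr(cfg, key, float(v))
    if "artifact_prob" in raw:
        v = raw["artifact_prob"]
        ok = isinstance(v, (int, float)) and 0 <= v <= 1
        _require(ok, "artifact_prob", "must lie in [0, 1]", errors)
        if ok:
            cfg.artifact_prob = float(v)
    if "alpha_level" in raw:
        v = raw["alpha_level"]
        ok = isinstance(v, (int, float)) and 0 < v < 1
        _require(ok, "alpha_level", "must lie in (0, 1)", errors)
        if ok:
            cfg.alpha_level = float(v)
    if "tar_method" in raw:
        ok = raw["tar_method"] in ("ratio_of_means", "mean_of_ratios")
        _require(ok, "tar_method", "must be 'ratio_of_means' or 'mean_of_ratios'", errors)
        if ok:
            cfg.tar_method = raw["tar_method"]

    if errors:
        raise ConfigError("invalid configuration: " + "; ".join(errors))
    return cfg
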