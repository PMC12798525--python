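"""Pipeline configuration: defaults, YAML round-trip and provenance hashing.

All analysis defaults are the study-condition values: 10-s epochs with a
10 ms blink pad and a strict 50% missing-data exclusion, 0.1-30 Hz gaze
band-pass and 5 Hz pupil low-pass, FuzzyEn with m=2, n=2, r=0.2 over
scales 1-30 (features averaged over scales 1-10), 10 IAAFT surrogates of
100 iterations, BH-FDR at q < 0.05 and q < 0.01, and a nested LOOCV with
inner stratified 5-fold tuning of the lasso penalty.
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .classification import CvConfig
from .preprocessing import PreprocessingConfig
from .synthetic import CohortConfig, SimulationParams

__all__ = ["EntropyConfig", "SurrogateConfig", "StatsConfig", "PipelineConfig"]


@dataclass(frozen=True)
class EntropyConfig:
    m: int = 2
    n: float = 2.0
    r: float = 0.2
    n_scales: int = 30
    feature_scale_min: int = 1
    feature_scale_max: int = 10

    @property
    def scales(self) -> tuple[int, ...]:
        return tuple(range(1, self.n_scales + 1))

    @property
    def feature_scales(self) -> tuple[int, ...]:
        return tuple(range(self.feature_scale_min, self.feature_scale_max + 1))


@dataclass(frozen=True)
class SurrogateConfig:
    count: int = 10
    iterations: int = 100


@dataclass(frozen=True)
class StatsConfig:
    q_levels: tuple[float, float] = (0.05, 0.01)
    alpha: float = 0.05


@dataclass
class PipelineConfig:
    recordings_dir: str = "recordings"
    manifest_path: str = "manifest.csv"
    output_dir: str = "output"
    preprocessing: PreprocessingConfig = field(default_factory=PreprocessingConfig)
    entropy: EntropyConfig = field(default_factory=EntropyConfig)
    surrogates: SurrogateConfig = field(default_factory=SurrogateConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)
    cv: CvConfig = field(default_factory=CvConfig)
    simulation: CohortConfig = field(default_factory=CohortConfig)
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path: str | Path | None = None) -> str:
        text = yaml.safe_dump(_plain(self.to_dict()), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source: str | Path) -> "PipelineConfig":
        if isinstance(source, Path) or (isinstance(source, str) and "\n" not in source and Path(source).exists()):
            text = Path(source).read_text()
        else:
            text = str(source)
        raw = yaml.safe_load(text) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        kwargs = dict(raw)
        if "preprocessing" in kwargs:
            pre = dict(kwargs["preprocessing"])
            if "eye_band_hz" in pre:
                pre["eye_band_hz"] = tuple(pre["eye_band_hz"])
            kwargs["preprocessing"] = PreprocessingConfig(**pre)
        if "entropy" in kwargs:
            kwargs["entropy"] = EntropyConfig(**kwargs["entropy"])
        if "surrogates" in kwargs:
            kwargs["surrogates"] = SurrogateConfig(**kwargs["surrogates"])
        if "stats" in kwargs:
            st = dict(kwargs["stats"])
            if "q_levels" in st:
                st["q_levels"] = tuple(st["q_levels"])
            kwargs["stats"] = StatsConfig(**st)
        if "cv" in kwargs:
            cv = dict(kwargs["cv"])
            if "lambda_grid" in cv:
                cv["lambda_grid"] = tuple(cv["lambda_grid"])
            kwargs["cv"] = CvConfig(**cv)
        if "simulation" in kwargs:
            sim = dict(kwargs["simulation"])
            if "group_params" in sim:
                sim["group_params"] = {
                    grp: SimulationParams(**_tupled(params, ("blink_dur_range",)))
                    for grp, params in sim["group_params"].items()
                }
            kwargs["simulation"] = CohortConfig(**sim)
        return cls(**kwargs)

    def with_seed(self, seed: int) -> "PipelineConfig":
        """Copy of this config with the master seed pushed into every stage
        that consumes randomness (simulation and cross-validation)."""
        return dataclasses.replace(
            self,
            seed=seed,
            simulation=dataclasses.replace(self.simulation, seed=seed),
            cv=dataclasses.replace(self.cv, seed=seed),
        )

    @property
    def config_hash(self) -> str:
        """Hash of the analysis parameters (filesystem paths excluded, so the
        same analysis written to a different location hashes identically)."""
        payload = {
            k: v for k, v in self.to_dict().items()
            if k not in ("recordings_dir", "manifest_path", "output_dir")
        }
        text = yaml.safe_dump(_plain(payload), sort_keys=True)
        return hashlib.sha256(text.encode()).hexdigest()[:12]

    def provenance(self) -> dict:
        return {"config_hash": self.config_hash, "seed": self.seed}


def _tupled(mapping: dict, keys: tuple[str, ...]) -> dict:
    out = dict(mapping)
    for key in keys:
        if key in out and isinstance(out[key], list):
            out[key] = tuple(out[key])
    return out


def _plain(obj):
    """Recursively convert tuples/numpy scalars so YAML round-trips cleanly."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if hasattr(obj, "item") and callable(obj.item):
        return obj.item()
    return obj
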