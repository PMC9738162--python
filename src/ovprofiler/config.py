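"""Run configuration: one structured block per pipeline stage, YAML
round-trippable, unknown keys rejected."""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, asdict

import yaml

from .simulate import SimConfig, ImmuneModel, SurvivalModel, HRDSignature

__all__ = ["RunConfig", "ProfileParams", "ClassifierParams", "SegmentationParams",
           "TMEParams"]

CONFIG_VERSION = "1"


@dataclass
class ProfileParams:
    qc_mapd: float = 0.6
    lowess_span: float = 0.3
    aggregate_size: int = 1_000_000


@dataclass
class ClassifierParams:
    n_train: int = 200
    delta: float | None = None        # None -> cross-validated choice
    delta_grid: list = field(default_factory=lambda: [0.0, 0.5, 1.0, 1.5, 2.0, 3.0, 4.0])
    folds: int = 5


@dataclass
class SegmentationParams:
    alpha: float = 0.01
    n_perm: int = 200       # cohort-scale default; the API default is 1000
    min_width: int = 2
    smooth_mapd: float = 0.45
    merge_threshold: float = 0.1


@dataclass
class TMEParams:
    mode: str = "fixed"     # fixed | quartile


def _build(cls, data, path="config"):
    if not isinstance(data, dict):
        raise ValueError(f"{path}: expected a mapping")
    names = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(names)
    if unknown:
        raise ValueError(f"{path}: unknown keys {sorted(unknown)}")
    kwargs = {}
    for key, value in data.items():
        ftype = names[key].type
        nested = _NESTED.get((cls, key))
        if nested is not None and isinstance(value, dict):
            kwargs[key] = _build(nested, value, f"{path}.{key}")
        else:
            kwargs[key] = _coerce(key, value)
    return cls(**kwargs)


def _coerce(key, value):
    if key in ("genome",) and isinstance(value, list):
        return [tuple(v) for v in value]
    if key in ("ccne1_locus", "profile_proportions", "n_segments",
               "segment_length", "copies", "amplicon_length") and isinstance(value, list):
        return tuple(value)
    return value


_NESTED = {
    (SimConfig, "immune_model"): ImmuneModel,
    (SimConfig, "survival_model"): SurvivalModel,
    (SimConfig, "hrd_signature"): HRDSignature,
}


@dataclass
class RunConfig:
    version: str = CONFIG_VERSION
    seed: int = 0
    simulation: SimConfig = field(default_factory=SimConfig)
    profile: ProfileParams = field(default_factory=ProfileParams)
    classifier: ClassifierParams = field(default_factory=ClassifierParams)
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    tme: TMEParams = field(default_factory=TMEParams)

    def __post_init__(self):
        # a single seed drives every stage; keep the simulator in sync
        self.simulation.seed = self.seed

    def to_dict(self) -> dict:
        def clean(obj):
            if isinstance(obj, dict):
                return {k: clean(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [clean(v) for v in obj]
            return obj

        return clean(asdict(self))

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        if not isinstance(data, dict):
            raise ValueError("config must be a mapping")
        names = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - names
        if unknown:
            raise ValueError(f"config: unknown keys {sorted(unknown)}")
        kwargs = {}
        for key, value in data.items():
            sub = {
                "simulation": SimConfig,
                "profile": ProfileParams,
                "classifier": ClassifierParams,
                "segmentation": SegmentationParams,
                "tme": TMEParams,
            }.get(key)
            kwargs[key] = _build(sub, value, f"config.{key}") if sub and isinstance(value, dict) else value
        return cls(**kwargs)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))
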