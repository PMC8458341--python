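"""Run configuration: one YAML-serialisable object covering every stage,
with a single top-level seed fanned out deterministically per stage."""

from __future__ import annotations

import dataclasses
import hashlib

import numpy as np
import yaml

__all__ = ["RunConfig", "stage_seeds", "config_hash"]

STAGES = ("simulate", "extract", "metrics", "series", "braess")


@dataclasses.dataclass
class SimulateConfig:
    n_seed_points: int = 14
    width: int = 256
    height: int = 256
    tube_width: float = 5.0
    noise_sd: float = 0.05
    hole_rate: float = 1.0       # holes per 1000 tube pixels
    speckle_count: int = 6
    n_frames: int = 25
    frame_interval_h: float = 2.0
    merge_fraction_per_frame: float = 0.05
    n_replicates: int = 1
    min_separation: float = 30.0


@dataclasses.dataclass
class ExtractConfig:
    threshold_method: str = "otsu"
    fixed_threshold: float | None = None
    clip_percentiles: tuple[float, float] = (0.0, 100.0)
    max_hole_area: float = 64.0
    min_object_area: float = 64.0
    spur_factor: float = 1.5
    pixel_size_um: float | None = None


@dataclasses.dataclass
class MetricsConfig:
    n_random: int = 20


@dataclasses.dataclass
class SeriesConfig:
    bin_width: float = 20.0
    max_length: float = 300.0
    make_plots: bool = True


@dataclasses.dataclass
class BraessConfig:
    demand: float = 4000.0
    with_bypass: bool = True


_SECTIONS = {
    "simulate": SimulateConfig,
    "extract": ExtractConfig,
    "metrics": MetricsConfig,
    "series": SeriesConfig,
    "braess": BraessConfig,
}


@dataclasses.dataclass
class RunConfig:
    seed: int = 0
    out_dir: str = "vascnet_out"
    log_level: str = "INFO"
    simulate: SimulateConfig = dataclasses.field(default_factory=SimulateConfig)
    extract: ExtractConfig = dataclasses.field(default_factory=ExtractConfig)
    metrics: MetricsConfig = dataclasses.field(default_factory=MetricsConfig)
    series: SeriesConfig = dataclasses.field(default_factory=SeriesConfig)
    braess: BraessConfig = dataclasses.field(default_factory=BraessConfig)

    # ------------------------------------------------------------------ YAML
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["extract"]["clip_percentiles"] = list(d["extract"]["clip_percentiles"])
        return d

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data or {})
        top_fields = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - top_fields
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs = {}
        for name, section_cls in _SECTIONS.items():
            section = data.pop(name, {}) or {}
            fields = {f.name for f in dataclasses.fields(section_cls)}
            bad = set(section) - fields
            if bad:
                raise ValueError(f"unknown keys in '{name}': {sorted(bad)}")
            kwargs[name] = section_cls(**section)
        kwargs["extract"].clip_percentiles = tuple(kwargs["extract"].clip_percentiles)
        kwargs.update(data)
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def stage_seeds(seed: int) -> dict[str, int]:
    """Derive one reproducible sub-seed per stage from the top-level seed."""
    state = np.random.SeedSequence(int(seed)).generate_state(len(STAGES))
    return {name: int(s % (2 ** 31)) for name, s in zip(STAGES, state)}


def config_hash(cfg: RunConfig) -> str:
    blob = yaml.safe_dump(cfg.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]
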