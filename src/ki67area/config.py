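"""Run configuration: a strict YAML schema for end-to-end pipeline runs."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

from .segmentation import SegmentationConfig
from .synth import ROISpec, SizeDistribution

__all__ = ["RunConfig", "ConfigError"]


class ConfigError(ValueError):
    """Unknown or invalid configuration keys."""


def _from_mapping(cls, data: dict, where: str):
    known = {f.name for f in fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown keys in {where}: {sorted(unknown)}")
    return cls(**data)


@dataclass
class RunConfig:
    """Everything a full generate->segment->calibrate->evaluate run needs.

    ``n_nuclei`` is the tumor-nucleus count per ROI; ``nontumor_frac_range``
    draws, per ROI, the non-tumor nucleus count as a uniform fraction of
    that, which is what makes the whole-image index degrade relative to
    the within-tumor index.
    """

    out_dir: str = "ki67_run"
    seed: int = 11
    n_rois: int = 75
    index_range: tuple[float, float] = (0.0, 80.0)
    width: int = 575
    height: int = 300
    n_nuclei: int = 100
    nontumor_frac_range: tuple[float, float] | None = (0.1, 0.6)
    noise_sd: float = 4.0
    stain_intensity_jitter: float = 0.15
    nucleus_mean_axis: float = 14.0
    nucleus_sd_axis: float = 3.0
    positive_size_scale: float = 1.0
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    models: dict = field(default_factory=lambda: {"A_within": 1, "A_whole": 3})
    log_level: str = "INFO"

    def roi_template(self) -> ROISpec:
        n_pos = self.n_nuclei // 2
        return ROISpec(
            n_positive=n_pos,
            n_negative=self.n_nuclei - n_pos,
            width=self.width,
            height=self.height,
            noise_sd=self.noise_sd,
            stain_intensity_jitter=self.stain_intensity_jitter,
            size_distribution=SizeDistribution(
                mean=self.nucleus_mean_axis, sd=self.nucleus_sd_axis
            ),
            positive_size_scale=self.positive_size_scale,
        )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["index_range"] = list(self.index_range)
        if self.nontumor_frac_range is not None:
            d["nontumor_frac_range"] = list(self.nontumor_frac_range)
        return d

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        seg = data.pop("segmentation", {})
        cfg = _from_mapping(cls, data, "run config")
        if isinstance(seg, dict):
            cfg.segmentation = _from_mapping(SegmentationConfig, seg, "segmentation")
        if data.get("index_range") is not None:
            cfg.index_range = tuple(cfg.index_range)
        if cfg.nontumor_frac_range is not None:
            cfg.nontumor_frac_range = tuple(cfg.nontumor_frac_range)
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(data, dict):
            raise ConfigError("config file must hold a mapping")
        return cls.from_dict(data)
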