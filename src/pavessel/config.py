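"""Run configuration: YAML round-trip of every pipeline knob."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .phantom import PhantomSpec, DrugEffectSpec
from .segmentation import SegmentationParams
from .projection import ROISpec

__all__ = ["RunConfig", "EFFECT_PRESETS"]

# Named drug-response presets accepted in configs; resolved in pavessel.phantom.
EFFECT_PRESETS = ("carfilzomib_like", "bortezomib_like", "null")

_MODES = ("simulate", "quantify", "report", "end_to_end")
_NORMALIZATIONS = ("none", "per_image", "shared")


@dataclass
class RunConfig:
    """Declarative description of one pipeline run.

    normalization: "none" keeps stored intensities (images written by the
    simulator share one absolute scale); "shared" rescales every timepoint
    by the control image's range; "per_image" min-max normalizes each frame
    independently (this erases longitudinal intensity changes and is not the
    default for PA-signal comparisons).
    """

    mode: str = "end_to_end"
    out_dir: str = "runs/run"
    seed: int = 0
    manifest: str | None = None
    metrics_csv: str | None = None
    group: str = "carfilzomib_like"
    n_timepoints: int = 10
    normalization: str = "shared"
    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    effect: DrugEffectSpec | None = None
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    rois: list[ROISpec] = field(default_factory=list)

    def validate(self) -> None:
        if self.mode not in _MODES:
            raise ValueError(f"mode must be one of {_MODES}, got {self.mode!r}")
        if self.normalization not in _NORMALIZATIONS:
            raise ValueError(f"normalization must be one of {_NORMALIZATIONS}")
        if self.mode in ("quantify",) and not self.manifest:
            raise ValueError("quantify mode requires a manifest")
        if self.mode == "report" and not self.metrics_csv:
            raise ValueError("report mode requires metrics_csv")
        self.phantom.validate()
        if self.effect is not None:
            self.effect.validate()
        self.segmentation.validate()

    def to_dict(self) -> dict:
        d = {
            "mode": self.mode,
            "out_dir": self.out_dir,
            "seed": self.seed,
            "manifest": self.manifest,
            "metrics_csv": self.metrics_csv,
            "group": self.group,
            "n_timepoints": self.n_timepoints,
            "normalization": self.normalization,
            "phantom": {**asdict(self.phantom), "image_size": list(self.phantom.image_size)},
            "effect": None if self.effect is None else {
                **asdict(self.effect),
                "effect_curve": list(self.effect.effect_curve),
            },
            "segmentation": self.segmentation.to_dict(),
            "rois": [asdict(r) for r in self.rois],
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "phantom" in d and isinstance(d["phantom"], dict):
            p = dict(d["phantom"])
            if "image_size" in p:
                p["image_size"] = tuple(p["image_size"])
            d["phantom"] = PhantomSpec(**p)
        if d.get("effect") is not None and isinstance(d["effect"], dict):
            e = dict(d["effect"])
            if "effect_curve" in e:
                e["effect_curve"] = tuple(e["effect_curve"])
            d["effect"] = DrugEffectSpec(**e)
        if "segmentation" in d and isinstance(d["segmentation"], dict):
            d["segmentation"] = SegmentationParams.from_dict(d["segmentation"])
        if "rois" in d:
            d["rois"] = [ROISpec(**r) for r in d["rois"]]
        cfg = cls(**d)
        cfg.validate()
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))
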