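"""Run configuration: a schema-validated YAML/JSON document.

Unknown keys are rejected before any computation so that a typo in a
parameter name cannot silently fall back to a default mid-run.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .pipeline import PipelineParams
from .segmentation import CellFilterParams


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class ThresholdConfig(_Strict):
    mode: str = "auto"                       # auto | manual
    manual_values: dict[int, dict[str, int]] = Field(default_factory=dict)
    n_transitions: int = 2
    smooth_window: int = 5

    @model_validator(mode="after")
    def _check_mode(self):
        if self.mode not in ("auto", "manual"):
            raise ValueError(f"threshold.mode must be auto|manual, got {self.mode}")
        return self


class SegmentationConfig(_Strict):
    median_window: int = 3
    connectivity: int = 8
    min_area_um2: float = 64.0
    max_area_um2: float = 6400.0
    min_roundness: float = 0.4


class AlignmentConfig(_Strict):
    search_radius: int = 10
    level: int = 0
    boundary_sigma: float = 2.0
    validate_thicknesses: list[int] = Field(default_factory=lambda: [0, 1, 2, 4])


class QuantConfig(_Strict):
    bin_um: float = 100.0
    n_bins: int = 20
    injection_organ: str | None = None
    injection_layer: str | None = None
    compartments: list[str] = Field(default_factory=list)   # [region_a, region_b]


class InputConfig(_Strict):
    preset: str | None = None                # synthetic fixture name
    section_paths: list[str] = Field(default_factory=list)
    label_mask_paths: list[str] = Field(default_factory=list)
    region_names: dict[int, str] = Field(default_factory=dict)
    pixel_size: float = 4.0
    thickness: float = 100.0

    @model_validator(mode="after")
    def _check_source(self):
        if self.preset is None and not self.section_paths:
            raise ValueError("input needs either a preset or section_paths")
        return self


class RunConfig(_Strict):
    input: InputConfig
    outdir: str = "mct_run"
    seed: int = 0
    log_level: str = "INFO"
    threshold: ThresholdConfig = Field(default_factory=ThresholdConfig)
    segmentation: SegmentationConfig = Field(default_factory=SegmentationConfig)
    alignment: AlignmentConfig = Field(default_factory=AlignmentConfig)
    quant: QuantConfig = Field(default_factory=QuantConfig)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.model_validate(data)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.model_dump(), sort_keys=False))

    def pipeline_params(self) -> PipelineParams:
        manual_tissue = {int(k): v["tissue"]
                         for k, v in self.threshold.manual_values.items()
                         if "tissue" in v}
        manual_cell = {int(k): v["cell"]
                       for k, v in self.threshold.manual_values.items()
                       if "cell" in v}
        return PipelineParams(
            cell_filter=CellFilterParams(
                min_area_um2=self.segmentation.min_area_um2,
                max_area_um2=self.segmentation.max_area_um2,
                min_roundness=self.segmentation.min_roundness,
                median_window=self.segmentation.median_window,
                connectivity=self.segmentation.connectivity,
            ),
            threshold_mode=self.threshold.mode,
            manual_tissue=manual_tissue,
            manual_cell=manual_cell,
            n_transitions=self.threshold.n_transitions,
            smooth_window=self.threshold.smooth_window,
            boundary_sigma=self.alignment.boundary_sigma,
            align_radius=self.alignment.search_radius,
            align_level=self.alignment.level,
        )
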