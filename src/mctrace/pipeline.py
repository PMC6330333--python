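"""End-to-end orchestration: sections in, reports out.

The stages mirror the analysis flow for a whole-brain retrograde-tracing
experiment: median filter and MCT curve per section; tissue and cell
thresholds from the curve's derivative transitions (or manual overrides);
soma detection; tissue-silhouette boundary tracing and Gaussian smoothing;
rigid section alignment; physical reconstruction; and the region-level
quantification reports.  Each stage is an ordinary function over in-memory
objects so the library, the CLI, and the test fixtures all drive the same
code path.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import alignment as al
from . import mct, quant, segmentation as seg
from .raster_io import SectionImage, build_pyramid
from .synthetic import GroundTruth, SyntheticBrainSpec, generate


@dataclass
class PipelineParams:
    """Everything tunable between raw sections and reports."""

    cell_filter: seg.CellFilterParams = field(default_factory=seg.CellFilterParams)
    threshold_mode: str = "auto"                     # auto | manual
    manual_tissue: dict[int, int] = field(default_factory=dict)
    manual_cell: dict[int, int] = field(default_factory=dict)
    n_transitions: int = 2
    smooth_window: int = 5
    boundary_sigma: float = 2.0
    align_radius: int = 10
    align_level: int = 0        # pyramid level the alignment search runs at


@dataclass
class SectionResult:
    """Per-section intermediate products."""

    rc_index: int
    curve: mct.CorrelationCurve | None
    selection: mct.ThresholdSelection | None
    cells: list
    boundary: seg.TissueBoundary | None
    smoothed_boundary: np.ndarray | None
    flagged: bool = False


@dataclass
class PipelineResult:
    sections: list[SectionImage]
    per_section: list[SectionResult]
    transforms: list[al.SectionTransform]
    reconstruction: quant.BrainReconstruction
    alignment_report: al.AlignmentReport | None = None
    truth: GroundTruth | None = None

    @property
    def cells(self):
        return self.reconstruction.cells

    def auto_counts(self) -> np.ndarray:
        return np.array([len(s.cells) for s in self.per_section])


def analyze_section(
    section: SectionImage, params: PipelineParams
) -> SectionResult:
    """Threshold, segment and outline one section."""
    filtered = seg.median_filter(section.pixels, params.cell_filter.median_window)
    try:
        curve = mct.correlation_curve(filtered, section.bit_depth,
                                      rc_index=section.rc_index)
    except mct.DegenerateImageError:
        return SectionResult(section.rc_index, None, None, [], None, None,
                             flagged=True)
    selection = mct.transition_thresholds(
        curve, n_transitions=params.n_transitions,
        smooth_window=params.smooth_window,
    )
    tissue_thr = params.manual_tissue.get(section.rc_index,
                                          selection.tissue_threshold)
    cell_thr = params.manual_cell.get(section.rc_index,
                                      selection.cell_threshold)
    if params.threshold_mode == "manual":
        if section.rc_index not in params.manual_cell:
            raise ValueError(
                f"manual threshold mode but no cell threshold for section "
                f"{section.rc_index}"
            )

    cells = []
    if cell_thr is not None:
        cells = seg.find_cells(section, int(cell_thr),
                               params=params.cell_filter)

    boundary = None
    smoothed = None
    if tissue_thr is not None:
        tissue_mask = mct.threshold_image(filtered, int(tissue_thr),
                                          section.max_gray)
        contours = seg.trace_boundary(tissue_mask, rc_index=section.rc_index)
        if contours:
            boundary = max(contours, key=len)       # tissue silhouette
            smoothed = seg.smooth_boundary(boundary, params.boundary_sigma,
                                           section.shape)
    return SectionResult(
        rc_index=section.rc_index, curve=curve, selection=selection,
        cells=cells, boundary=boundary, smoothed_boundary=smoothed,
        flagged=cell_thr is None and tissue_thr is None,
    )


def _boundary_at_level(raster: np.ndarray | None, section: SectionImage,
                       level: int) -> np.ndarray | None:
    if raster is None or level == 0:
        return raster
    pyr = build_pyramid(
        SectionImage(raster * 255.0, bit_depth=section.bit_depth,
                     pixel_size=section.pixel_size,
                     thickness=section.thickness,
                     rc_index=section.rc_index),
        level,
    )
    return pyr.levels[min(level, pyr.max_level)]


def run_pipeline(
    sections: list[SectionImage],
    region_labels: list[np.ndarray] | None = None,
    region_table: quant.RegionTable | None = None,
    params: PipelineParams | None = None,
    align: bool = True,
    validate_thicknesses: list[int] | None = None,
) -> PipelineResult:
    """Full run over an ordered section stack."""
    params = params or PipelineParams()
    per_section = [analyze_section(s, params) for s in sections]

    if align and len(sections) >= 2:
        rasters = [
            _boundary_at_level(r.smoothed_boundary, s, params.align_level)
            for r, s in zip(per_section, sections)
        ]
        transforms = al.align_stack(rasters, search_radius=params.align_radius)
        if params.align_level > 0:
            scale = 2 ** params.align_level
            transforms = [
                al.SectionTransform(t.rc_index,
                                    (t.shift[0] * scale, t.shift[1] * scale),
                                    t.score, t.flagged)
                for t in transforms
            ]
    else:
        transforms = [al.SectionTransform(i, (0, 0), 1.0)
                      for i in range(len(sections))]

    report = None
    if validate_thicknesses:
        aligned = al.apply_transforms(
            [r.smoothed_boundary for r in per_section],
            transforms,
        )
        usable = [a for a in aligned if a is not None]
        if len(usable) >= 2:
            report = al.validate_alignment(usable, validate_thicknesses)

    all_cells = [c for r in per_section for c in r.cells]
    recon = quant.build_reconstruction(
        sections=sections, transforms=transforms,
        boundaries=[r.boundary for r in per_section],
        cells=all_cells, region_labels=region_labels,
        region_table=region_table,
    )
    return PipelineResult(
        sections=sections, per_section=per_section, transforms=transforms,
        reconstruction=recon, alignment_report=report,
    )


def run_synthetic(
    spec: SyntheticBrainSpec,
    params: PipelineParams | None = None,
    align: bool = True,
    validate_thicknesses: list[int] | None = None,
) -> PipelineResult:
    """Generate a synthetic brain and push it through the full pipeline."""
    sections, masks, truth = generate(spec)
    result = run_pipeline(
        sections, region_labels=masks, region_table=spec.region_table(),
        params=params, align=align, validate_thicknesses=validate_thicknesses,
    )
    result.truth = truth
    return result


def true_counts_by_section(truth: GroundTruth, n_sections: int) -> np.ndarray:
    by_rc = truth.counts_by_section()
    return np.array([by_rc.get(rc, 0) for rc in range(n_sections)])
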