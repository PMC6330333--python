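"""3D reconstruction and region-level quantification of labeled neurons.

Aligned sections, their tissue boundaries, and the detected cells assemble
into a physical reconstruction: each cell's pixel centroid is mapped through
its section's rigid transform and scaled to micrometers, with the
rostro-caudal coordinate given by section index times section thickness.
Anatomy enters through per-section integer label masks plus a name table
(label -> region name, with ``is_olfactory_cortex`` and ``hemisphere`` flags),
standing in for manual region drawing / atlas registration.

Axis semantics, used by every report: dorsal-ventral = image row axis,
medial-lateral = image column axis, rostral-caudal = section index.

The reports mirror a retrograde-tracing analysis: injection-site precision
(fraction of bulb cells inside the granule cell layer), per-axis position
histograms, projected density maps, brain-wide per-region percentages, and
two-compartment ratios such as the main vs. accessory olfactory bulb split.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .alignment import SectionTransform
from .raster_io import SectionImage
from .segmentation import DetectedCell, TissueBoundary


@dataclass
class RegionTable:
    """Name table for integer label masks.

    names maps label -> region name (label 0 is reserved for unassigned);
    flags carries per-region booleans/strings, e.g. is_olfactory_cortex,
    hemisphere.
    """

    names: dict[int, str]
    flags: dict[str, dict] = field(default_factory=dict)

    def label_of(self, name: str) -> int:
        for lab, nm in self.names.items():
            if nm == name:
                return lab
        raise KeyError(f"unknown region name: {name}")

    def is_olfactory(self, name: str) -> bool:
        return bool(self.flags.get(name, {}).get("is_olfactory_cortex", False))


@dataclass
class BrainReconstruction:
    """Aligned section stack with cells in physical coordinates."""

    sections: list[SectionImage]
    transforms: list[SectionTransform]
    boundaries: list[TissueBoundary | None]
    cells: pd.DataFrame          # one row per cell, micrometer coordinates
    region_labels: list[np.ndarray] | None = None
    region_table: RegionTable | None = None

    @property
    def pixel_size(self) -> float:
        return self.sections[0].pixel_size

    @property
    def thickness(self) -> float:
        return self.sections[0].thickness


@dataclass
class InjectionSiteReport:
    center_of_mass: tuple[float, float, float]   # (x, y, z) um
    n_inside: int
    n_outside: int
    empty: bool = False

    @property
    def fraction_inside(self) -> float:
        total = self.n_inside + self.n_outside
        return self.n_inside / total if total else float("nan")


@dataclass
class DistributionReport:
    counts: dict[str, int]          # per-region cell counts (assigned only)
    percentages: dict[str, float]   # per-region share of assigned cells, 0-100
    n_assigned: int
    n_unassigned: int

    def group_percentage(self, names) -> float:
        return float(sum(self.percentages.get(n, 0.0) for n in names))


class StructuralError(ValueError):
    """Raised when reconstruction inputs are mutually inconsistent."""


def build_reconstruction(
    sections: list[SectionImage],
    transforms: list[SectionTransform],
    boundaries: list[TissueBoundary | None],
    cells: list[DetectedCell],
    region_labels: list[np.ndarray] | None = None,
    region_table: RegionTable | None = None,
) -> BrainReconstruction:
    """Assemble the physical reconstruction.

    Cell pixel centroids are mapped through their section's transform, then
    scaled to micrometers (x = col * pixel_size, y = row * pixel_size,
    z = rc_index * thickness).  Cells falling outside their section's tissue
    boundary raster are flagged (column ``inside_tissue``), never dropped.
    Raises StructuralError if a cell-bearing section has no transform.
    """
    by_rc = {t.rc_index: t for t in transforms}
    rows = []
    for cell in cells:
        if cell.rc_index not in by_rc:
            raise StructuralError(
                f"section {cell.rc_index} has cells but no transform"
            )
        t = by_rc[cell.rc_index]
        sec = sections[cell.rc_index]
        r_al = cell.centroid_px[0] + t.shift[0]
        c_al = cell.centroid_px[1] + t.shift[1]
        inside = True
        b = boundaries[cell.rc_index] if boundaries else None
        if b is not None and len(b.contour) >= 3:
            from matplotlib.path import Path

            inside = bool(
                Path(b.contour).contains_point(cell.centroid_px, radius=1.0)
            )
        rows.append(
            {
                "rc_index": cell.rc_index,
                "row": cell.centroid_px[0],
                "col": cell.centroid_px[1],
                "x_um": c_al * sec.pixel_size,
                "y_um": r_al * sec.pixel_size,
                "z_um": cell.rc_index * sec.thickness,
                "area_px": cell.area_px,
                "roundness": cell.roundness,
                "mean_intensity": cell.mean_intensity,
                "inside_tissue": inside,
            }
        )
    frame = pd.DataFrame(
        rows,
        columns=["rc_index", "row", "col", "x_um", "y_um", "z_um",
                 "area_px", "roundness", "mean_intensity", "inside_tissue"],
    )
    return BrainReconstruction(
        sections=sections, transforms=transforms, boundaries=boundaries,
        cells=frame, region_labels=region_labels, region_table=region_table,
    )


def _assigned_labels(recon: BrainReconstruction) -> np.ndarray:
    """Region label under each cell's centroid pixel, in the section's native
    frame (masks and cells live in the same frame, so the rigid transform
    cancels).  Cells on label 0 are unassigned."""
    if recon.region_labels is None:
        raise StructuralError("reconstruction carries no region label masks")
    labels = np.zeros(len(recon.cells), dtype=int)
    cell_rcs = recon.cells["rc_index"].to_numpy()
    for rc in np.unique(cell_rcs):
        mask = recon.region_labels[int(rc)]
        if mask is None:
            raise StructuralError(f"section {rc} has cells but no label mask")
        sel = cell_rcs == rc
        rr = np.clip(np.rint(recon.cells.loc[sel, "row"]).astype(int),
                     0, mask.shape[0] - 1)
        cc = np.clip(np.rint(recon.cells.loc[sel, "col"]).astype(int),
                     0, mask.shape[1] - 1)
        labels[sel] = mask[rr, cc]
    return labels


def region_assignment(recon: BrainReconstruction) -> DistributionReport:
    """Assign each cell the region label under its centroid and tabulate.

    Cells on label 0 are reported separately as unassigned; percentages are
    over assigned cells and sum to 100.
    """
    labels = _assigned_labels(recon)
    table = recon.region_table or RegionTable(names={})
    recon.cells["region"] = [table.names.get(int(l), None) if l else None
                             for l in labels]
    assigned = labels[labels > 0]
    n_assigned = int(len(assigned))
    counts: dict[str, int] = {}
    for lab, nm in table.names.items():
        counts[nm] = int((assigned == lab).sum())
    pct = {nm: (100.0 * c / n_assigned if n_assigned else 0.0)
           for nm, c in counts.items()}
    return DistributionReport(
        counts=counts, percentages=pct,
        n_assigned=n_assigned, n_unassigned=int((labels == 0).sum()),
    )


def injection_site_report(
    recon: BrainReconstruction, organ_region: str, layer_region: str
) -> InjectionSiteReport:
    """Injection precision: cells inside the target layer vs elsewhere in the
    organ.

    The organ's cells are those assigned either the layer label or the
    organ's outside-the-layer label (the layer is nested inside the organ).
    The center of mass is the arithmetic mean of (x, y, z) over all organ
    cells.
    """
    if recon.region_table is None:
        raise StructuralError("injection report needs a region table")
    organ_lab = recon.region_table.label_of(organ_region)
    layer_lab = recon.region_table.label_of(layer_region)
    labels = _assigned_labels(recon)
    in_layer = labels == layer_lab
    in_organ = in_layer | (labels == organ_lab)
    if not in_organ.any():
        return InjectionSiteReport((float("nan"),) * 3, 0, 0, empty=True)
    pts = recon.cells.loc[in_organ, ["x_um", "y_um", "z_um"]].to_numpy()
    com = tuple(float(v) for v in pts.mean(axis=0))
    return InjectionSiteReport(
        center_of_mass=com,
        n_inside=int(in_layer.sum()),
        n_outside=int((in_organ & ~in_layer).sum()),
    )


_AXIS_COLUMN = {"ML": "x_um", "DV": "y_um", "RC": "z_um"}


def axis_distribution(
    recon: BrainReconstruction, region: str | None, axis: str, n_bins: int = 20
) -> tuple[np.ndarray, np.ndarray]:
    """Normalized histogram of cell positions along one anatomical axis.

    axis: 'ML' (medial-lateral, image columns), 'DV' (dorsal-ventral, image
    rows) or 'RC' (rostral-caudal, section index).  Restricted to cells
    assigned to ``region`` when given.  Returns (fractions, bin_edges);
    fractions sum to 1.  Zero cells -> empty arrays.
    """
    if axis not in _AXIS_COLUMN:
        raise ValueError(f"axis must be one of {sorted(_AXIS_COLUMN)}")
    cells = recon.cells
    if region is not None:
        if "region" not in cells.columns:
            region_assignment(recon)
            cells = recon.cells
        cells = cells[cells["region"] == region]
    vals = cells[_AXIS_COLUMN[axis]].to_numpy()
    if len(vals) == 0:
        return np.array([]), np.array([])
    counts, edges = np.histogram(vals, bins=n_bins)
    return counts / counts.sum(), edges


_PLANE_AXES = {
    # (vertical, horizontal) columns for each projection plane
    "sagittal": ("y_um", "z_um"),     # DV vs RC (ML projected out)
    "coronal": ("y_um", "x_um"),      # DV vs ML (RC projected out)
    "horizontal": ("z_um", "x_um"),   # RC vs ML (DV projected out)
}


def density_map(
    recon: BrainReconstruction,
    plane: str = "sagittal",
    bin_um: float = 100.0,
    normalize_to: tuple[float, float, float] | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """2D binned cell counts after projecting out one axis.

    ``normalize_to`` (e.g. the injection-site center of mass) is subtracted
    from all coordinates before binning.  Returns (counts, v_edges, h_edges);
    total counts equal total cells.
    """
    if bin_um <= 0:
        raise ValueError("bin_um must be > 0")
    if plane not in _PLANE_AXES:
        raise ValueError(f"plane must be one of {sorted(_PLANE_AXES)}")
    vcol, hcol = _PLANE_AXES[plane]
    pts = recon.cells[["x_um", "y_um", "z_um"]].to_numpy(dtype=float)
    if normalize_to is not None:
        pts = pts - np.asarray(normalize_to, dtype=float)
    col_idx = {"x_um": 0, "y_um": 1, "z_um": 2}
    v = pts[:, col_idx[vcol]]
    h = pts[:, col_idx[hcol]]
    if len(v) == 0:
        return np.zeros((1, 1)), np.array([0, bin_um]), np.array([0, bin_um])

    def edges(x):
        lo = np.floor(x.min() / bin_um) * bin_um
        hi = np.ceil(x.max() / bin_um) * bin_um
        if hi <= lo:
            hi = lo + bin_um
        return np.arange(lo, hi + bin_um / 2, bin_um)

    ve, he = edges(v), edges(h)
    counts, _, _ = np.histogram2d(v, h, bins=(ve, he))
    return counts, ve, he


def compartment_ratio(
    recon: BrainReconstruction, region_a: str, region_b: str
) -> dict:
    """Two-compartment split (e.g. main vs accessory olfactory bulb).

    Returns counts for each compartment and region_a's share of (a + b) as a
    fraction in [0, 1]; the share is NaN (flagged undefined) when both counts
    are zero.
    """
    if recon.region_table is None:
        raise StructuralError("compartment ratio needs a region table")
    lab_a = recon.region_table.label_of(region_a)
    lab_b = recon.region_table.label_of(region_b)
    labels = _assigned_labels(recon)
    n_a = int((labels == lab_a).sum())
    n_b = int((labels == lab_b).sum())
    share = n_a / (n_a + n_b) if (n_a + n_b) else float("nan")
    return {"count_a": n_a, "count_b": n_b, "share_a": share,
            "undefined": (n_a + n_b) == 0}
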