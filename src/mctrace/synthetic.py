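"""Synthetic whole-brain section stacks with complete ground truth.

The generator emulates the statistical structure the pipeline assumes so that
every stage can be tested against known truth with no data download:

* two intensity populations per section — dim tissue autofluorescence and
  bright labeled somata — over a dark (zero) off-section background;
* shot noise as isolated saturated pixels;
* a smooth multiplicative rostral-to-caudal decline in tissue and soma
  fluorescence;
* dense, deliberately overlapping somata at an injection site (blobs placed
  within touching distance merge after thresholding, the mechanism behind
  undercounting at high label density) and sparse distal cells distributed
  across named regions with configurable proportions;
* nested non-spherical layer geometries (a granule-cell-layer ring inside an
  elliptical bulb) and integer per-section misalignments.

Tissue is an ellipse per section (axes may vary smoothly along the
rostro-caudal axis).  Regions are defined in the ellipse's normalized
coordinates by radial and angular extents, so ring-in-shell and wedge
partitions are exact and label masks never overlap.  Somata render as
flat-core Gaussian-edged blobs composited by per-pixel maximum, so touching
blobs merge exactly as clumped cells do in real sections.

Everything is deterministic given the spec's seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .quant import RegionTable
from .raster_io import SectionImage


class CapacityError(ValueError):
    """Requested cell count exceeds what a region can hold."""


@dataclass
class RegionSpec:
    """One labeled region in normalized ellipse coordinates.

    radial: (rho_lo, rho_hi) with rho = 1 on the tissue edge.
    wedge: (theta_lo, theta_hi) in degrees, measured in normalized
    coordinates (0 = +column axis, counterclockwise), or None for all angles.
    sections: explicit rc indices the region spans, or None for all.
    n_cells: total ground-truth cells to place in the region.
    cells_by_section: optional explicit per-section counts overriding n_cells.
    overlap_fraction: fraction of the region's cells placed within touching
    distance of an already-placed cell, guaranteeing merged blobs.
    placement_inset: radial margin kept between placed cells and the region's
    radial bounds (normalized units), so detected centroids stay in-region.
    """

    name: str
    label: int
    radial: tuple[float, float] = (0.0, 1.0)
    wedge: tuple[float, float] | None = None
    sections: list[int] | None = None
    n_cells: int = 0
    cells_by_section: dict[int, int] | None = None
    overlap_fraction: float = 0.0
    is_olfactory_cortex: bool = False
    hemisphere: str | None = None
    placement_inset: float = 0.0
    # minimum center-to-center spacing between seed cells (px); 0 = none,
    # so dense sections show natural chance overlaps
    min_spacing_px: float = 0.0


@dataclass
class IntensityModel:
    """Two-population intensity model plus soma rendering parameters."""

    background_mean: float = 0.0
    background_sd: float = 0.0
    tissue_mean: float = 50.0
    tissue_sd: float = 5.0
    soma_mean: float = 200.0
    soma_sd: float = 10.0
    soma_radius_px: float = 1.3     # flat core radius
    soma_edge_sd: float = 0.5       # Gaussian fall-off beyond the core
    rc_decay: float = 0.0           # per-section multiplicative decay rate


@dataclass
class SyntheticBrainSpec:
    """Full generative configuration; the seed fixes every random draw."""

    n_sections: int = 10
    section_shape: tuple[int, int] = (512, 512)
    pixel_size: float = 4.0
    thickness: float = 100.0
    bit_depth: int = 8
    regions: list[RegionSpec] = field(default_factory=list)
    intensity: IntensityModel = field(default_factory=IntensityModel)
    shot_noise_rate: float = 1e-4
    # semi-axes (rows, cols) at the rostral end and per-section increments
    axes: tuple[float, float] = (170.0, 130.0)
    axes_slope: tuple[float, float] = (0.0, 0.0)
    shifts: list[tuple[int, int]] | None = None
    # optional per-section overlap fraction overriding every region's own
    # (used by the density sweep, where overlap rises with label density)
    overlap_by_section: dict[int, float] | None = None
    seed: int = 0

    def region_table(self) -> RegionTable:
        names = {r.label: r.name for r in self.regions}
        flags = {
            r.name: {
                "is_olfactory_cortex": r.is_olfactory_cortex,
                "hemisphere": r.hemisphere,
            }
            for r in self.regions
        }
        return RegionTable(names=names, flags=flags)


@dataclass
class GroundTruth:
    """Everything the generator knows: the answer key for the pipeline."""

    cells: pd.DataFrame                      # rc_index, row, col, label, region
    region_masks: list[np.ndarray]
    shifts: list[tuple[int, int]]
    section_mean_intensity: list[float]
    counts_by_region: dict[str, int]
    spec: SyntheticBrainSpec

    def counts_by_section(self) -> dict[int, int]:
        return self.cells.groupby("rc_index").size().to_dict()


def _normalized_coords(shape, center, axes):
    rr, cc = np.mgrid[0:shape[0], 0:shape[1]]
    u = (rr - center[0]) / axes[0]
    v = (cc - center[1]) / axes[1]
    rho = np.sqrt(u * u + v * v)
    theta = np.degrees(np.arctan2(-u, v)) % 360.0   # 0 = +col, CCW, row-up
    return rho, theta


def _in_wedge(theta: np.ndarray, wedge) -> np.ndarray:
    lo, hi = wedge[0] % 360.0, wedge[1] % 360.0
    if lo <= hi:
        return (theta >= lo) & (theta < hi)
    return (theta >= lo) | (theta < hi)


def _section_axes(spec: SyntheticBrainSpec, rc: int) -> tuple[float, float]:
    return (spec.axes[0] + spec.axes_slope[0] * rc,
            spec.axes[1] + spec.axes_slope[1] * rc)


def build_masks(spec: SyntheticBrainSpec, rc: int):
    """Tissue mask and integer label mask for one (unshifted) section."""
    shape = spec.section_shape
    center = ((shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0)
    axes = _section_axes(spec, rc)
    rho, theta = _normalized_coords(shape, center, axes)
    tissue = rho <= 1.0
    labels = np.zeros(shape, dtype=np.int16)
    for reg in spec.regions:
        if reg.sections is not None and rc not in reg.sections:
            continue
        sel = tissue & (rho >= reg.radial[0]) & (rho < reg.radial[1])
        if reg.wedge is not None:
            sel &= _in_wedge(theta, reg.wedge)
        labels[sel & (labels == 0)] = reg.label
    return tissue, labels, rho, theta, center, axes


def _placement_candidates(reg: RegionSpec, rho, theta, tissue,
                          edge_margin: float = 0.07, core_margin: float = 0.10):
    lo = max(reg.radial[0] + reg.placement_inset, core_margin)
    hi = min(reg.radial[1] - reg.placement_inset, 1.0 - edge_margin)
    sel = tissue & (rho >= lo) & (rho < hi)
    if reg.wedge is not None:
        sel &= _in_wedge(theta, reg.wedge)
    return np.column_stack(np.nonzero(sel))


def _split_counts(total: int, weights: np.ndarray, rng) -> np.ndarray:
    w = np.asarray(weights, dtype=float)
    if w.sum() == 0:
        raise CapacityError("region has no capacity in its sections")
    return rng.multinomial(total, w / w.sum())


def generate(spec: SyntheticBrainSpec):
    """Render the stack.

    Returns ``(sections, region_masks, truth)``: a list of SectionImage, the
    per-section integer label masks (in the same, possibly shifted, frame as
    the images), and the GroundTruth bookkeeping.
    """
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    shape = spec.section_shape
    max_gray = (1 << spec.bit_depth) - 1
    shifts = list(spec.shifts) if spec.shifts is not None else \
        [(0, 0)] * spec.n_sections
    if len(shifts) != spec.n_sections:
        raise ValueError("shifts must list one (d_row, d_col) per section")

    # Decide per-region, per-section cell counts.  Geometry is recomputed per
    # section rather than held for the whole stack (memory stays flat in
    # stack length).
    cap_cache: dict[int, tuple] = {}

    def geometry(rc: int):
        if rc not in cap_cache:
            cap_cache[rc] = build_masks(spec, rc)
            if len(cap_cache) > 4:
                cap_cache.pop(next(iter(cap_cache)))
        return cap_cache[rc]

    plan: dict[tuple[int, int], int] = {}   # (rc, label) -> count
    for reg in spec.regions:
        secs = reg.sections if reg.sections is not None \
            else list(range(spec.n_sections))
        if reg.cells_by_section is not None:
            for rc, cnt in reg.cells_by_section.items():
                plan[(rc, reg.label)] = cnt
            continue
        if reg.n_cells == 0:
            continue
        caps = []
        for rc in secs:
            tis, _lab, rho, theta, _c, _a = geometry(rc)
            caps.append(len(_placement_candidates(reg, rho, theta, tis)))
        caps = np.array(caps)
        counts = _split_counts(reg.n_cells, caps, rng)
        for rc, cnt in zip(secs, counts):
            if cnt:
                plan[(rc, reg.label)] = int(cnt)

    by_label = {r.label: r for r in spec.regions}
    touch = 2.0 * spec.intensity.soma_radius_px + 1.0   # merge-guarantee offset

    sections: list[SectionImage] = []
    masks_out: list[np.ndarray] = []
    truth_rows = []
    mean_intensity = []

    for rc in range(spec.n_sections):
        tissue, labels, rho, theta, center, axes = build_masks(spec, rc)
        decay = math.exp(-spec.intensity.rc_decay * rc)
        im = spec.intensity

        img = np.zeros(shape, dtype=float)
        if im.background_mean > 0 or im.background_sd > 0:
            img += np.clip(rng.normal(im.background_mean, max(im.background_sd, 1e-12),
                                      shape), 0, None)
        tissue_vals = np.clip(
            rng.normal(im.tissue_mean * decay, im.tissue_sd, int(tissue.sum())),
            0, None)
        img[tissue] = np.maximum(img[tissue], tissue_vals)

        # Place and stamp somata.
        r_patch = int(math.ceil(im.soma_radius_px + 4 * im.soma_edge_sd))
        yy, xx = np.mgrid[-r_patch:r_patch + 1, -r_patch:r_patch + 1]
        for (rc_k, label), count in sorted(plan.items()):
            if rc_k != rc or count == 0:
                continue
            reg = by_label[label]
            cand = _placement_candidates(reg, rho, theta, tissue)
            if count > max(1, len(cand) // 3):
                raise CapacityError(
                    f"{reg.name}: {count} cells exceed capacity "
                    f"({len(cand)} candidate pixels) in section {rc}"
                )
            ovl = reg.overlap_fraction
            if spec.overlap_by_section is not None:
                ovl = spec.overlap_by_section.get(rc, ovl)
            n_touch = min(int(round(ovl * count)), count - 1)
            n_seed = count - n_touch
            if reg.min_spacing_px > 0:
                centers = _spaced_sample(cand, n_seed, reg.min_spacing_px, rng)
            else:
                idx = rng.choice(len(cand), size=n_seed, replace=False)
                centers = cand[idx].astype(float)
            centers = centers + rng.uniform(-0.5, 0.5, (len(centers), 2))
            extra = []
            for _ in range(n_touch):
                anchor = centers[rng.integers(0, len(centers))]
                ang = rng.uniform(0, 2 * np.pi)
                d = rng.uniform(0.4, 0.9) * touch
                extra.append(anchor + d * np.array([np.sin(ang), np.cos(ang)]))
            if extra:
                centers = np.vstack([centers, np.array(extra)])
            peaks = np.clip(rng.normal(im.soma_mean * decay, im.soma_sd,
                                       len(centers)), 1, max_gray)
            for (r0, c0), pk in zip(centers, peaks):
                ri, ci = int(round(r0)), int(round(c0))
                dr, dc = r0 - ri, c0 - ci
                d = np.sqrt((yy - dr) ** 2 + (xx - dc) ** 2)
                prof = np.where(
                    d <= im.soma_radius_px, 1.0,
                    np.exp(-0.5 * ((d - im.soma_radius_px) / im.soma_edge_sd) ** 2),
                )
                rs, re = max(0, ri - r_patch), min(shape[0], ri + r_patch + 1)
                cs, ce = max(0, ci - r_patch), min(shape[1], ci + r_patch + 1)
                pr = prof[rs - (ri - r_patch):re - (ri - r_patch),
                          cs - (ci - r_patch):ce - (ci - r_patch)]
                np.maximum(img[rs:re, cs:ce], pk * pr, out=img[rs:re, cs:ce])
                truth_rows.append(
                    {"rc_index": rc, "row": r0, "col": c0,
                     "label": label, "region": reg.name}
                )

        # Shot noise: isolated saturated pixels.
        if spec.shot_noise_rate > 0:
            n_hot = rng.binomial(img.size, spec.shot_noise_rate)
            if n_hot:
                flat = rng.choice(img.size, size=n_hot, replace=False)
                img.ravel()[flat] = max_gray

        # Inject per-section misalignment: shift image, mask, and truth alike.
        d_r, d_c = shifts[rc]
        if (d_r, d_c) != (0, 0):
            img = _int_shift(img, d_r, d_c)
            labels = _int_shift(labels, d_r, d_c)
            for row in truth_rows:
                if row["rc_index"] == rc:
                    row["row"] += d_r
                    row["col"] += d_c

        img = np.clip(np.rint(img), 0, max_gray).astype(
            np.uint8 if spec.bit_depth == 8 else np.uint16)
        sections.append(
            SectionImage(img, bit_depth=spec.bit_depth, pixel_size=spec.pixel_size,
                         thickness=spec.thickness, rc_index=rc)
        )
        masks_out.append(labels)
        mean_intensity.append(float(img.mean()))

    cells = pd.DataFrame(truth_rows,
                         columns=["rc_index", "row", "col", "label", "region"])
    counts = cells.groupby("region").size().to_dict() if len(cells) else {}
    truth = GroundTruth(
        cells=cells, region_masks=masks_out, shifts=shifts,
        section_mean_intensity=mean_intensity,
        counts_by_region={r.name: int(counts.get(r.name, 0)) for r in spec.regions},
        spec=spec,
    )
    return sections, masks_out, truth


def _spaced_sample(cand: np.ndarray, n: int, spacing: float, rng) -> np.ndarray:
    """Sequential rejection sampling with a minimum pairwise distance."""
    chosen: list[np.ndarray] = []
    order = rng.permutation(len(cand))
    s2 = spacing * spacing
    for k in order:
        p = cand[k].astype(float)
        if all(((p - q) ** 2).sum() >= s2 for q in chosen):
            chosen.append(p)
            if len(chosen) == n:
                return np.array(chosen)
    raise CapacityError(
        f"cannot place {n} cells with {spacing:.1f} px spacing "
        f"({len(chosen)} fit)"
    )


def _int_shift(img: np.ndarray, dr: int, dc: int) -> np.ndarray:
    out = np.zeros_like(img)
    h, w = img.shape
    rs, re = max(dr, 0), min(h, h + dr)
    cs, ce = max(dc, 0), min(w, w + dc)
    out[rs:re, cs:ce] = img[rs - dr:re - dr, cs - dc:ce - dc]
    return out


# ---------------------------------------------------------------------------
# Packaged fixtures
# ---------------------------------------------------------------------------

#: Brain-wide distribution of retrogradely labeled cells used by the
#: fig5_distribution fixture, in percent.  The ten named entries are kept
#: verbatim from the source accounting even though they total 96.93; the
#: remainder is carried by an explicit "Unattributed" label (flagged
#: non-olfactory) so proportions sum to 1.  See docs/methods.md.
FIG5_PROPORTIONS: dict[str, tuple[float, bool, str | None]] = {
    # name: (percent, is_olfactory_cortex, hemisphere)
    "AON_ipsi": (58.0, True, "ipsi"),
    "AON_contra": (5.0, True, "contra"),
    "Pir_nLOT": (27.9, True, "ipsi"),
    "HDB": (3.5, False, "ipsi"),
    "Amygdala": (1.4, False, "ipsi"),
    "ZI": (0.001, False, "ipsi"),
    "PirEnt_transition": (0.001, False, "ipsi"),
    "Hypothalamus": (0.08, False, "ipsi"),
    "EC": (0.3, False, "ipsi"),
    "CA1": (0.75, False, "ipsi"),
}
FIG5_PROPORTIONS["Unattributed"] = (
    100.0 - sum(v[0] for v in FIG5_PROPORTIONS.values()), False, None,
)

#: Per-replicate in-layer proportions for the nine-injection suite
#: (mean exactly 0.80, spread matching the reported 80 +/- 19%).
FIG4_REPLICATE_PROPORTIONS = (0.84, 0.99, 0.93, 0.55, 0.62, 0.71, 0.95, 0.86, 0.75)

#: Share of injection-site cells placed in the main (vs accessory) olfactory
#: bulb granule layer by the fig6_injection fixture.
FIG6_MOB_SHARE = 0.993


def _gcl_in_bulb_regions(in_frac: float, n_cells: int, overlap: float = 0.05):
    n_in = int(round(in_frac * n_cells))
    return [
        RegionSpec(name="GCL", label=2, radial=(0.30, 0.78), n_cells=n_in,
                   overlap_fraction=overlap, placement_inset=0.03,
                   is_olfactory_cortex=True, hemisphere="ipsi"),
        RegionSpec(name="MOB", label=1, radial=(0.0, 0.30), n_cells=n_cells - n_in,
                   overlap_fraction=overlap, placement_inset=0.03,
                   is_olfactory_cortex=True, hemisphere="ipsi"),
        RegionSpec(name="MOB_outer", label=3, radial=(0.78, 1.0), n_cells=0,
                   is_olfactory_cortex=True, hemisphere="ipsi"),
    ]


def fig4_spec(in_frac: float = 0.84, n_cells: int = 1500, seed: int = 7
              ) -> SyntheticBrainSpec:
    """Single-experiment injection-site fixture: granule-cell-layer ring
    nested in an elliptical bulb, ``in_frac`` of the cells inside the ring,
    the rest in the bulb core (the out-of-layer compartment)."""
    return SyntheticBrainSpec(
        n_sections=20, section_shape=(512, 512), axes=(170.0, 130.0),
        regions=_gcl_in_bulb_regions(in_frac, n_cells), seed=seed,
    )


def _fig5_spec(n_cells: int, seed: int) -> SyntheticBrainSpec:
    # Wedge widths proportional to region share: equal expected cell density
    # everywhere, so density-dependent merge losses cancel in percentages.
    regions = []
    start = 0.0
    for lab, (name, (pct, olf, hemi)) in enumerate(FIG5_PROPORTIONS.items(), 1):
        width = 360.0 * pct / 100.0
        regions.append(
            RegionSpec(name=name, label=lab, wedge=(start, start + width),
                       n_cells=0, is_olfactory_cortex=olf, hemisphere=hemi)
        )
        start += width
    spec = SyntheticBrainSpec(
        n_sections=16, section_shape=(512, 512), axes=(180.0, 140.0),
        regions=regions, seed=seed,
    )
    # One multinomial draw fixes per-region totals; bookkeeping is exact.
    rng = np.random.default_rng(np.random.SeedSequence([seed, 5]))
    probs = np.array([v[0] for v in FIG5_PROPORTIONS.values()]) / 100.0
    draws = rng.multinomial(n_cells, probs)
    for reg, n in zip(spec.regions, draws):
        reg.n_cells = int(n)
    return spec


def preset(name: str, seed: int | None = None, n_cells: int | None = None
           ) -> SyntheticBrainSpec:
    """Packaged fixture specs.

    Names: fig2_gradient, fig3_density_sweep, fig4_example, fig5_distribution,
    fig6_injection, alignment_shifts.  ``seed``/``n_cells`` override the
    packaged defaults without changing the fixture's study conditions.
    """
    if name == "fig2_gradient":
        spec = SyntheticBrainSpec(
            n_sections=10, section_shape=(256, 256), axes=(90.0, 70.0),
            regions=[RegionSpec(name="tissue", label=1, n_cells=250)],
            intensity=IntensityModel(rc_decay=0.04),
            seed=21 if seed is None else seed,
        )
    elif name == "fig3_density_sweep":
        counts = np.rint(np.geomspace(10, 2000, 100)).astype(int)
        spec = SyntheticBrainSpec(
            n_sections=100, section_shape=(512, 512), axes=(235.0, 185.0),
            regions=[RegionSpec(
                name="tissue", label=1,
                cells_by_section={rc: int(c) for rc, c in enumerate(counts)},
            )],
            intensity=IntensityModel(rc_decay=0.005),
            # Overlap fraction rises with density: the injection-site regime.
            overlap_by_section={rc: 0.25 * c / counts.max()
                                for rc, c in enumerate(counts)},
            seed=42 if seed is None else seed,
        )
    elif name == "fig4_example":
        spec = fig4_spec(seed=7 if seed is None else seed,
                         n_cells=n_cells or 1500)
    elif name == "fig5_distribution":
        spec = _fig5_spec(n_cells or 5000, 11 if seed is None else seed)
    elif name == "fig6_injection":
        n = n_cells or 3000
        n_mob = int(round(FIG6_MOB_SHARE * n))
        spec = SyntheticBrainSpec(
            n_sections=26, section_shape=(512, 512), axes=(170.0, 130.0),
            regions=[
                RegionSpec(name="MOB_GCL", label=1, radial=(0.0, 0.80),
                           sections=list(range(0, 24)), n_cells=n_mob,
                           overlap_fraction=0.05, placement_inset=0.02,
                           is_olfactory_cortex=True, hemisphere="ipsi"),
                RegionSpec(name="AOB_GCL", label=2, radial=(0.0, 0.80),
                           sections=[24, 25], n_cells=n - n_mob,
                           placement_inset=0.02,
                           is_olfactory_cortex=True, hemisphere="ipsi"),
            ],
            seed=5 if seed is None else seed,
        )
    elif name == "alignment_shifts":
        shifts = [(0, 0), (3, -2), (-4, 5), (6, 1), (-2, -7),
                  (5, 4), (-3, 2), (1, -6)]
        spec = SyntheticBrainSpec(
            n_sections=8, section_shape=(256, 256), axes=(72.0, 56.0),
            axes_slope=(1.5, 1.2),
            regions=[RegionSpec(name="tissue", label=1, n_cells=80)],
            shifts=shifts,
            seed=3 if seed is None else seed,
        )
    else:
        raise KeyError(f"unknown preset: {name}")
    return spec


def fig4_replicate(k: int) -> SyntheticBrainSpec:
    """k-th (0-based) replicate of the nine-injection suite, seeds 1-9."""
    return fig4_spec(in_frac=FIG4_REPLICATE_PROPORTIONS[k], seed=k + 1)
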