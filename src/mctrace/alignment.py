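"""Serial-section alignment and its validation.

Sections are registered by rigid integer translation only: each section's
Gaussian-smoothed tissue-boundary raster is shifted over a square search
window and the shift maximizing Pearson correlation with the previous aligned
section is kept; transforms compose cumulatively down the stack with section 0
fixed.  Alignment quality is validated by dilating each aligned boundary with
a disc of increasing radius (the "edge thickness" tolerance) and reporting the
full pairwise correlation matrix: a tight reconstruction shows high
correlation between adjacent sections that falls off with rostro-caudal
distance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage


@dataclass
class SectionTransform:
    """Integer translation applied to one section, with its match score."""

    rc_index: int
    shift: tuple[int, int]        # (d_row, d_col)
    score: float                  # boundary correlation vs previous section
    flagged: bool = False         # True when the section had no usable boundary


@dataclass
class AlignmentReport:
    """Pairwise boundary correlations for each tested edge thickness."""

    thicknesses: list[int]
    corr_matrices: list[np.ndarray]   # one symmetric matrix per thickness


def _shift_raster(img: np.ndarray, dr: int, dc: int) -> np.ndarray:
    """Integer shift with zero fill (content moves by (dr, dc))."""
    out = np.zeros_like(img)
    h, w = img.shape
    rs, re = max(dr, 0), min(h, h + dr)
    cs, ce = max(dc, 0), min(w, w + dc)
    out[rs:re, cs:ce] = img[rs - dr:re - dr, cs - dc:ce - dc]
    return out


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a.ravel().astype(float)
    b = b.ravel().astype(float)
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a * a).sum() * (b * b).sum())
    if denom == 0:
        return 0.0
    return float((a * b).sum() / denom)


def _best_shift(
    ref: np.ndarray, mov: np.ndarray, radius: int
) -> tuple[tuple[int, int], float]:
    best = (0, 0)
    best_score = -np.inf
    for dr in range(-radius, radius + 1):
        for dc in range(-radius, radius + 1):
            score = _pearson(ref, _shift_raster(mov, dr, dc))
            # Deterministic tie-break: smaller shift magnitude, then row/col order.
            if score > best_score + 1e-12 or (
                abs(score - best_score) <= 1e-12
                and (abs(dr) + abs(dc)) < (abs(best[0]) + abs(best[1]))
            ):
                best_score = score
                best = (dr, dc)
    return best, float(best_score)


def align_stack(
    boundaries: list[np.ndarray | None], search_radius: int = 50
) -> list[SectionTransform]:
    """Chain-align smoothed boundary rasters by exhaustive translation search.

    Section 0 is fixed.  Each subsequent section receives the integer
    translation (within ``search_radius``) maximizing Pearson correlation
    between its boundary raster and the previous *aligned* section's;
    transforms compose cumulatively.  A section with no boundary (None or
    empty raster) inherits the previous transform and is flagged.
    """
    if len(boundaries) < 2:
        raise ValueError("need at least 2 sections to align")
    transforms = [SectionTransform(rc_index=0, shift=(0, 0), score=1.0)]
    prev_aligned = None
    for b in boundaries:
        if b is not None and np.asarray(b).any():
            prev_aligned = np.asarray(b, dtype=float)
            break
    for idx in range(1, len(boundaries)):
        raster = boundaries[idx]
        prev_shift = transforms[-1].shift
        if raster is None or not np.asarray(raster).any() or prev_aligned is None:
            transforms.append(
                SectionTransform(rc_index=idx, shift=prev_shift, score=float("nan"),
                                 flagged=True)
            )
            continue
        raster = np.asarray(raster, dtype=float)
        # The search runs against the already-aligned previous section, so
        # (dr, dc) is the absolute shift into the fixed frame.
        (dr, dc), score = _best_shift(prev_aligned, raster, search_radius)
        aligned = _shift_raster(raster, dr, dc)
        transforms.append(SectionTransform(rc_index=idx, shift=(dr, dc), score=score))
        prev_aligned = aligned
    return transforms


def apply_transforms(
    boundaries: list[np.ndarray | None], transforms: list[SectionTransform]
) -> list[np.ndarray | None]:
    """Shift each boundary raster by its transform into the common frame."""
    out = []
    for b, t in zip(boundaries, transforms):
        if b is None:
            out.append(None)
        else:
            out.append(_shift_raster(np.asarray(b, dtype=float), *t.shift))
    return out


def validate_alignment(
    aligned_boundaries: list[np.ndarray], thicknesses: list[int]
) -> AlignmentReport:
    """Pairwise boundary correlation at each edge-thickness tolerance.

    Each aligned boundary raster is dilated by a disc of radius t and all
    pairwise Pearson correlations are reported as one matrix per thickness
    (symmetric, unit diagonal).
    """
    if len(aligned_boundaries) < 2:
        raise ValueError("need at least 2 sections to validate")
    rasters = [np.asarray(b) > 0 for b in aligned_boundaries]
    matrices = []
    for t in thicknesses:
        if t > 0:
            yy, xx = np.mgrid[-t:t + 1, -t:t + 1]
            disc = (yy * yy + xx * xx) <= t * t
            dil = [ndimage.binary_dilation(r, structure=disc).astype(float)
                   for r in rasters]
        else:
            dil = [r.astype(float) for r in rasters]
        n = len(dil)
        mat = np.eye(n)
        for i in range(n):
            for k in range(i + 1, n):
                mat[i, k] = mat[k, i] = _pearson(dil[i], dil[k])
        matrices.append(mat)
    return AlignmentReport(thicknesses=list(thicknesses), corr_matrices=matrices)


def adjacent_vs_lag(report: AlignmentReport, lag: int = 5) -> list[tuple[float, float]]:
    """Mean adjacent-pair correlation vs mean correlation at the given lag,
    one pair of values per thickness — the fall-off summary used to judge
    reconstruction tightness."""
    out = []
    for mat in report.corr_matrices:
        n = len(mat)
        adj = np.mean([mat[i, i + 1] for i in range(n - 1)])
        far = (np.mean([mat[i, i + lag] for i in range(n - lag)])
               if n > lag else float("nan"))
        out.append((float(adj), float(far)))
    return out
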