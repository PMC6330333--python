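"""Maximum correlation thresholding (MCT).

For a grayscale image ``x`` and a candidate threshold ``i`` define the binary
indicator ``y(i)`` with ``y_n = 1`` iff ``x_n > i`` (strict).  The MCT curve is
the Pearson correlation ``corr(x, y(i))`` evaluated at every gray level.  With
``n_j`` the histogram count at gray value ``j``, ``x̄`` the image mean, ``N_m``
the pixel total and ``N_i`` the number of pixels above ``i``, the correlation
has the closed form

    corr(x, y(i)) = sum_{j>i} n_j (j - x̄)
                    / ( sqrt(sum_j n_j (j - x̄)^2) * sqrt(N_i (N_m - N_i) / N_m) )

The optimal threshold is the argmax of the curve.  The curve's first
finite-difference derivative shows sharp excursions wherever the threshold
sweeps through an intensity population; the gray values at which those
excursions *begin* (their left bases) separate background from tissue and
tissue from labeled somata, and are the thresholds used downstream for tissue
silhouettes and cell detection.  Both transitions can also be supplied
manually, mirroring how an experimenter would pick them off the curve.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from .raster_io import SectionImage


class DegenerateImageError(ValueError):
    """Raised when an image has no intensity variance to threshold."""


@dataclass
class GrayHistogram:
    """Gray-level histogram with the moments the MCT closed form needs."""

    counts: np.ndarray          # n_j for j = 0 .. 2^bit_depth - 1
    mean_intensity: float       # x̄
    total_pixels: int           # N_m

    @classmethod
    def from_image(cls, image: np.ndarray, bit_depth: int = 8) -> "GrayHistogram":
        flat = np.asarray(image).ravel()
        n_gray = 1 << bit_depth
        counts = np.bincount(np.rint(flat).astype(np.int64), minlength=n_gray)
        if len(counts) > n_gray:
            raise ValueError("image values exceed the stated bit depth")
        return cls(counts=counts, mean_intensity=float(flat.mean()),
                   total_pixels=int(flat.size))


@dataclass
class BinaryMask:
    """Indicator image y(i): 1 exactly where the source pixel exceeds i."""

    pixels: np.ndarray
    threshold: int


@dataclass
class CorrelationCurve:
    """corr(x, y(i)) per gray level, its derivative, and the above-counts N_i.

    ``defined`` flags thresholds where the correlation exists (0 < N_i < N_m);
    elsewhere ``corr`` holds NaN rather than a silent zero.
    """

    thresholds: np.ndarray
    corr: np.ndarray
    deriv: np.ndarray
    above_counts: np.ndarray
    defined: np.ndarray
    rc_index: int = 0


@dataclass
class ThresholdSelection:
    """Optimal threshold plus the detected population transitions.

    ``tissue_threshold`` separates off-section background from tissue (the
    silhouette threshold); ``cell_threshold`` separates tissue
    autofluorescence from labeled somata.  Either may be None when the curve
    exhibits fewer transitions than requested; ``missing`` lists what was not
    found.
    """

    optimal: int
    tissue_threshold: int | None = None
    cell_threshold: int | None = None
    transitions: list = field(default_factory=list)
    missing: int = 0
    rc_index: int = 0


def threshold_image(image: np.ndarray, i: int, max_gray: int = 255) -> BinaryMask:
    """Binary mask of pixels strictly above gray value ``i``."""
    if not 0 <= i <= max_gray:
        raise ValueError(f"threshold {i} outside gray range [0, {max_gray}]")
    return BinaryMask((np.asarray(image) > i).astype(np.uint8), int(i))


def correlation_curve(
    image: np.ndarray, bit_depth: int = 8, rc_index: int = 0
) -> CorrelationCurve:
    """MCT curve over every gray level, via the histogram closed form.

    Raises DegenerateImageError for constant images (zero variance).
    """
    hist = GrayHistogram.from_image(image, bit_depth)
    n = hist.counts.astype(float)
    n_gray = len(n)
    j = np.arange(n_gray, dtype=float)
    xbar = float((j * n).sum() / hist.total_pixels)
    ssq = float(((j - xbar) ** 2 * n).sum())
    if ssq == 0.0:
        raise DegenerateImageError("constant image: correlation undefined")
    nm = hist.total_pixels

    # Suffix sums over j > i via reversed cumulative sums.
    dev = n * (j - xbar)
    num = dev[::-1].cumsum()[::-1]          # sum_{j>=i} n_j (j - x̄)
    above = n[::-1].cumsum()[::-1]          # count of pixels >= i
    # Shift: threshold i keeps values strictly greater than i.
    num = np.concatenate([num[1:], [0.0]])
    n_i = np.concatenate([above[1:], [0.0]])

    defined = (n_i > 0) & (n_i < nm)
    corr = np.full(n_gray, np.nan)
    denom = np.sqrt(ssq) * np.sqrt(n_i[defined] * (nm - n_i[defined]) / nm)
    corr[defined] = num[defined] / denom

    # First finite difference; NaN wherever either operand is undefined.
    deriv = np.full(n_gray, np.nan)
    deriv[1:] = corr[1:] - corr[:-1]
    if defined.any():
        first = int(np.flatnonzero(defined)[0])
        deriv[first] = 0.0

    return CorrelationCurve(
        thresholds=np.arange(n_gray),
        corr=corr,
        deriv=deriv,
        above_counts=n_i.astype(np.int64),
        defined=defined,
        rc_index=rc_index,
    )


def optimal_threshold(curve: CorrelationCurve) -> int:
    """Smallest gray value attaining the maximum defined correlation."""
    if not curve.defined.any():
        raise DegenerateImageError("no defined correlation values")
    corr = np.where(curve.defined, curve.corr, -np.inf)
    best = corr.max()
    return int(np.flatnonzero(corr == best)[0])


def _smooth(values: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return values
    kernel = np.ones(window) / window
    return np.convolve(values, kernel, mode="same")


def _left_base(mag: np.ndarray, peak: int, rel: float = 0.05,
               gap: int = 3) -> int:
    """Walk left from a |derivative| peak to where its excursion begins.

    The base is the first gray value of a sustained (>= ``gap`` levels) run
    below ``rel`` of the peak height, so single-level noise dips inside a
    broad excursion are stepped over.
    """
    floor = rel * mag[peak]
    k = peak
    run = 0
    base = peak
    while k > 0:
        k -= 1
        if mag[k] <= floor:
            run += 1
            if run == 1:
                base = k
            if run >= gap:
                return base
        else:
            run = 0
    return base if run > 0 else 0


def transition_thresholds(
    curve: CorrelationCurve,
    n_transitions: int = 2,
    smooth_window: int = 5,
    min_separation: int = 5,
) -> ThresholdSelection:
    """Locate intensity-population transitions from the curve derivative.

    The absolute derivative is smoothed with a moving average, its
    ``n_transitions`` largest local extrema (separated by at least
    ``min_separation`` gray levels) are found, and each transition is reported
    at the gray value where its excursion begins (left base, 5% of peak
    height).  Transitions are returned sorted ascending: the lowest is the
    tissue-edge threshold, the highest the labeled-cell threshold.  If fewer
    extrema exist than requested the found subset is returned and ``missing``
    counts the shortfall.
    """
    mag = np.abs(_smooth(np.nan_to_num(curve.deriv, nan=0.0), smooth_window))
    peaks, _ = find_peaks(mag, distance=max(1, min_separation))
    order = np.argsort(mag[peaks])[::-1]
    # Accept peaks in magnitude order, but collapse peaks that belong to one
    # excursion (same left base) so a ragged excursion cannot consume two
    # transition slots.
    uniq: list[int] = []
    for k in order:
        base = _left_base(mag, int(peaks[k]))
        if all(abs(base - b) >= min_separation for b in uniq):
            uniq.append(base)
        if len(uniq) == n_transitions:
            break
    uniq.sort()
    sel = ThresholdSelection(
        optimal=optimal_threshold(curve),
        transitions=uniq,
        missing=max(0, n_transitions - len(uniq)),
        rc_index=curve.rc_index,
    )
    if len(uniq) >= 2:
        sel.tissue_threshold, sel.cell_threshold = uniq[0], uniq[-1]
    elif len(uniq) == 1:
        sel.tissue_threshold = uniq[0]
    return sel


def per_section_curves(stack: list[SectionImage]) -> list[CorrelationCurve | None]:
    """One MCT curve per section, computed independently.

    Degenerate (e.g. empty-tissue) sections yield None instead of aborting the
    stack, so the caller can flag them and continue.
    """
    if not stack:
        raise ValueError("empty section stack")
    curves: list[CorrelationCurve | None] = []
    for sec in stack:
        try:
            curves.append(
                correlation_curve(sec.pixels, sec.bit_depth, rc_index=sec.rc_index)
            )
        except DegenerateImageError:
            curves.append(None)
    return curves


def curve_to_table(curve: CorrelationCurve):
    """Curve as a DataFrame (threshold, corr, deriv, n_above) for CSV export."""
    import pandas as pd

    return pd.DataFrame(
        {
            "threshold": curve.thresholds,
            "corr": curve.corr,
            "deriv": curve.deriv,
            "n_above": curve.above_counts,
        }
    )
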