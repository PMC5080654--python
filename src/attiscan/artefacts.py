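"""Moving-object artefact removal from back-to-back scan pairs.

Two scans of the same scene are aligned by circular cross-correlation of
their range rasters.  Within user-supplied bounding boxes, the per-pixel
range contrast between the pair is histogrammed; its smoothed, bimodal
distribution separates static background (low contrast) from a mover
present in one scan (high contrast).  Cells above the valley threshold
take the larger of the two range estimates, which restores the background
surface.  Low-intensity returns (< 0.005 of maximum) are flagged for
removal separately.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

from .scenes import SphericalScan

__all__ = [
    "LOW_INTENSITY_THRESHOLD",
    "BoundingBoxSpec",
    "ContrastHistogram",
    "UnimodalHistogramError",
    "AlignmentWarning",
    "align_pair",
    "apply_azimuth_shift",
    "range_contrast",
    "contrast_histogram",
    "find_threshold",
    "remove_movers",
    "low_intensity_filter",
    "propose_boxes",
]

LOW_INTENSITY_THRESHOLD = 0.005

#: Savitzky-Golay smoothing emulating a quadratic-fit moving window.
SMOOTH_WINDOW = 11
SMOOTH_ORDER = 2

#: Correlation peak must exceed this multiple of the mean correlation,
#: otherwise the alignment is flagged low-confidence.
ALIGN_CONFIDENCE_RATIO = 1.02


class UnimodalHistogramError(ValueError):
    """Contrast histogram lacks two modes; the box is rejected."""


class AlignmentWarning(UserWarning):
    """Cross-correlation peak is not well separated from the baseline."""


@dataclass(frozen=True)
class BoundingBoxSpec:
    """Rectangular region of the scan grid, in degrees."""

    azimuth_lo: float
    azimuth_hi: float
    elevation_lo: float
    elevation_hi: float

    def cell_mask(self, scan: SphericalScan) -> np.ndarray:
        az = scan.azimuths_deg
        el = scan.elevations_deg
        col = (az >= self.azimuth_lo) & (az <= self.azimuth_hi)
        row = (el >= self.elevation_lo) & (el <= self.elevation_hi)
        if not col.any() or not row.any():
            raise ValueError("bounding box does not intersect the scan grid")
        return row[:, None] & col[None, :]


@dataclass
class ContrastHistogram:
    bin_edges: np.ndarray
    counts: np.ndarray
    smoothed: np.ndarray

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


def align_pair(scan1: SphericalScan, scan2: SphericalScan) -> int:
    """Azimuthal shift (grid cells) that best aligns ``scan2`` to ``scan1``.

    Maximizes the NaN-ignoring circular cross-correlation of the two
    range rasters over azimuth.  Returns the shift to pass to
    :func:`apply_azimuth_shift`.  Warns with :class:`AlignmentWarning`
    when the correlation peak barely exceeds its circular mean.
    """
    if scan1.shape != scan2.shape:
        raise ValueError("scan grids differ; cannot align")
    r1 = scan1.range_m
    r2 = scan2.range_m
    m1 = np.isfinite(r1)
    m2 = np.isfinite(r2)
    a = np.where(m1, r1, 0.0)
    b = np.where(m2, r2, 0.0)
    # Circular cross-correlation over azimuth via FFT; normalize each lag
    # by the number of cells where both scans have returns.
    fa = np.fft.rfft(a, axis=1)
    fb = np.fft.rfft(b, axis=1)
    corr = np.fft.irfft(fa * np.conj(fb), n=a.shape[1], axis=1).sum(axis=0)
    fm1 = np.fft.rfft(m1.astype(float), axis=1)
    fm2 = np.fft.rfft(m2.astype(float), axis=1)
    overlap = np.fft.irfft(fm1 * np.conj(fm2), n=a.shape[1], axis=1).sum(axis=0)
    if not (overlap > 0).any():
        raise ValueError("no overlapping returns between the two scans")
    with np.errstate(divide="ignore", invalid="ignore"):
        score = np.where(overlap > 0, corr / overlap, -np.inf)
    lag = int(np.argmax(score))
    # irfft correlation at index j corresponds to b shifted by +j matching a;
    # express as the roll to apply to scan2.
    shift = lag if lag <= a.shape[1] // 2 else lag - a.shape[1]
    finite = score[np.isfinite(score)]
    if finite.size > 1 and np.max(finite) < ALIGN_CONFIDENCE_RATIO * np.mean(finite):
        warnings.warn(
            "alignment peak poorly separated from baseline; shift may be unreliable",
            AlignmentWarning,
            stacklevel=2,
        )
    return shift


def apply_azimuth_shift(scan: SphericalScan, shift: int) -> SphericalScan:
    """Circularly roll a scan's rasters along azimuth by ``shift`` cells."""
    out = scan.copy()
    out.range_m = np.roll(out.range_m, shift, axis=1)
    out.intensity = np.roll(out.intensity, shift, axis=1)
    if out.true_normals is not None:
        out.true_normals = np.roll(out.true_normals, shift, axis=1)
    if out.prim_id is not None:
        out.prim_id = np.roll(out.prim_id, shift, axis=1)
    if out.removed is not None:
        out.removed = np.roll(out.removed, shift, axis=1)
    return out


def range_contrast(
    scan1: SphericalScan, scan2: SphericalScan, kind: str = "normalized"
) -> np.ndarray:
    """Per-cell contrast between two aligned range rasters.

    ``normalized``: |R1 - R2| / (R1 + R2), bounded in [0, 1).
    ``log``: |log R1 - log R2|.
    NaN wherever either scan has no return.
    """
    r1, r2 = scan1.range_m, scan2.range_m
    if r1.shape != r2.shape:
        raise ValueError("scan grids differ")
    with np.errstate(invalid="ignore", divide="ignore"):
        if kind == "normalized":
            c = np.abs(r1 - r2) / (r1 + r2)
        elif kind == "log":
            c = np.abs(np.log(r1) - np.log(r2))
        else:
            raise ValueError(f"unknown contrast kind {kind!r}")
    return c


def contrast_histogram(values: np.ndarray, n_bins: int = 100) -> ContrastHistogram:
    """Histogram of finite contrast values on [0, max], with quadratic-fit
    moving-window smoothing."""
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size == 0:
        raise ValueError("no finite contrast values to histogram")
    hi = float(v.max())
    if hi <= 0:
        hi = 1e-12
    counts, edges = np.histogram(v, bins=n_bins, range=(0.0, hi))
    window = min(SMOOTH_WINDOW, n_bins if n_bins % 2 == 1 else n_bins - 1)
    smoothed = savgol_filter(counts.astype(float), window, SMOOTH_ORDER)
    return ContrastHistogram(bin_edges=edges, counts=counts, smoothed=np.maximum(smoothed, 0.0))


def find_threshold(hist: ContrastHistogram, min_prominence: float = 0.02) -> float:
    """Contrast threshold at the valley between the two tallest smoothed
    modes; raises :class:`UnimodalHistogramError` without two modes.

    Modes must have prominence of at least ``min_prominence`` times the
    histogram maximum, which rejects smoothing ripples.
    """
    from scipy.signal import find_peaks

    s = hist.smoothed
    # Pad so a mode in the first or last bin still counts as a peak.
    padded = np.concatenate([[-1.0], s, [-1.0]])
    peaks, _ = find_peaks(padded, prominence=min_prominence * s.max())
    peaks = [int(p) - 1 for p in peaks if s[int(p) - 1] > 0]
    if len(peaks) < 2:
        raise UnimodalHistogramError("smoothed contrast histogram has fewer than two modes")
    order = sorted(peaks, key=lambda i: (-s[i], i))
    i, j = sorted(order[:2])
    valley = np.arange(i + 1, j)
    if valley.size == 0:
        raise UnimodalHistogramError("no valley between the two largest modes")
    # Ties broken toward lower contrast.
    k = valley[np.argmin(s[valley])]
    return float(hist.bin_centers[k])


def remove_movers(
    scan1: SphericalScan,
    scan2: SphericalScan,
    boxes: list[BoundingBoxSpec],
    contrast_kind: str = "normalized",
    n_bins: int = 100,
) -> tuple[SphericalScan, np.ndarray]:
    """Clean a pre-aligned pair: within each box, cells whose range
    contrast exceeds the per-box valley threshold take the larger range.

    Returns the cleaned scan (scan1 outside boxes) and the artefact mask.
    Boxes whose histogram is unimodal are skipped.
    """
    contrast = range_contrast(scan1, scan2, kind=contrast_kind)
    cleaned = scan1.copy()
    mask = np.zeros(scan1.shape, dtype=bool)
    for box in boxes:
        cells = box.cell_mask(scan1)
        vals = contrast[cells]
        try:
            hist = contrast_histogram(vals, n_bins=n_bins)
            thresh = find_threshold(hist)
        except (UnimodalHistogramError, ValueError):
            continue
        art = cells & (contrast > thresh)
        mask |= art
    larger = np.fmax(scan1.range_m, scan2.range_m)
    cleaned.range_m = np.where(mask, larger, scan1.range_m)
    return cleaned, mask


def low_intensity_filter(
    scan: SphericalScan, threshold: float = LOW_INTENSITY_THRESHOLD
) -> tuple[SphericalScan, np.ndarray]:
    """Flag returns with intensity strictly below ``threshold`` as removed.

    Removed cells keep their raster values but are excluded from point
    conversion and written as all-zero records by the PCD writer.
    """
    out = scan.copy()
    removed = np.isfinite(out.range_m) & (out.intensity < threshold)
    out.removed = removed if out.removed is None else (out.removed | removed)
    return out, removed


def propose_boxes(
    scan1: SphericalScan,
    scan2: SphericalScan,
    contrast_floor: float = 0.2,
    pad_cells: int = 2,
) -> list[BoundingBoxSpec]:
    """Heuristic stand-in for manual box selection: bounding boxes of
    connected high-contrast regions.  Convenience only — thresholds are
    still derived per box from the contrast histogram."""
    from scipy.ndimage import label

    contrast = range_contrast(scan1, scan2)
    hot = np.isfinite(contrast) & (contrast > contrast_floor)
    labels, n = label(hot)
    boxes = []
    for i in range(1, n + 1):
        rows, cols = np.nonzero(labels == i)
        r0 = max(rows.min() - pad_cells, 0)
        r1 = min(rows.max() + pad_cells, scan1.shape[0] - 1)
        c0 = max(cols.min() - pad_cells, 0)
        c1 = min(cols.max() + pad_cells, scan1.shape[1] - 1)
        boxes.append(
            BoundingBoxSpec(
                azimuth_lo=float(scan1.azimuths_deg[c0]),
                azimuth_hi=float(scan1.azimuths_deg[c1]),
                elevation_lo=float(scan1.elevations_deg[r0]),
                elevation_hi=float(scan1.elevations_deg[r1]),
            )
        )
    return boxes
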