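"""Aggregate per-point attitudes into probability densities.

Per scan, every return gets an egocentric (slant, tilt) pair from its own
view ray, a gravity-referenced world slant, and its grid elevation.
Returns are histogrammed — jointly in the equal-area slant/tilt plane and
marginally over tilt, slant and world slant — conditioned on elevation
band, normalized to unit bin mass, and averaged over scenes with equal
scene weight.

Because the scan grid is equal-angle, cells near the zenith cover less
solid angle than cells at the horizon; by default each return is weighted
by the solid angle of its cell, sin(elevation-from-nadir) (equivalently
cos(elevation - 90 deg)).  Set ``weighting="none"`` for raw counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import (
    equal_area_map,
    maxent_slant_marginal,
    slant_tilt_arrays,
    world_slant,
)
from .scenes import PointCloud

__all__ = [
    "DEFAULT_BANDS",
    "BinningConfig",
    "Attitudes",
    "AttitudeDensity",
    "point_attitudes",
    "accumulate",
    "average_over_scenes",
    "compare_to_maxent",
    "maxent_slant_bin_mass",
]

#: Elevation bands in degrees from nadir; the first matches the printed
#: downward-gaze band, the last is closed at the zenith.
DEFAULT_BANDS = ((45.0, 68.0), (68.0, 90.0), (90.0, 112.0), (112.0, 135.0), (135.0, 180.0))

COLLAPSED = "collapsed"


@dataclass(frozen=True)
class BinningConfig:
    """Histogram binning.  ``plane_bin_deg`` is nominal: the equal-area
    radial coordinate approximates slant in degrees-as-radians scale, so
    the square joint bins have side radians(plane_bin_deg)."""

    plane_bin_deg: float = 2.0
    tilt_bin_deg: float = 5.0
    slant_bin_deg: float = 2.0
    world_slant_bin_deg: float = 2.0
    #: center tilt bins on the canonical directions (0/90/180/270) so a
    #: floor mode is not split across the 0/360 seam
    tilt_centered: bool = True

    @property
    def plane_edges(self) -> np.ndarray:
        w = np.radians(self.plane_bin_deg)
        half = int(np.ceil(np.sqrt(2.0) / w))
        return np.arange(-half, half + 1) * w

    @property
    def tilt_edges(self) -> np.ndarray:
        offset = -self.tilt_bin_deg / 2.0 if self.tilt_centered else 0.0
        return offset + np.arange(0.0, 360.0 + 1e-9, self.tilt_bin_deg)

    @property
    def tilt_centers(self) -> np.ndarray:
        return 0.5 * (self.tilt_edges[:-1] + self.tilt_edges[1:]) % 360.0

    @property
    def slant_edges(self) -> np.ndarray:
        return np.arange(0.0, 90.0 + 1e-9, self.slant_bin_deg)

    @property
    def world_slant_edges(self) -> np.ndarray:
        return np.arange(0.0, 180.0 + 1e-9, self.world_slant_bin_deg)


@dataclass
class Attitudes:
    """Per-point attitude table (rows aligned with the input cloud subset
    that had a valid normal)."""

    slant_deg: np.ndarray
    tilt_deg: np.ndarray
    tilt_defined: np.ndarray
    world_slant_deg: np.ndarray
    elevation_deg: np.ndarray

    def __len__(self) -> int:
        return len(self.slant_deg)


@dataclass
class AttitudeDensity:
    """Normalized histograms over the attitude hemisphere for one
    (category, band) cell.  All histograms use the bin-mass convention:
    each sums to 1 (when non-empty)."""

    binning: BinningConfig
    joint: np.ndarray  # (ny, nx) over the equal-area plane
    tilt: np.ndarray
    slant: np.ndarray
    world: np.ndarray
    weight_total: float = 0.0
    n_scenes: int = 1
    category: str = ""
    band: str = COLLAPSED
    weighting: str = "solid_angle"

    @property
    def empty(self) -> bool:
        return self.weight_total == 0.0

    @classmethod
    def zeros(cls, binning: BinningConfig, **kw) -> "AttitudeDensity":
        ne = len(binning.plane_edges) - 1
        return cls(
            binning=binning,
            joint=np.zeros((ne, ne)),
            tilt=np.zeros(len(binning.tilt_edges) - 1),
            slant=np.zeros(len(binning.slant_edges) - 1),
            world=np.zeros(len(binning.world_slant_edges) - 1),
            **kw,
        )


def point_attitudes(cloud: PointCloud, normals: np.ndarray) -> Attitudes:
    """Egocentric and world attitude of every return with a valid normal.

    ``normals`` is row-aligned with ``cloud`` (NaN rows — degenerate or
    isolated points — are dropped).  View rays within the degenerate-view
    tolerance of vertical keep their slant but have no tilt.
    """
    n = np.asarray(normals, dtype=float)
    if n.shape != cloud.xyz.shape:
        raise ValueError("normals must be row-aligned with the cloud")
    ok = np.isfinite(n).all(axis=1)
    slant, tilt, defined = slant_tilt_arrays(n[ok], cloud.view_dirs[ok])
    return Attitudes(
        slant_deg=slant,
        tilt_deg=tilt,
        tilt_defined=defined,
        world_slant_deg=world_slant(n[ok]),
        elevation_deg=cloud.elevations_deg[ok],
    )


def _band_label(band: tuple[float, float]) -> str:
    return f"{band[0]:g}-{band[1]:g}"


def _accumulate_one(
    att: Attitudes,
    sel: np.ndarray,
    weights: np.ndarray,
    binning: BinningConfig,
    **labels,
) -> AttitudeDensity:
    d = AttitudeDensity.zeros(binning, **labels)
    if not sel.any():
        return d
    w = weights[sel]
    slant = att.slant_deg[sel]
    tilt = att.tilt_deg[sel]
    defined = att.tilt_defined[sel]
    ws = att.world_slant_deg[sel]

    # Joint histogram in the equal-area plane.  Points with undefined tilt
    # from near-zero slant carry their mass to the plane origin; rows with
    # NaN tilt (degenerate view rays) are excluded.
    plane_ok = np.isfinite(tilt) & np.isfinite(slant)
    x, y = equal_area_map(slant, np.where(np.isfinite(tilt), tilt, 0.0))
    small = ~defined & np.isfinite(tilt)  # near-zero slant, not degenerate view
    x = np.where(small, 0.0, x)
    y = np.where(small, 0.0, y)
    e = binning.plane_edges
    joint, _, _ = np.histogram2d(
        y[plane_ok], x[plane_ok], bins=(e, e), weights=w[plane_ok]
    )
    d.joint = joint
    t_edges = binning.tilt_edges
    t_wrapped = (tilt[defined] - t_edges[0]) % 360.0 + t_edges[0]
    d.tilt, _ = np.histogram(t_wrapped, bins=t_edges, weights=w[defined])
    s_ok = np.isfinite(slant)
    d.slant, _ = np.histogram(
        np.clip(slant[s_ok], 0, 90 - 1e-9), bins=binning.slant_edges, weights=w[s_ok]
    )
    d.world, _ = np.histogram(
        np.clip(ws, 0, 180 - 1e-9), bins=binning.world_slant_edges, weights=w
    )
    d.weight_total = float(w.sum())
    for h in ("joint", "tilt", "slant", "world"):
        arr = getattr(d, h)
        tot = arr.sum()
        if tot > 0:
            setattr(d, h, arr / tot)
    return d


def accumulate(
    att: Attitudes,
    bands: tuple[tuple[float, float], ...] = DEFAULT_BANDS,
    weighting: str = "solid_angle",
    binning: BinningConfig = BinningConfig(),
    category: str = "",
) -> dict[str, AttitudeDensity]:
    """Histogram attitudes per elevation band and collapsed over bands.

    Returns a dict keyed by band label plus ``"collapsed"``.  Empty bands
    yield densities with ``empty`` True (all-zero histograms, never NaN).
    """
    if weighting == "solid_angle":
        weights = np.sin(np.radians(att.elevation_deg))
    elif weighting == "none":
        weights = np.ones(len(att))
    else:
        raise ValueError(f"unknown weighting {weighting!r}")

    out: dict[str, AttitudeDensity] = {}
    el = att.elevation_deg
    last_hi = max(b[1] for b in bands) if bands else None
    for band in bands:
        lo, hi = band
        sel = (el >= lo) & ((el < hi) | (hi == last_hi) & (el == hi))
        out[_band_label(band)] = _accumulate_one(
            att, sel, weights, binning,
            category=category, band=_band_label(band), weighting=weighting,
        )
    out[COLLAPSED] = _accumulate_one(
        att, np.ones(len(att), dtype=bool), weights, binning,
        category=category, band=COLLAPSED, weighting=weighting,
    )
    return out


def average_over_scenes(densities: list[AttitudeDensity]) -> AttitudeDensity:
    """Unweighted mean of per-scene normalized densities (each scene
    contributes equally, regardless of return count)."""
    if not densities:
        raise ValueError("no densities to average")
    first = densities[0]
    for d in densities[1:]:
        if d.joint.shape != first.joint.shape or d.binning != first.binning:
            raise ValueError("density binning mismatch")
    non_empty = [d for d in densities if not d.empty]
    if not non_empty:
        return AttitudeDensity.zeros(first.binning, category=first.category,
                                     band=first.band, weighting=first.weighting)
    return AttitudeDensity(
        binning=first.binning,
        joint=np.mean([d.joint for d in non_empty], axis=0),
        tilt=np.mean([d.tilt for d in non_empty], axis=0),
        slant=np.mean([d.slant for d in non_empty], axis=0),
        world=np.mean([d.world for d in non_empty], axis=0),
        weight_total=float(sum(d.weight_total for d in non_empty)),
        n_scenes=len(non_empty),
        category=first.category,
        band=first.band,
        weighting=first.weighting,
    )


def maxent_slant_bin_mass(edges_deg: np.ndarray) -> np.ndarray:
    """Exact bin masses of the sin(2 phi) slant marginal on given edges:
    integral over [a, b] is (cos 2a - cos 2b) / 2."""
    e = np.radians(np.asarray(edges_deg, dtype=float))
    return 0.5 * (np.cos(2 * e[:-1]) - np.cos(2 * e[1:]))


@dataclass(frozen=True)
class MaxentComparison:
    kl_divergence: float
    sup_norm: float
    modal_tilt_bins_deg: tuple[float, ...]


def compare_to_maxent(density: AttitudeDensity, n_modes: int = 4) -> MaxentComparison:
    """Divergence of a slant marginal from the random-world prediction.

    KL divergence and sup-norm distance are computed between the measured
    slant bin masses and the analytic sin(2 phi) masses on identical
    bins; the tilt marginal's ``n_modes`` heaviest bin centers are
    reported as modal tilt directions.
    """
    q = maxent_slant_bin_mass(density.binning.slant_edges)
    p = density.slant
    pos = p > 0
    kl = float(np.sum(p[pos] * np.log(p[pos] / q[pos])))
    sup = float(np.max(np.abs(p - q)))
    centers = density.binning.tilt_centers
    top = np.argsort(density.tilt)[::-1][:n_modes]
    return MaxentComparison(
        kl_divergence=kl,
        sup_norm=sup,
        modal_tilt_bins_deg=tuple(float(centers[i]) for i in sorted(top)),
    )
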