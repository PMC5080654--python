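"""Per-point surface normals with minimum-reliable-scale selection.

At every query point a local plane is fit by PCA to its k nearest
neighbours (3D Euclidean), with iterative removal of points deviating by
more than three residual standard deviations.  The normal is the
eigenvector of the smallest covariance eigenvalue; elongated
neighbourhoods with eigenvalue ratio lambda2/lambda1 below 0.3 are
degenerate and skipped.

Scale selection walks a geometric schedule of neighbourhood sizes from
k = 7 to k = 300 and tests, at each scale, the planarity null hypothesis:
the mean absolute point-to-plane deviation is compared against a
distance-dependent threshold calibrated on scans of known planar surfaces
(which absorbs the instrument's correlated noise).  The first scale that
rejects the null marks the onset of contamination by neighbouring
structure; by default the fit reported is the one at the last scale that
did NOT reject (set ``report_at_rejection=True`` to report the rejecting
fit itself).  If no scale rejects, the maximum-scale fit is returned.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .scenes import PointCloud, PlanePatch, ScanConfig, SphericalScan, raycast, scan_to_points, SceneSpec

__all__ = [
    "STATUS_REJECTED",
    "STATUS_MAX_SCALE",
    "STATUS_DEGENERATE",
    "STATUS_ISOLATED",
    "STATUS_NAMES",
    "PlaneFit",
    "ScaleConfig",
    "NoiseCalibration",
    "ScaleSelection",
    "NormalEstimates",
    "DegenerateNeighbourhoodError",
    "fit_plane",
    "k_schedule",
    "planar_calibration_cloud",
    "calibrate_thresholds",
    "select_scale",
    "estimate_normals",
]

STATUS_REJECTED = 0  # planarity rejected at some scale; scale selected
STATUS_MAX_SCALE = 1  # never rejected; maximum-scale fit returned
STATUS_DEGENERATE = 2  # every scale degenerate; no normal
STATUS_ISOLATED = 3  # fewer than k_min neighbours
STATUS_NAMES = {
    STATUS_REJECTED: "rejected-at-k",
    STATUS_MAX_SCALE: "max-scale",
    STATUS_DEGENERATE: "degenerate",
    STATUS_ISOLATED: "isolated",
}


class DegenerateNeighbourhoodError(ValueError):
    """Too few or collinear points for a plane fit."""


@dataclass(frozen=True)
class PlaneFit:
    """Local planar model of a neighbourhood."""

    centroid: np.ndarray
    normal: np.ndarray
    eigenvalues: np.ndarray  # descending: lambda1 >= lambda2 >= lambda3
    mean_abs_deviation: float
    inlier_count: int
    k: int

    @property
    def eigen_ratio(self) -> float:
        """lambda2 / lambda1; below the degeneracy threshold the normal is
        unreliable."""
        l1 = float(self.eigenvalues[0])
        return float(self.eigenvalues[1]) / l1 if l1 > 0 else 0.0


@dataclass(frozen=True)
class ScaleConfig:
    k_min: int = 7
    k_max: int = 300
    schedule_ratio: float = 1.3
    outlier_multiple: float = 3.0
    degeneracy_ratio: float = 0.3
    calibration_quantile: float = 0.99
    report_at_rejection: bool = False

    def __post_init__(self):
        if not (3 <= self.k_min <= self.k_max):
            raise ValueError("need 3 <= k_min <= k_max")
        if not (0.0 < self.degeneracy_ratio < 1.0):
            raise ValueError("degeneracy ratio must lie in (0, 1)")


def k_schedule(config: ScaleConfig) -> list[int]:
    """Geometric neighbourhood-size schedule from k_min to k_max."""
    ks = []
    k = float(config.k_min)
    while k < config.k_max:
        ks.append(int(round(k)))
        k *= config.schedule_ratio
    ks.append(config.k_max)
    out = []
    for k in ks:
        if not out or k > out[-1]:
            out.append(k)
    return out


def _batch_fit(
    pts: np.ndarray, outlier_multiple: float, max_iter: int = 15
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized PCA plane fit with iterative 3-sigma outlier removal.

    ``pts``: (M, k, 3).  Returns (centroids (M,3), normals (M,3),
    eigenvalues descending (M,3), mean_abs_dev (M,), inlier_counts (M,)).
    """
    m, k, _ = pts.shape
    mask = np.ones((m, k), dtype=bool)
    centroid = np.empty((m, 3))
    normal = np.empty((m, 3))
    evals_desc = np.empty((m, 3))
    mean_dev = np.empty(m)
    counts = np.empty(m, dtype=np.int64)
    # Iterate only the rows whose inlier set changed last round.
    rows = np.arange(m)
    for _ in range(max_iter):
        p = pts[rows]
        msk = mask[rows]
        cnt = msk.sum(axis=1)
        w = msk[..., None].astype(float)
        c = (p * w).sum(axis=1) / cnt[:, None]
        d = (p - c[:, None, :]) * w
        cov = np.einsum("mki,mkj->mij", d, d) / cnt[:, None, None]
        evals, evecs = np.linalg.eigh(cov)  # ascending
        nrm = evecs[:, :, 0]
        resid = np.einsum("mki,mi->mk", p - c[:, None, :], nrm)
        sd = np.sqrt((resid**2 * msk).sum(axis=1) / cnt)
        centroid[rows] = c
        normal[rows] = nrm
        evals_desc[rows] = evals[:, ::-1]
        mean_dev[rows] = (np.abs(resid) * msk).sum(axis=1) / cnt
        counts[rows] = cnt
        # An exact plane has sd ~ machine eps; treat as outlier-free.
        can_shrink = (cnt > 3) & (sd > 1e-12)
        new_msk = msk & ~(
            can_shrink[:, None] & (np.abs(resid) > outlier_multiple * sd[:, None])
        )
        # Never shrink a neighbourhood below 3 points.
        too_small = new_msk.sum(axis=1) < 3
        new_msk[too_small] = msk[too_small]
        changed = (new_msk != msk).any(axis=1)
        mask[rows] = new_msk
        rows = rows[changed]
        if rows.size == 0:
            break
    return centroid, normal, evals_desc, mean_dev, counts


def fit_plane(
    points: np.ndarray,
    outlier_multiple: float = 3.0,
    sensor_origin: np.ndarray | None = None,
) -> PlaneFit:
    """PCA plane fit with iterative outlier rejection.

    The normal is the smallest-eigenvalue eigenvector of the inlier
    covariance, signed toward ``sensor_origin`` (default: the world
    origin).  Raises :class:`DegenerateNeighbourhoodError` for fewer than
    three points or a collinear configuration.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or len(pts) < 3:
        raise DegenerateNeighbourhoodError("need at least 3 points of dimension 3")
    centroid, normal, evals, mean_dev, cnt = (
        a[0] for a in _batch_fit(pts[None], outlier_multiple)
    )
    if evals[1] <= 1e-20 * max(evals[0], 1.0):
        raise DegenerateNeighbourhoodError("points are (near-)collinear")
    origin = np.zeros(3) if sensor_origin is None else np.asarray(sensor_origin, float)
    if normal @ (centroid - origin) > 0:
        normal = -normal
    return PlaneFit(
        centroid=centroid,
        normal=normal,
        eigenvalues=evals,
        mean_abs_deviation=float(mean_dev),
        inlier_count=int(cnt),
        k=len(pts),
    )


@dataclass
class NoiseCalibration:
    """Distance-binned planarity thresholds from known-plane scans.

    ``distances_m`` are bin representative distances (sorted);
    ``thresholds_m`` are the corresponding mean-deviation thresholds,
    monotone non-decreasing in distance.  Lookup clamps to the outer bins.
    """

    distances_m: np.ndarray
    thresholds_m: np.ndarray

    def __post_init__(self):
        order = np.argsort(self.distances_m)
        self.distances_m = np.asarray(self.distances_m, float)[order]
        self.thresholds_m = np.maximum.accumulate(
            np.asarray(self.thresholds_m, float)[order]
        )

    def lookup(self, distance_m: np.ndarray) -> np.ndarray:
        """Threshold for the nearest calibration distance bin."""
        d = np.asarray(distance_m, dtype=float)
        edges = 0.5 * (self.distances_m[:-1] + self.distances_m[1:])
        idx = np.searchsorted(edges, d)
        return self.thresholds_m[idx]

    def to_text(self) -> str:
        lines = ["# distance_m threshold_m"]
        for d, t in zip(self.distances_m, self.thresholds_m):
            lines.append(f"{float(d)!r} {float(t)!r}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "NoiseCalibration":
        rows = [
            [float(x) for x in ln.split()]
            for ln in text.splitlines()
            if ln.strip() and not ln.lstrip().startswith("#")
        ]
        arr = np.asarray(rows, dtype=float)
        return cls(distances_m=arr[:, 0], thresholds_m=arr[:, 1])


def planar_calibration_cloud(
    distance_m: float,
    range_noise_m: float,
    step_arcmin: float = 30.0,
    rng_seed: int = 0,
    patch_half_extent_m: float | None = None,
) -> PointCloud:
    """Scan a frontal planar target at a known distance.

    A square patch is placed perpendicular to the horizontal view ray at
    ``distance_m`` and scanned over a narrow angular window, mimicking
    the known-plane measurements used to characterise instrument noise.
    """
    half = patch_half_extent_m if patch_half_extent_m is not None else max(
        0.35 * distance_m, 1.0
    )
    span = 2.0 * np.degrees(np.arctan(0.8 * half / distance_m))
    patch = PlanePatch(
        center=np.array([distance_m, 0.0, 0.0]),
        normal=np.array([-1.0, 0.0, 0.0]),
        u_axis=np.array([0.0, 1.0, 0.0]),
        v_axis=np.array([0.0, 0.0, 1.0]),
        half_u=half,
        half_v=half,
        albedo=0.7,
    )
    config = ScanConfig(
        azimuth_span_deg=360.0,
        elevation_min_deg=max(45.0, 90.0 - span / 2),
        elevation_max_deg=min(179.0, 90.0 + span / 2),
        step_arcmin=step_arcmin,
        max_range_m=max(120.0, distance_m * 2),
        range_noise_m=range_noise_m,
        intensity_noise=0.0,
        low_intensity_fraction=0.0,
    )
    scene = SceneSpec(category="outdoor-built", primitives=(patch,), seed=rng_seed)
    scan = raycast(scene, config, rng_seed=rng_seed)
    return scan_to_points(scan)


def calibrate_thresholds(
    planar_clouds: list[PointCloud],
    config: ScaleConfig,
    n_query: int = 150,
    rng_seed: int = 0,
) -> NoiseCalibration:
    """Derive distance-dependent planarity thresholds.

    For each known-plane cloud, the mean absolute plane-fit deviation is
    sampled over query points and neighbourhood sizes; the per-distance
    threshold is the ``calibration_quantile`` of that null distribution,
    maximized over k, then monotonized over distance.
    """
    if len(planar_clouds) < 1:
        raise ValueError("need at least one planar calibration cloud")
    rng = np.random.default_rng(rng_seed)
    ks = k_schedule(config)
    distances = []
    thresholds = []
    for cloud in planar_clouds:
        xyz = cloud.xyz
        if len(xyz) < config.k_min + 1:
            raise ValueError("calibration cloud too sparse for k_min neighbourhood")
        tree = cKDTree(xyz)
        q = rng.choice(len(xyz), size=min(n_query, len(xyz)), replace=False)
        k_eff = min(config.k_max, len(xyz))
        _, nbr = tree.query(xyz[q], k=k_eff)
        per_k_thresh = []
        for k in ks:
            if k > k_eff:
                break
            pts = xyz[nbr[:, :k]]
            *_, mean_dev, _ = _batch_fit(pts, config.outlier_multiple)
            per_k_thresh.append(np.quantile(mean_dev, config.calibration_quantile))
        distances.append(float(np.median(np.linalg.norm(xyz, axis=1))))
        thresholds.append(float(np.max(per_k_thresh)))
    return NoiseCalibration(
        distances_m=np.asarray(distances), thresholds_m=np.asarray(thresholds)
    )


@dataclass(frozen=True)
class ScaleSelection:
    fit: PlaneFit | None
    selected_k: int
    status: int


def select_scale(
    point_index: int,
    cloud: PointCloud,
    config: ScaleConfig,
    calibration: NoiseCalibration,
    tree: cKDTree | None = None,
) -> ScaleSelection:
    """Minimum-reliable-scale selection for one query point.

    Walks the k schedule; the first scale whose mean deviation exceeds
    the calibrated threshold (at the query point's range) is the
    selected scale.  Degenerate scales are skipped.  See the module
    docstring for which fit is reported.
    """
    xyz = cloud.xyz
    if tree is None:
        tree = cKDTree(xyz)
    if len(xyz) < config.k_min:
        return ScaleSelection(fit=None, selected_k=0, status=STATUS_ISOLATED)
    point = xyz[point_index]
    k_eff = min(config.k_max, len(xyz))
    _, nbr = tree.query(point, k=k_eff)
    nbr = np.atleast_1d(nbr)
    threshold = float(calibration.lookup(np.linalg.norm(point)))

    prev: PlaneFit | None = None
    for k in k_schedule(config):
        if k > k_eff:
            break
        try:
            fit = fit_plane(xyz[nbr[:k]], config.outlier_multiple)
        except DegenerateNeighbourhoodError:
            continue
        if fit.eigen_ratio < config.degeneracy_ratio:
            continue
        if fit.mean_abs_deviation > threshold:
            reported = fit if (config.report_at_rejection or prev is None) else prev
            return ScaleSelection(fit=reported, selected_k=k, status=STATUS_REJECTED)
        prev = fit
    if prev is None:
        return ScaleSelection(fit=None, selected_k=0, status=STATUS_DEGENERATE)
    return ScaleSelection(fit=prev, selected_k=prev.k, status=STATUS_MAX_SCALE)


@dataclass
class NormalEstimates:
    """Per-point output of :func:`estimate_normals` (row-aligned with the
    input cloud)."""

    normals: np.ndarray  # (N, 3), NaN where no normal
    k: np.ndarray  # selected neighbourhood size, 0 where none
    status: np.ndarray  # STATUS_* codes
    mean_abs_deviation: np.ndarray
    eigen_ratio: np.ndarray

    def counts(self) -> dict[str, int]:
        return {
            name: int(np.sum(self.status == code)) for code, name in STATUS_NAMES.items()
        }


def estimate_normals(
    cloud: PointCloud,
    config: ScaleConfig,
    calibration: NoiseCalibration,
    query_indices: np.ndarray | None = None,
    chunk_size: int = 4096,
) -> NormalEstimates:
    """Adaptive-scale normals for every point (or a subset) of a cloud.

    Vectorized equivalent of calling :func:`select_scale` per point; all
    normals are oriented toward the sensor.  Per-point failures become
    status codes, never exceptions.
    """
    xyz = cloud.xyz
    n_total = len(xyz)
    q_idx = np.arange(n_total) if query_indices is None else np.asarray(query_indices)
    nq = len(q_idx)
    out = NormalEstimates(
        normals=np.full((nq, 3), np.nan),
        k=np.zeros(nq, dtype=np.int32),
        status=np.full(nq, STATUS_ISOLATED, dtype=np.int8),
        mean_abs_deviation=np.full(nq, np.nan),
        eigen_ratio=np.full(nq, np.nan),
    )
    if nq == 0 or n_total < config.k_min:
        return out

    tree = cKDTree(xyz)
    ks = [k for k in k_schedule(config) if k <= n_total]
    k_eff = ks[-1]
    thresholds = calibration.lookup(np.linalg.norm(xyz[q_idx], axis=1))

    for lo in range(0, nq, chunk_size):
        sl = slice(lo, min(lo + chunk_size, nq))
        pts_q = xyz[q_idx[sl]]
        thr = thresholds[sl]
        m = len(pts_q)
        _, nbr = tree.query(pts_q, k=k_eff)
        nbr = nbr.reshape(m, k_eff)

        active = np.ones(m, dtype=bool)
        have_prev = np.zeros(m, dtype=bool)
        prev_n = np.full((m, 3), np.nan)
        prev_k = np.zeros(m, dtype=np.int32)
        prev_dev = np.full(m, np.nan)
        prev_ratio = np.full(m, np.nan)
        sel_n = np.full((m, 3), np.nan)
        sel_k = np.zeros(m, dtype=np.int32)
        sel_dev = np.full(m, np.nan)
        sel_ratio = np.full(m, np.nan)
        status = np.full(m, STATUS_DEGENERATE, dtype=np.int8)
        done = np.zeros(m, dtype=bool)

        for k in ks:
            idx = np.flatnonzero(active & ~done)
            if idx.size == 0:
                break
            pts = xyz[nbr[idx, :k]]
            _, nrm, evals, dev, _ = _batch_fit(pts, config.outlier_multiple)
            with np.errstate(invalid="ignore", divide="ignore"):
                ratio = np.where(evals[:, 0] > 0, evals[:, 1] / evals[:, 0], 0.0)
            ok = ratio >= config.degeneracy_ratio
            rej = ok & (dev > thr[idx])
            keep = ok & ~rej

            r_idx = idx[rej]
            if r_idx.size:
                use_prev = have_prev[r_idx] & (not config.report_at_rejection)
                cur = ~use_prev
                sel_n[r_idx[cur]] = nrm[rej][cur]
                sel_dev[r_idx[cur]] = dev[rej][cur]
                sel_ratio[r_idx[cur]] = ratio[rej][cur]
                sel_n[r_idx[use_prev]] = prev_n[r_idx[use_prev]]
                sel_dev[r_idx[use_prev]] = prev_dev[r_idx[use_prev]]
                sel_ratio[r_idx[use_prev]] = prev_ratio[r_idx[use_prev]]
                sel_k[r_idx] = k
                status[r_idx] = STATUS_REJECTED
                done[r_idx] = True

            k_idx = idx[keep]
            if k_idx.size:
                prev_n[k_idx] = nrm[keep]
                prev_k[k_idx] = k
                prev_dev[k_idx] = dev[keep]
                prev_ratio[k_idx] = ratio[keep]
                have_prev[k_idx] = True

        final = ~done & have_prev
        sel_n[final] = prev_n[final]
        sel_k[final] = prev_k[final]
        sel_dev[final] = prev_dev[final]
        sel_ratio[final] = prev_ratio[final]
        status[final] = STATUS_MAX_SCALE

        # Orient toward the sensor at the origin: normal . point < 0.
        flip = np.einsum("ij,ij->i", sel_n, pts_q) > 0
        sel_n[flip] = -sel_n[flip]

        out.normals[sl] = sel_n
        out.k[sl] = sel_k
        out.status[sl] = status
        out.mean_abs_deviation[sl] = sel_dev
        out.eigen_ratio[sl] = sel_ratio
    return out
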