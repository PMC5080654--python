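"""Synthetic spherical LiDAR scans of parametric scenes.

The simulator emulates a tripod-mounted time-of-flight scanner at human
eye height (1.65 m): a full 360-degree azimuth sweep, elevations from 45
degrees above nadir to the zenith (the tripod footprint occludes lower
elevations), 2.2 arcmin angular sampling, 120 m maximum range and ~1 mm
RMS range noise.  Rendering happens on the equal-angle scan grid, exactly
as the instrument samples; consumers that need view-sphere-uniform
statistics must apply solid-angle weights downstream.

Scene archetypes:

``indoor``
    floor + ceiling (2.6 m) + four walls + furniture boxes
``outdoor-built``
    unbounded ground plane + building boxes
``outdoor-natural``
    unbounded ground plane + vertical cylinders (trunks) + spheroid
    clutter (foliage)

Every scan keeps a ground-truth normal map and primitive-id map alongside
the range/intensity rasters so downstream estimators can be scored.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import normalize

__all__ = [
    "SENSOR_HEIGHT_M",
    "CATEGORIES",
    "PlanePatch",
    "Box",
    "Cylinder",
    "Spheroid",
    "Mover",
    "SceneSpec",
    "ScanConfig",
    "SphericalScan",
    "PointCloud",
    "build_scene",
    "raycast",
    "make_scan_pair",
    "scan_to_points",
    "ray_directions",
]

SENSOR_HEIGHT_M = 1.65
CATEGORIES = ("indoor", "outdoor-built", "outdoor-natural")

_MISS = np.inf


@dataclass(frozen=True)
class PlanePatch:
    """Finite rectangular patch: center, unit normal, two in-plane axes."""

    center: np.ndarray
    normal: np.ndarray
    u_axis: np.ndarray
    v_axis: np.ndarray
    half_u: float
    half_v: float
    albedo: float = 0.5

    def intersect(self, dirs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        n = normalize(self.normal)
        denom = dirs @ n
        with np.errstate(divide="ignore", invalid="ignore"):
            t = (self.center @ n) / denom
        hit = (np.abs(denom) > 1e-12) & (t > 1e-9)
        p = dirs * np.where(np.isfinite(t), t, 0.0)[:, None]
        local = p - self.center
        hit &= np.abs(local @ normalize(self.u_axis)) <= self.half_u
        hit &= np.abs(local @ normalize(self.v_axis)) <= self.half_v
        t = np.where(hit, t, _MISS)
        normals = np.broadcast_to(n, dirs.shape)
        return t, normals


@dataclass(frozen=True)
class Box:
    """Axis-aligned box given by min/max corners."""

    lo: np.ndarray
    hi: np.ndarray
    albedo: float = 0.5

    def intersect(self, dirs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        lo = np.asarray(self.lo, dtype=float)
        hi = np.asarray(self.hi, dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            t_lo = lo / dirs
            t_hi = hi / dirs
        t_near = np.minimum(t_lo, t_hi)
        t_far = np.maximum(t_lo, t_hi)
        # Rays parallel to a slab: inside iff origin between the planes.
        par = np.abs(dirs) < 1e-15
        inside = (lo <= 0.0) & (0.0 <= hi)
        t_near = np.where(par, np.where(inside, -np.inf, np.inf), t_near)
        t_far = np.where(par, np.where(inside, np.inf, -np.inf), t_far)
        t_enter = t_near.max(axis=1)
        t_exit = t_far.min(axis=1)
        hit = (t_enter <= t_exit) & (t_enter > 1e-9)
        t = np.where(hit, t_enter, _MISS)
        # Entering face is the slab that produced t_enter.
        axis = np.argmax(t_near, axis=1)
        sign = -np.sign(np.take_along_axis(dirs, axis[:, None], axis=1)[:, 0])
        normals = np.zeros_like(dirs)
        normals[np.arange(len(dirs)), axis] = np.where(sign == 0.0, 1.0, sign)
        return t, normals


@dataclass(frozen=True)
class Cylinder:
    """Vertical circular cylinder (lateral surface only)."""

    cx: float
    cy: float
    radius: float
    z_lo: float
    z_hi: float
    albedo: float = 0.5

    def intersect(self, dirs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        dx, dy, dz = dirs[:, 0], dirs[:, 1], dirs[:, 2]
        a = dx**2 + dy**2
        b = -2.0 * (dx * self.cx + dy * self.cy)
        c = self.cx**2 + self.cy**2 - self.radius**2
        disc = b**2 - 4.0 * a * c
        with np.errstate(divide="ignore", invalid="ignore"):
            sq = np.sqrt(np.maximum(disc, 0.0))
            t1 = (-b - sq) / (2.0 * a)
            t2 = (-b + sq) / (2.0 * a)
        t = np.where(t1 > 1e-9, t1, np.where(t2 > 1e-9, t2, _MISS))
        t = np.where((disc >= 0.0) & (a > 1e-15), t, _MISS)
        z_hit = t * dz
        t = np.where((z_hit >= self.z_lo) & (z_hit <= self.z_hi), t, _MISS)
        p = dirs * np.where(np.isfinite(t), t, 0.0)[:, None]
        normals = np.zeros_like(dirs)
        normals[:, 0] = p[:, 0] - self.cx
        normals[:, 1] = p[:, 1] - self.cy
        nn = np.linalg.norm(normals, axis=1, keepdims=True)
        normals = np.divide(normals, nn, out=normals, where=nn > 0)
        return t, normals


@dataclass(frozen=True)
class Spheroid:
    """Axis-aligned spheroid: equatorial radius ``a``, polar radius ``b``."""

    center: np.ndarray
    a: float
    b: float
    albedo: float = 0.5

    def intersect(self, dirs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        scale = np.array([1.0 / self.a, 1.0 / self.a, 1.0 / self.b])
        d = dirs * scale
        o = -np.asarray(self.center, dtype=float) * scale
        a_q = np.sum(d * d, axis=1)
        b_q = 2.0 * np.sum(o * d, axis=1)
        c_q = float(o @ o) - 1.0
        disc = b_q**2 - 4.0 * a_q * c_q
        sq = np.sqrt(np.maximum(disc, 0.0))
        with np.errstate(divide="ignore", invalid="ignore"):
            t1 = (-b_q - sq) / (2.0 * a_q)
            t2 = (-b_q + sq) / (2.0 * a_q)
        t = np.where(t1 > 1e-9, t1, np.where(t2 > 1e-9, t2, _MISS))
        t = np.where(disc >= 0.0, t, _MISS)
        p = dirs * np.where(np.isfinite(t), t, 0.0)[:, None]
        normals = (p - self.center) * scale**2
        nn = np.linalg.norm(normals, axis=1, keepdims=True)
        normals = np.divide(normals, nn, out=normals, where=nn > 0)
        return t, normals


@dataclass(frozen=True)
class Mover:
    """A primitive present in only one of the two back-to-back scans."""

    primitive: object
    present_in_scan: int  # 1 or 2


@dataclass(frozen=True)
class SceneSpec:
    category: str
    primitives: tuple
    movers: tuple = ()
    seed: int = 0


@dataclass(frozen=True)
class ScanConfig:
    """Spherical scan geometry and noise model.

    Elevation is measured from nadir: 0 straight down, 90 horizon, 180
    zenith.  The default grid covers [45, 180] at 2.2 arcmin; tests use a
    much coarser step for runtime.
    """

    azimuth_span_deg: float = 360.0
    elevation_min_deg: float = 45.0
    elevation_max_deg: float = 180.0
    step_arcmin: float = 2.2
    max_range_m: float = 120.0
    range_noise_m: float = 0.001
    intensity_noise: float = 0.02
    low_intensity_fraction: float = 0.01

    def __post_init__(self):
        if self.step_arcmin <= 0:
            raise ValueError("angular step must be positive")
        if not (0.0 <= self.elevation_min_deg < self.elevation_max_deg <= 180.0):
            raise ValueError("elevation span must satisfy 0 <= lo < hi <= 180")
        if not (0.0 < self.azimuth_span_deg <= 360.0):
            raise ValueError("azimuth span must lie in (0, 360]")

    @property
    def azimuths_deg(self) -> np.ndarray:
        step = self.step_arcmin / 60.0
        n = int(round(self.azimuth_span_deg / step))
        return np.arange(n) * step

    @property
    def elevations_deg(self) -> np.ndarray:
        step = self.step_arcmin / 60.0
        n = int(np.floor((self.elevation_max_deg - self.elevation_min_deg) / step + 1e-9)) + 1
        return self.elevation_min_deg + np.arange(n) * step


@dataclass
class SphericalScan:
    """Raster of returns on an elevation x azimuth grid.

    ``range_m`` and ``intensity`` have shape (n_elevation, n_azimuth);
    NaN range means no return.  ``true_normals`` (same grid, trailing 3)
    and ``prim_id`` are simulator ground truth, absent for real data.
    """

    azimuths_deg: np.ndarray
    elevations_deg: np.ndarray
    range_m: np.ndarray
    intensity: np.ndarray
    sensor_height_m: float = SENSOR_HEIGHT_M
    max_range_m: float = 120.0
    true_normals: np.ndarray | None = None
    prim_id: np.ndarray | None = None
    removed: np.ndarray | None = None  # mask of returns deleted by cleaning

    @property
    def shape(self) -> tuple[int, int]:
        return self.range_m.shape

    def copy(self) -> "SphericalScan":
        return SphericalScan(
            azimuths_deg=self.azimuths_deg.copy(),
            elevations_deg=self.elevations_deg.copy(),
            range_m=self.range_m.copy(),
            intensity=self.intensity.copy(),
            sensor_height_m=self.sensor_height_m,
            max_range_m=self.max_range_m,
            true_normals=None if self.true_normals is None else self.true_normals.copy(),
            prim_id=None if self.prim_id is None else self.prim_id.copy(),
            removed=None if self.removed is None else self.removed.copy(),
        )


@dataclass
class PointCloud:
    """Unstructured view of a scan: one row per actual return."""

    xyz: np.ndarray
    intensity: np.ndarray
    view_dirs: np.ndarray
    elevations_deg: np.ndarray
    azimuths_deg: np.ndarray
    grid_index: np.ndarray  # (N, 2) = (row, col) into the scan raster
    true_normals: np.ndarray | None = None
    prim_id: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.xyz)

    def take(self, idx: np.ndarray) -> "PointCloud":
        """Row subset preserving all per-point attributes."""
        return PointCloud(
            xyz=self.xyz[idx],
            intensity=self.intensity[idx],
            view_dirs=self.view_dirs[idx],
            elevations_deg=self.elevations_deg[idx],
            azimuths_deg=self.azimuths_deg[idx],
            grid_index=self.grid_index[idx],
            true_normals=None if self.true_normals is None else self.true_normals[idx],
            prim_id=None if self.prim_id is None else self.prim_id[idx],
        )


def ray_directions(azimuths_deg: np.ndarray, elevations_deg: np.ndarray) -> np.ndarray:
    """Unit ray directions for a grid, shape (n_el, n_az, 3).

    Azimuth counter-clockwise from +X; elevation from nadir, so
    dir = (sin e cos a, sin e sin a, -cos e).
    """
    a = np.radians(np.asarray(azimuths_deg, dtype=float))[None, :]
    e = np.radians(np.asarray(elevations_deg, dtype=float))[:, None]
    return np.stack(
        [np.sin(e) * np.cos(a), np.sin(e) * np.sin(a), -np.cos(e) * np.ones_like(a)],
        axis=-1,
    )


def _ground(albedo: float = 0.55) -> PlanePatch:
    return PlanePatch(
        center=np.array([0.0, 0.0, -SENSOR_HEIGHT_M]),
        normal=np.array([0.0, 0.0, 1.0]),
        u_axis=np.array([1.0, 0.0, 0.0]),
        v_axis=np.array([0.0, 1.0, 0.0]),
        half_u=500.0,
        half_v=500.0,
        albedo=albedo,
    )


def _wall(cx, cy, normal, half_w, z_lo, z_hi, albedo=0.6) -> PlanePatch:
    n = normalize(np.asarray(normal, dtype=float))
    u = np.cross(np.array([0.0, 0.0, 1.0]), n)
    return PlanePatch(
        center=np.array([cx, cy, 0.5 * (z_lo + z_hi)]),
        normal=n,
        u_axis=normalize(u),
        v_axis=np.array([0.0, 0.0, 1.0]),
        half_u=half_w,
        half_v=0.5 * (z_hi - z_lo),
        albedo=albedo,
    )


def _mover_box(rng: np.random.Generator, scan_index: int) -> Mover:
    # Pedestrian/vehicle stand-in: a box 2-8 m away at a random azimuth.
    az = rng.uniform(0, 2 * np.pi)
    dist = rng.uniform(2.0, 8.0)
    cx, cy = dist * np.cos(az), dist * np.sin(az)
    w, d, h = rng.uniform(0.4, 1.8), rng.uniform(0.4, 1.8), rng.uniform(1.5, 2.0)
    box = Box(
        lo=np.array([cx - w / 2, cy - d / 2, -SENSOR_HEIGHT_M]),
        hi=np.array([cx + w / 2, cy + d / 2, -SENSOR_HEIGHT_M + h]),
        albedo=rng.uniform(0.3, 0.8),
    )
    return Mover(primitive=box, present_in_scan=scan_index)


def build_scene(category: str, rng_seed: int, n_movers: int = 0) -> SceneSpec:
    """Deterministically generate a parametric scene of one archetype."""
    if category not in CATEGORIES:
        raise ValueError(f"unknown scene category {category!r}; expected one of {CATEGORIES}")
    rng = np.random.default_rng(rng_seed)
    prims: list = []

    if category == "indoor":
        # Room dimensions; sensor is offset from the room center.
        half_x = rng.uniform(2.5, 4.5)
        half_y = rng.uniform(2.5, 4.5)
        ceiling_z = -SENSOR_HEIGHT_M + 2.6
        floor = PlanePatch(
            center=np.array([0.0, 0.0, -SENSOR_HEIGHT_M]),
            normal=np.array([0.0, 0.0, 1.0]),
            u_axis=np.array([1.0, 0.0, 0.0]),
            v_axis=np.array([0.0, 1.0, 0.0]),
            half_u=half_x,
            half_v=half_y,
            albedo=0.5,
        )
        ceiling = PlanePatch(
            center=np.array([0.0, 0.0, ceiling_z]),
            normal=np.array([0.0, 0.0, -1.0]),
            u_axis=np.array([1.0, 0.0, 0.0]),
            v_axis=np.array([0.0, 1.0, 0.0]),
            half_u=half_x,
            half_v=half_y,
            albedo=0.8,
        )
        prims += [floor, ceiling]
        prims += [
            _wall(half_x, 0.0, [-1, 0, 0], half_y, -SENSOR_HEIGHT_M, ceiling_z),
            _wall(-half_x, 0.0, [1, 0, 0], half_y, -SENSOR_HEIGHT_M, ceiling_z),
            _wall(0.0, half_y, [0, -1, 0], half_x, -SENSOR_HEIGHT_M, ceiling_z),
            _wall(0.0, -half_y, [0, 1, 0], half_x, -SENSOR_HEIGHT_M, ceiling_z),
        ]
        for _ in range(rng.integers(1, 4)):
            cx = rng.uniform(-half_x + 1.0, half_x - 1.0)
            cy = rng.uniform(-half_y + 1.0, half_y - 1.0)
            if np.hypot(cx, cy) < 1.0:  # keep clear of the tripod
                continue
            w, d, h = rng.uniform(0.4, 1.2, size=3)
            prims.append(
                Box(
                    lo=np.array([cx - w / 2, cy - d / 2, -SENSOR_HEIGHT_M]),
                    hi=np.array([cx + w / 2, cy + d / 2, -SENSOR_HEIGHT_M + h]),
                    albedo=rng.uniform(0.3, 0.8),
                )
            )
    elif category == "outdoor-built":
        prims.append(_ground())
        for _ in range(rng.integers(3, 8)):
            az = rng.uniform(0, 2 * np.pi)
            dist = rng.uniform(6.0, 40.0)
            cx, cy = dist * np.cos(az), dist * np.sin(az)
            w = rng.uniform(4.0, 15.0)
            d = rng.uniform(4.0, 15.0)
            h = rng.uniform(3.0, 12.0)
            prims.append(
                Box(
                    lo=np.array([cx - w / 2, cy - d / 2, -SENSOR_HEIGHT_M]),
                    hi=np.array([cx + w / 2, cy + d / 2, -SENSOR_HEIGHT_M + h]),
                    albedo=rng.uniform(0.3, 0.8),
                )
            )
    else:  # outdoor-natural
        prims.append(_ground())
        for _ in range(rng.integers(5, 16)):  # trunks
            az = rng.uniform(0, 2 * np.pi)
            dist = rng.uniform(3.0, 40.0)
            prims.append(
                Cylinder(
                    cx=dist * np.cos(az),
                    cy=dist * np.sin(az),
                    radius=rng.uniform(0.1, 0.5),
                    z_lo=-SENSOR_HEIGHT_M,
                    z_hi=-SENSOR_HEIGHT_M + rng.uniform(4.0, 12.0),
                    albedo=rng.uniform(0.2, 0.5),
                )
            )
        for _ in range(rng.integers(10, 31)):  # foliage clutter
            az = rng.uniform(0, 2 * np.pi)
            dist = rng.uniform(2.0, 30.0)
            a = rng.uniform(0.2, 1.5)
            prims.append(
                Spheroid(
                    center=np.array(
                        [
                            dist * np.cos(az),
                            dist * np.sin(az),
                            -SENSOR_HEIGHT_M + rng.uniform(a, 8.0),
                        ]
                    ),
                    a=a,
                    b=rng.uniform(0.2, 1.5),
                    albedo=rng.uniform(0.2, 0.6),
                )
            )

    movers = tuple(_mover_box(rng, 1 + int(i % 2)) for i in range(n_movers))
    return SceneSpec(category=category, primitives=tuple(prims), movers=movers, seed=rng_seed)


def raycast(
    scene: SceneSpec,
    config: ScanConfig,
    scan_index: int = 1,
    rng_seed: int | None = None,
) -> SphericalScan:
    """Render one spherical scan: nearest primitive hit per grid ray.

    Gaussian noise is added to range and intensity; movers are included
    only in their designated scan; the ground-truth normal map records
    the noiseless normal of the hit primitive.
    """
    if scan_index not in (1, 2):
        raise ValueError("scan_index must be 1 or 2")
    az = config.azimuths_deg
    el = config.elevations_deg
    dirs = ray_directions(az, el).reshape(-1, 3)

    prims = list(scene.primitives) + [
        m.primitive for m in scene.movers if m.present_in_scan == scan_index
    ]

    best_t = np.full(len(dirs), _MISS)
    best_n = np.zeros_like(dirs)
    best_id = np.full(len(dirs), -1, dtype=np.int32)
    albedos = np.array([p.albedo for p in prims]) if prims else np.ones(1)
    for i, prim in enumerate(prims):
        t, n = prim.intersect(dirs)
        closer = t < best_t
        best_t = np.where(closer, t, best_t)
        best_n[closer] = n[closer]
        best_id = np.where(closer, i, best_id)

    hit = np.isfinite(best_t) & (best_t <= config.max_range_m)
    rng = np.random.default_rng(rng_seed)

    rng_noise = rng.normal(0.0, config.range_noise_m, size=len(dirs))
    rr = np.where(hit, best_t + (rng_noise if config.range_noise_m > 0 else 0.0), np.nan)

    cos_inc = np.abs(np.sum(best_n * dirs, axis=1))
    inten = np.where(hit, albedos[np.clip(best_id, 0, None)] * cos_inc, 0.0)
    if config.intensity_noise > 0:
        inten = inten + rng.normal(0.0, config.intensity_noise, size=len(dirs))
    inten = np.clip(inten, 0.0, 1.0)
    # Exercise the downstream low-intensity filter on a known fraction.
    if config.low_intensity_fraction > 0 and hit.any():
        idx = np.flatnonzero(hit)
        n_low = int(round(config.low_intensity_fraction * len(idx)))
        low = rng.choice(idx, size=n_low, replace=False)
        inten[low] = rng.uniform(0.0, 0.005, size=n_low)
    inten = np.where(hit, inten, 0.0)

    shape = (len(el), len(az))
    return SphericalScan(
        azimuths_deg=az,
        elevations_deg=el,
        range_m=rr.reshape(shape),
        intensity=inten.reshape(shape),
        sensor_height_m=SENSOR_HEIGHT_M,
        max_range_m=config.max_range_m,
        true_normals=np.where(hit[:, None], best_n, np.nan).reshape(shape + (3,)),
        prim_id=np.where(hit, best_id, -1).astype(np.int32).reshape(shape),
    )


def make_scan_pair(
    scene: SceneSpec, config: ScanConfig, seeds: tuple[int, int] = (0, 1)
) -> tuple[SphericalScan, SphericalScan]:
    """Back-to-back scan pair: shared static content, independent noise,
    movers present only in their designated scan."""
    s1 = raycast(scene, config, scan_index=1, rng_seed=seeds[0])
    s2 = raycast(scene, config, scan_index=2, rng_seed=seeds[1])
    return s1, s2


def scan_to_points(scan: SphericalScan) -> PointCloud:
    """Convert a scan raster into a point cloud (one row per return).

    Cells flagged ``removed`` by the cleaning stage are excluded along
    with no-return cells.
    """
    dirs = ray_directions(scan.azimuths_deg, scan.elevations_deg)
    valid = np.isfinite(scan.range_m)
    if scan.removed is not None:
        valid &= ~scan.removed
    rows, cols = np.nonzero(valid)
    r = scan.range_m[rows, cols]
    d = dirs[rows, cols]
    return PointCloud(
        xyz=d * r[:, None],
        intensity=scan.intensity[rows, cols],
        view_dirs=d,
        elevations_deg=scan.elevations_deg[rows],
        azimuths_deg=scan.azimuths_deg[cols],
        grid_index=np.stack([rows, cols], axis=1),
        true_normals=None if scan.true_normals is None else scan.true_normals[rows, cols],
        prim_id=None if scan.prim_id is None else scan.prim_id[rows, cols],
    )
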