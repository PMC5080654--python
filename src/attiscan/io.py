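"""Readers and writers: PCD point clouds, scan containers, density files.

Point clouds use the PCD format with four scalar fields
(x, y, z, intensity); returns deleted by cleaning are written as all-zero
``[0, 0, 0, 0]`` records, the dataset's removed-point sentinel.  Scan
rasters are stored as a NumPy ``.npz`` container with a JSON text sidecar
describing grid geometry and conventions.  Densities are JSON with
explicit binning metadata.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .scenes import SphericalScan
from .stats import AttitudeDensity, BinningConfig

__all__ = [
    "PCDError",
    "read_pcd",
    "write_pcd",
    "save_scan",
    "load_scan",
    "write_density",
    "read_density",
]

_PCD_FIELDS = ("x", "y", "z", "intensity")


class PCDError(ValueError):
    """Malformed PCD header or payload."""


def write_pcd(
    path,
    xyz: np.ndarray,
    intensity: np.ndarray,
    removed: np.ndarray | None = None,
) -> None:
    """Write an ASCII PCD file; rows flagged ``removed`` become zeros."""
    xyz = np.asarray(xyz, dtype=np.float32)
    intensity = np.asarray(intensity, dtype=np.float32)
    if xyz.ndim != 2 or xyz.shape[1] != 3 or len(intensity) != len(xyz):
        raise ValueError("xyz must be (N, 3) with matching intensity")
    data = np.column_stack([xyz, intensity])
    if removed is not None:
        data[np.asarray(removed, dtype=bool)] = 0.0
    n = len(data)
    header = "\n".join(
        [
            "# .PCD v0.7 - Point Cloud Data file format",
            "VERSION 0.7",
            "FIELDS x y z intensity",
            "SIZE 4 4 4 4",
            "TYPE F F F F",
            "COUNT 1 1 1 1",
            f"WIDTH {n}",
            "HEIGHT 1",
            "VIEWPOINT 0 0 0 1 0 0 0",
            f"POINTS {n}",
            "DATA ascii",
        ]
    )
    with open(path, "w") as fh:
        fh.write(header + "\n")
        np.savetxt(fh, data, fmt="%.9g")


def read_pcd(path) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Read an ASCII or binary PCD with x/y/z/intensity float fields.

    Returns ``(xyz, intensity, removed)``; ``removed`` marks all-zero
    sentinel records.
    """
    header: dict[str, list[str]] = {}
    with open(path, "rb") as fh:
        while True:
            line = fh.readline()
            if not line:
                raise PCDError("truncated PCD header")
            text = line.decode("ascii", errors="replace").strip()
            if text.startswith("#") or not text:
                continue
            key, *vals = text.split()
            header[key.upper()] = vals
            if key.upper() == "DATA":
                break
        for req in ("FIELDS", "TYPE", "SIZE", "POINTS", "DATA"):
            if req not in header:
                raise PCDError(f"PCD header missing {req}")
        fields = tuple(f.lower() for f in header["FIELDS"])
        if fields != _PCD_FIELDS:
            raise PCDError(f"expected fields {_PCD_FIELDS}, found {fields}")
        if header["TYPE"] != ["F"] * 4 or header["SIZE"] != ["4"] * 4:
            raise PCDError("expected four float32 fields")
        n = int(header["POINTS"][0])
        mode = header["DATA"][0].lower()
        if mode == "ascii":
            data = np.loadtxt(fh, dtype=np.float64, ndmin=2)
        elif mode == "binary":
            raw = fh.read(n * 16)
            if len(raw) < n * 16:
                raise PCDError("binary payload shorter than POINTS")
            data = np.frombuffer(raw, dtype="<f4").reshape(n, 4).astype(np.float64)
        else:
            raise PCDError(f"unsupported DATA mode {mode!r}")
    if len(data) != n:
        raise PCDError(f"POINTS says {n} but payload has {len(data)} records")
    removed = (data == 0.0).all(axis=1)
    return data[:, :3], data[:, 3], removed


def save_scan(path, scan: SphericalScan) -> None:
    """Scan container: ``.npz`` arrays plus a ``.json`` text sidecar."""
    path = Path(path)
    arrays = {
        "azimuths_deg": scan.azimuths_deg,
        "elevations_deg": scan.elevations_deg,
        "range_m": scan.range_m,
        "intensity": scan.intensity,
    }
    for name in ("true_normals", "prim_id", "removed"):
        val = getattr(scan, name)
        if val is not None:
            arrays[name] = val
    np.savez_compressed(path, **arrays)
    sidecar = {
        "format": "attiscan spherical scan v1",
        "conventions": {
            "frame": "sensor at origin, +Z up, azimuth CCW from +X",
            "elevation": "degrees from nadir (0 down, 90 horizon, 180 zenith)",
            "range": "metres, NaN = no return",
        },
        "sensor_height_m": scan.sensor_height_m,
        "max_range_m": scan.max_range_m,
        "shape": list(scan.shape),
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))


def load_scan(path) -> SphericalScan:
    path = Path(path)
    with np.load(path) as z:
        arrays = {k: z[k] for k in z.files}
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    return SphericalScan(
        azimuths_deg=arrays["azimuths_deg"],
        elevations_deg=arrays["elevations_deg"],
        range_m=arrays["range_m"],
        intensity=arrays["intensity"],
        sensor_height_m=float(meta["sensor_height_m"]),
        max_range_m=float(meta["max_range_m"]),
        true_normals=arrays.get("true_normals"),
        prim_id=arrays.get("prim_id"),
        removed=arrays.get("removed"),
    )


def write_density(path, density: AttitudeDensity) -> None:
    """Density export: JSON with binning metadata and raw histograms."""
    b = density.binning
    payload = {
        "category": density.category,
        "band": density.band,
        "weighting": density.weighting,
        "n_scenes": density.n_scenes,
        "weight_total": density.weight_total,
        "binning": {
            "plane_bin_deg": b.plane_bin_deg,
            "tilt_bin_deg": b.tilt_bin_deg,
            "slant_bin_deg": b.slant_bin_deg,
            "world_slant_bin_deg": b.world_slant_bin_deg,
        },
        "joint": density.joint.tolist(),
        "tilt": density.tilt.tolist(),
        "slant": density.slant.tolist(),
        "world": density.world.tolist(),
    }
    Path(path).write_text(json.dumps(payload))


def read_density(path) -> AttitudeDensity:
    d = json.loads(Path(path).read_text())
    return AttitudeDensity(
        binning=BinningConfig(**d["binning"]),
        joint=np.asarray(d["joint"]),
        tilt=np.asarray(d["tilt"]),
        slant=np.asarray(d["slant"]),
        world=np.asarray(d["world"]),
        weight_total=d["weight_total"],
        n_scenes=d["n_scenes"],
        category=d["category"],
        band=d["band"],
        weighting=d["weighting"],
    )
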