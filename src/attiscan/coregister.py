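"""Rigid alignment of two sensor frames from three target correspondences.

Three calibration targets are seen as 3D positions ``l_i`` in frame A and
as unit directions ``s_hat_i`` in frame B (a camera knows only bearings).
The rigid transform is estimated by minimizing the sum of squared
deviations between the transformed, normalized frame-A vectors and the
frame-B unit vectors:

    cost(R, T) = sum_i || normalize(R (l_i + T)) - s_hat_i ||^2

(the ``"Rl+T"`` convention, normalize(R l_i + T'), is available via the
``convention`` flag; the two parameterizations reach the same optimum
with T' = R T).  The rotation is initialized with the closed-form
orthogonal (Kabsch/Wahba) alignment of the two direction sets at T = 0,
then jointly refined over axis-angle rotation and translation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares
from scipy.spatial.transform import Rotation

from .geometry import normalize

__all__ = [
    "TargetSet",
    "RigidTransform",
    "DegenerateTargetsError",
    "estimate_rigid",
    "apply_transform",
    "read_targets",
    "write_transform",
    "read_transform",
]


class DegenerateTargetsError(ValueError):
    """Target directions are (near-)collinear; rotation unobservable."""


@dataclass(frozen=True)
class TargetSet:
    """Three targets: positions in frame A, unit directions in frame B."""

    positions: np.ndarray  # (3, 3) l_i, metres
    directions: np.ndarray  # (3, 3) s_hat_i, unit vectors

    def __post_init__(self):
        p = np.asarray(self.positions, dtype=float)
        d = np.asarray(self.directions, dtype=float)
        if p.shape != (3, 3) or d.shape != (3, 3):
            raise ValueError("need exactly three 3D targets in each frame")
        object.__setattr__(self, "positions", p)
        object.__setattr__(self, "directions", normalize(d))
        d0, d1, d2 = self.directions
        if (
            np.linalg.norm(np.cross(d0, d1)) < 1e-8
            and np.linalg.norm(np.cross(d0, d2)) < 1e-8
        ):
            raise DegenerateTargetsError("target directions are collinear")


@dataclass(frozen=True)
class RigidTransform:
    rotation: np.ndarray  # (3, 3), orthonormal, det +1
    translation: np.ndarray  # (3,), metres

    def __post_init__(self):
        r = np.asarray(self.rotation, dtype=float)
        if not np.allclose(r.T @ r, np.eye(3), atol=1e-9) or np.linalg.det(r) < 0:
            raise ValueError("rotation must be orthonormal with det +1")
        object.__setattr__(self, "rotation", r)
        object.__setattr__(self, "translation", np.asarray(self.translation, dtype=float))

    def inverse(self) -> "RigidTransform":
        # y = R(x + T)  =>  x = R^T y - T
        return RigidTransform(
            rotation=self.rotation.T, translation=-self.rotation @ self.translation
        )

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Transform applying ``other`` first, then ``self``."""
        # self(other(x)) = R1 (R2 (x + T2) + T1) = (R1 R2)(x + T2 + R2^T T1)
        return RigidTransform(
            rotation=self.rotation @ other.rotation,
            translation=other.translation + other.rotation.T @ self.translation,
        )

    def as_matrix(self) -> np.ndarray:
        m = np.eye(4)
        m[:3, :3] = self.rotation
        m[:3, 3] = self.rotation @ self.translation
        return m


def _residuals(params: np.ndarray, targets: TargetSet, convention: str) -> np.ndarray:
    rot = Rotation.from_rotvec(params[:3]).as_matrix()
    t = params[3:]
    if convention == "R(l+T)":
        v = (targets.positions + t) @ rot.T
    elif convention == "Rl+T":
        v = targets.positions @ rot.T + t
    else:
        raise ValueError(f"unknown convention {convention!r}")
    return (normalize(v) - targets.directions).ravel()


def estimate_rigid(
    targets: TargetSet, convention: str = "R(l+T)"
) -> tuple[RigidTransform, float]:
    """Estimate the frame A -> frame B rigid transform.

    Returns ``(transform, residual)`` where residual is the optimal sum
    of squared direction deviations.  Raises
    :class:`DegenerateTargetsError` on collinear geometry.
    """
    # Closed-form Wahba/Kabsch initialization on the direction sets.
    a = normalize(targets.positions)
    b = targets.directions
    h = a.T @ b
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    r0 = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    x0 = np.concatenate([Rotation.from_matrix(r0).as_rotvec(), np.zeros(3)])

    result = least_squares(
        _residuals, x0, args=(targets, convention), method="lm",
        xtol=1e-15, ftol=1e-15, gtol=1e-15,
    )
    if not result.success:
        raise RuntimeError(f"rigid-transform refinement failed: {result.message}")
    rot = Rotation.from_rotvec(result.x[:3]).as_matrix()
    t = result.x[3:]
    if convention == "Rl+T":
        # Store canonically as y = R(x + T).
        t = rot.T @ t
    residual = float(2.0 * result.cost)  # least_squares cost is 1/2 sum r^2
    return RigidTransform(rotation=rot, translation=t), residual


def apply_transform(points: np.ndarray, transform: RigidTransform) -> np.ndarray:
    """Rigidly map (N, 3) points from frame A to frame B: R (x + T)."""
    p = np.asarray(points, dtype=float)
    return (p + transform.translation) @ transform.rotation.T


def read_targets(path) -> TargetSet:
    """Plain-text target file: three lines of ``ax ay az bx by bz``
    (frame-A position, frame-B direction)."""
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if line:
                rows.append([float(x) for x in line.split()])
    arr = np.asarray(rows, dtype=float)
    if arr.shape != (3, 6):
        raise ValueError("target file must contain three rows of six numbers")
    return TargetSet(positions=arr[:, :3], directions=arr[:, 3:])


def write_transform(path, transform: RigidTransform) -> None:
    """Write a 4x4 homogeneous matrix as plain text."""
    np.savetxt(path, transform.as_matrix(), fmt="%.12g")


def read_transform(path) -> RigidTransform:
    m = np.loadtxt(path)
    if m.shape != (4, 4):
        raise ValueError("transform file must be a 4x4 matrix")
    rot = m[:3, :3]
    return RigidTransform(rotation=rot, translation=rot.T @ m[:3, 3])
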