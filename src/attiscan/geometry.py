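"""Egocentric attitude geometry.

Conventions (fixed repo-wide):

* World frame: sensor at origin, +Z is world up.  The scanner self-levels,
  so world up and sensor up coincide.
* View vector: unit ray from the sensor to the surface point (egocentric
  z-axis).
* Egocentric frame: x-axis horizontal in world coordinates, y-axis
  orthogonal to x and z with a positive upward component.
* Slant ``phi``: angle in [0, 90] degrees between the viewer-facing surface
  normal and the anti-view direction (0 = frontoparallel, 90 = edge-on).
* Tilt ``theta``: angle in [0, 360) degrees of the normal's image-plane
  projection, clockwise from the egocentric upward axis.  A floor surface
  has tilt 0, a ceiling 180, left/right walls 90/270.
* World slant: angle of the viewer-facing normal from world up, in
  [0, 180] degrees (0 = horizontal seen from above, 180 = from below).

Angles cross API boundaries in degrees; internal trigonometry is in
radians.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "WORLD_UP",
    "DEGENERATE_VIEW_TOL_DEG",
    "UNDEFINED_TILT_TOL_DEG",
    "DegenerateViewError",
    "EgocentricFrame",
    "SlantTilt",
    "normalize",
    "egocentric_frame",
    "slant_tilt",
    "slant_tilt_arrays",
    "normal_from_slant_tilt",
    "world_slant",
    "equal_area_map",
    "equal_area_radius",
    "maxent_density",
    "maxent_slant_marginal",
    "maxent_conditional_given_tilt",
    "sample_maxent",
]

WORLD_UP = np.array([0.0, 0.0, 1.0])

#: Views within this angle of world +/-vertical have no defined horizontal
#: x-axis; frame construction raises.
DEGENERATE_VIEW_TOL_DEG = 0.01

#: Below this slant the normal's image-plane projection vanishes and tilt
#: is reported as 0 with the undefined flag set.
UNDEFINED_TILT_TOL_DEG = 0.01


class DegenerateViewError(ValueError):
    """View direction (anti)parallel to world vertical: tilt is undefined."""


def normalize(v: np.ndarray) -> np.ndarray:
    """Return ``v`` scaled to unit Euclidean norm (last axis)."""
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v, axis=-1, keepdims=True)
    return v / n


@dataclass(frozen=True)
class EgocentricFrame:
    """Right-handed orthonormal triad attached to a view direction.

    ``x_axis`` is horizontal in world coordinates, ``y_axis`` has a
    positive upward component, ``z_axis`` is the view direction.
    """

    x_axis: np.ndarray
    y_axis: np.ndarray
    z_axis: np.ndarray


@dataclass(frozen=True)
class SlantTilt:
    """Egocentric attitude: slant and tilt in degrees.

    ``tilt_defined`` is False when the slant is below
    :data:`UNDEFINED_TILT_TOL_DEG`; tilt is then reported as 0.
    """

    slant: float
    tilt: float
    tilt_defined: bool = True


def egocentric_frame(view_dir: np.ndarray) -> EgocentricFrame:
    """Build the egocentric frame for a unit view direction.

    Raises :class:`DegenerateViewError` when ``view_dir`` is within
    :data:`DEGENERATE_VIEW_TOL_DEG` of world +/-vertical.
    """
    z = normalize(np.asarray(view_dir, dtype=float))
    cos_tol = np.cos(np.radians(DEGENERATE_VIEW_TOL_DEG))
    if abs(float(z @ WORLD_UP)) >= cos_tol:
        raise DegenerateViewError(
            "view direction is (anti)parallel to world vertical; "
            "the egocentric frame is undefined"
        )
    # Gram-Schmidt world up against the view direction: y is the in-plane
    # upward axis, x = y x z is horizontal and completes a right-handed triad.
    y = normalize(WORLD_UP - (WORLD_UP @ z) * z)
    x = np.cross(y, z)
    return EgocentricFrame(x_axis=x, y_axis=y, z_axis=z)


def slant_tilt(normal: np.ndarray, frame: EgocentricFrame) -> SlantTilt:
    """Egocentric slant/tilt of a viewer-facing unit normal in ``frame``."""
    n = normalize(np.asarray(normal, dtype=float))
    cos_phi = float(np.clip(-(n @ frame.z_axis), -1.0, 1.0))
    phi = float(np.degrees(np.arccos(cos_phi)))
    if phi < UNDEFINED_TILT_TOL_DEG:
        return SlantTilt(slant=phi, tilt=0.0, tilt_defined=False)
    # Image-plane projection; clockwise from the upward axis means rotating
    # from +y toward +x as seen by the viewer.
    theta = float(np.degrees(np.arctan2(n @ frame.x_axis, n @ frame.y_axis)))
    return SlantTilt(slant=phi, tilt=theta % 360.0, tilt_defined=True)


def slant_tilt_arrays(
    normals: np.ndarray, view_dirs: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized slant/tilt for (N, 3) normals against (N, 3) view dirs.

    Returns ``(slant_deg, tilt_deg, tilt_defined)``.  Rows whose view
    direction is within :data:`DEGENERATE_VIEW_TOL_DEG` of world vertical
    keep their slant (it only needs the view vector) but get NaN tilt and
    ``tilt_defined`` False.
    """
    v = normalize(np.asarray(view_dirs, dtype=float))
    n = normalize(np.asarray(normals, dtype=float))
    up_dot = v @ WORLD_UP
    degenerate = np.abs(up_dot) >= np.cos(np.radians(DEGENERATE_VIEW_TOL_DEG))

    y = WORLD_UP - up_dot[:, None] * v
    with np.errstate(invalid="ignore", divide="ignore"):
        y = y / np.linalg.norm(y, axis=1, keepdims=True)
    x = np.cross(y, v)

    cos_phi = np.clip(-np.sum(n * v, axis=1), -1.0, 1.0)
    slant = np.degrees(np.arccos(cos_phi))
    tilt = np.degrees(np.arctan2(np.sum(n * x, axis=1), np.sum(n * y, axis=1))) % 360.0

    defined = slant >= UNDEFINED_TILT_TOL_DEG
    tilt = np.where(defined, tilt, 0.0)
    tilt = np.where(degenerate, np.nan, tilt)
    return slant, tilt, defined & ~degenerate


def normal_from_slant_tilt(st: SlantTilt, frame: EgocentricFrame) -> np.ndarray:
    """Inverse of :func:`slant_tilt`: viewer-facing unit normal with the
    given attitude in ``frame``."""
    phi = np.radians(st.slant)
    theta = np.radians(st.tilt)
    return (
        np.sin(phi) * np.sin(theta) * frame.x_axis
        + np.sin(phi) * np.cos(theta) * frame.y_axis
        - np.cos(phi) * frame.z_axis
    )


def world_slant(normal: np.ndarray) -> np.ndarray:
    """Gravity-referenced slant in degrees: arccos(normal . world up).

    Accepts a single vector or an (N, 3) array.
    """
    n = normalize(np.asarray(normal, dtype=float))
    cos_a = np.clip(n @ WORLD_UP, -1.0, 1.0)
    return np.degrees(np.arccos(cos_a))


def equal_area_radius(slant_deg: np.ndarray) -> np.ndarray:
    """Radial coordinate phi' = sqrt(2 (1 - cos phi)) of the equal-area map.

    Slightly compressive: phi' ~= phi for small slants, falling to 90% of
    phi at phi = 90 degrees.
    """
    phi = np.radians(np.asarray(slant_deg, dtype=float))
    return np.sqrt(2.0 * (1.0 - np.cos(phi)))


def equal_area_map(
    slant_deg: np.ndarray, tilt_deg: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Map (slant, tilt) in degrees to the area-preserving plane.

    Tilt is a clockwise polar angle from the -y axis, so a floor surface
    (tilt 0) maps to the bottom of the plot:

        x = phi' sin(theta),  y = -phi' cos(theta)

    The map has unit Jacobian with respect to the hemisphere area element
    dA = sin(phi) dphi dtheta.
    """
    r = equal_area_radius(slant_deg)
    theta = np.radians(np.asarray(tilt_deg, dtype=float))
    return r * np.sin(theta), -r * np.cos(theta)


def maxent_density(slant_deg: np.ndarray, tilt_deg: np.ndarray = 0.0) -> np.ndarray:
    """Maximum-entropy (random-world) density of observed attitude.

    Uniform normals on the visible hemisphere weighted by cos-phi
    foreshortening give ``p(phi, theta) = sin(phi) cos(phi) / pi`` in
    (phi, theta) radian measure; it integrates to 1 over
    phi in [0, pi/2], theta in [0, 2 pi).  Independent of tilt.
    """
    phi = np.radians(np.asarray(slant_deg, dtype=float))
    return np.sin(phi) * np.cos(phi) / np.pi + 0.0 * np.asarray(tilt_deg, dtype=float)


def maxent_slant_marginal(slant_deg: np.ndarray) -> np.ndarray:
    """Slant density sin(2 phi) after marginalizing tilt (radian measure).

    Peaks at 45 degrees and vanishes at 0 and 90.
    """
    phi = np.radians(np.asarray(slant_deg, dtype=float))
    return np.sin(2.0 * phi)


def maxent_conditional_given_tilt(slant_deg: np.ndarray) -> np.ndarray:
    """Slant density cos(phi) at fixed tilt (radian measure)."""
    phi = np.radians(np.asarray(slant_deg, dtype=float))
    return np.cos(phi)


def sample_maxent(n: int, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Draw (slant, tilt) degrees from the foreshortened random-world model.

    Inverse-CDF in slant: P(phi <= x) = sin^2(x), so phi = arcsin(sqrt(u));
    tilt is uniform.
    """
    u = rng.random(n)
    phi = np.degrees(np.arcsin(np.sqrt(u)))
    theta = rng.random(n) * 360.0
    return phi, theta
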