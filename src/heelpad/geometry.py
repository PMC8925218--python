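"""Heel-pad thickness from plate/calcaneus geometry.

The measurement setup marks the ground plane with three steel balls resting
on the force plate: the plane through their centers is parallel to the plate
at a height of one ball radius. Per frame, the calcaneus is available as a
3D point cloud, and the heel-pad thickness is the minimum signed distance
from the cloud to the ball-center plane plus the ball radius — i.e. the gap
between the lowest bone point and the plate surface, filled by the fat pad.

Distances are signed along the plane normal (oriented from the plate toward
the foot), so a noisy point below the plate surface reduces the thickness
estimate instead of silently inflating it. All lengths are millimetres.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.typing import ArrayLike, NDArray

from .errors import DegenerateGeometryError, EmptyInputError, NoContactError

__all__ = [
    "Plane",
    "GeometryScene",
    "plane_from_balls",
    "heel_pad_thickness",
    "detect_contact_frame",
    "primary_thickness",
]


@dataclass(frozen=True)
class Plane:
    """A plane ``{x : (x - point) . normal = 0}`` with unit normal."""

    point: NDArray[np.float64]
    normal: NDArray[np.float64]

    def __post_init__(self) -> None:
        object.__setattr__(self, "point", np.asarray(self.point, dtype=float))
        n = np.asarray(self.normal, dtype=float)
        if abs(np.linalg.norm(n) - 1.0) > 1e-9:
            raise ValueError("plane normal must be unit length")
        object.__setattr__(self, "normal", n)

    def signed_distance(self, points: ArrayLike) -> NDArray[np.float64]:
        """Signed distance of each point along the normal (positive = foot side)."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return (pts - self.point) @ self.normal


@dataclass
class GeometryScene:
    """Ball markers plus a per-frame calcaneus point cloud.

    Attributes
    ----------
    ball_centers : (3, 3) array, mm
    ball_radius : float, mm
    frames : list of (time_s, (n, 3) point cloud) tuples
    plate_tilt_deg : float
        Tilt applied rigidly to the whole scene when it was rendered
        (bookkeeping only; the analysis never reads it).
    """

    ball_centers: NDArray[np.float64]
    ball_radius: float
    frames: list[tuple[float, NDArray[np.float64]]] = field(default_factory=list)
    plate_tilt_deg: float = 0.0

    def __post_init__(self) -> None:
        self.ball_centers = np.asarray(self.ball_centers, dtype=float)
        if self.ball_centers.shape != (3, 3):
            raise ValueError("expected exactly 3 ball centers (3x3 array)")
        if self.ball_radius <= 0:
            raise ValueError("ball_radius must be positive")
        _min_altitude(self.ball_centers)  # raises if collinear
        for t, cloud in self.frames:
            if np.asarray(cloud).size == 0:
                raise EmptyInputError(f"empty point cloud at frame t={t}")


def _min_altitude(centers: NDArray[np.float64]) -> float:
    """Minimum triangle altitude of the three centers; raises if degenerate."""
    a, b, c = centers
    cross = np.cross(b - a, c - a)
    area2 = np.linalg.norm(cross)  # twice the triangle area
    longest = max(
        np.linalg.norm(b - a), np.linalg.norm(c - b), np.linalg.norm(a - c)
    )
    if longest == 0.0:
        raise DegenerateGeometryError(
            "duplicate ball centers (minimum altitude 0 mm)"
        )
    alt = area2 / longest
    if alt < 1e-9:
        raise DegenerateGeometryError(
            f"collinear ball centers (minimum altitude {alt:.3e} mm)"
        )
    return alt


def plane_from_balls(
    centers: ArrayLike,
    radius: float,
    up_hint: ArrayLike = (0.0, 0.0, 1.0),
) -> Plane:
    """Plane through three ball centers, normal oriented plate-to-foot.

    The balls rest on the plate, so the plane sits one `radius` above the
    plate surface and parallel to it. The plane itself does not know which
    side the plate is on; `up_hint` (default +z, the lab vertical) picks the
    foot-facing orientation of the normal.

    Raises
    ------
    DegenerateGeometryError
        If the centers are collinear or duplicated (message reports the
        triangle's minimum altitude).
    """
    centers = np.asarray(centers, dtype=float)
    if centers.shape != (3, 3):
        raise ValueError("expected three 3-vectors")
    _min_altitude(centers)
    a, b, c = centers
    n = np.cross(b - a, c - a)
    n = n / np.linalg.norm(n)
    hint = np.asarray(up_hint, dtype=float)
    if float(n @ hint) < 0:
        n = -n
    return Plane(point=a, normal=n)


def heel_pad_thickness(cloud: ArrayLike, plane: Plane, radius: float) -> float:
    """Minimum signed cloud-to-plane distance plus the ball radius, mm.

    May be negative if points penetrate the plate (reported, not clamped).
    """
    pts = np.atleast_2d(np.asarray(cloud, dtype=float))
    if pts.size == 0:
        raise EmptyInputError("empty point cloud")
    return float(np.min(plane.signed_distance(pts))) + float(radius)


def detect_contact_frame(
    force: ArrayLike, threshold: float, min_consecutive: int = 1
) -> int:
    """First frame index where force stays >= threshold for min_consecutive frames.

    Raises
    ------
    NoContactError
        If no window of `min_consecutive` frames qualifies.
    """
    f = np.asarray(force, dtype=float)
    if f.size == 0:
        raise EmptyInputError("empty force series")
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if min_consecutive < 1:
        raise ValueError("min_consecutive must be >= 1")
    above = f >= threshold
    for i in range(f.size - min_consecutive + 1):
        if above[i : i + min_consecutive].all():
            return i
    raise NoContactError(
        f"no run of {min_consecutive} frame(s) with force >= {threshold} N"
    )


def primary_thickness(
    thickness_or_scene: ArrayLike | GeometryScene,
    contact_index: int,
    plane: Plane | None = None,
    radius: float | None = None,
) -> float:
    """Heel-pad thickness at the frame of initial heel-plate contact, mm.

    Accepts either a per-frame thickness channel, or a
    :class:`GeometryScene` (with `plane`; `radius` defaults to the scene's
    ball radius), in which case the thickness is computed from the contact
    frame's point cloud.
    """
    if isinstance(thickness_or_scene, GeometryScene):
        scene = thickness_or_scene
        if plane is None:
            plane = plane_from_balls(scene.ball_centers, scene.ball_radius)
        if radius is None:
            radius = scene.ball_radius
        if not 0 <= contact_index < len(scene.frames):
            raise IndexError(f"contact_index {contact_index} out of range")
        _, cloud = scene.frames[contact_index]
        return heel_pad_thickness(cloud, plane, radius)
    thickness = np.asarray(thickness_or_scene, dtype=float)
    if thickness.size == 0:
        raise EmptyInputError("empty thickness channel")
    if not 0 <= contact_index < thickness.size:
        raise IndexError(f"contact_index {contact_index} out of range")
    return float(thickness[contact_index])


def scene_thickness_channel(scene: GeometryScene, plane: Plane | None = None) -> NDArray[np.float64]:
    """Per-frame thickness computed from the scene's point clouds, mm."""
    if plane is None:
        plane = plane_from_balls(scene.ball_centers, scene.ball_radius)
    return np.array(
        [heel_pad_thickness(cloud, plane, scene.ball_radius) for _, cloud in scene.frames]
    )
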