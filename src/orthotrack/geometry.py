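"""Exact 3-D primitives: rigid poses, planes, angles and point-set registration.

Conventions used throughout the package:

* Quaternions are scalar-first ``(w, x, y, z)``, unit-norm, and represent
  **active** rotations of points expressed in a fixed right-handed lab frame.
* Positions are in metres; angles cross the API boundary in **degrees** and
  are handled in radians internally.
* Dot products are clamped to ``[-1, 1]`` before any arc function.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

#: Default numerical tolerance for unit-norm / orthogonality checks.
TOL = 1e-9


class GeometryError(ValueError):
    """Degenerate geometric input (zero vector, collinear points, ...)."""


class InvalidPoseError(GeometryError):
    """Quaternion norm too far from 1 to be a rigid-body rotation."""


def _as_vec3(v) -> np.ndarray:
    a = np.asarray(v, dtype=float)
    if a.shape != (3,):
        raise GeometryError(f"expected a 3-vector, got shape {a.shape}")
    return a


def unit(v) -> np.ndarray:
    """Return ``v`` normalised to unit length.

    Raises
    ------
    GeometryError
        If ``v`` has (near-)zero norm.
    """
    a = _as_vec3(v)
    n = np.linalg.norm(a)
    if n < 1e-12:
        raise GeometryError("zero-norm vector cannot be normalised")
    return a / n


@dataclass(frozen=True)
class RigidPose:
    """Rotation + translation of a tracked body: ``x_lab = R x_body + t``.

    Parameters
    ----------
    quaternion : array-like, shape (4,)
        Unit quaternion, scalar-first ``(w, x, y, z)``.
    translation : array-like, shape (3,)
        Lab-frame position of the body origin, metres.
    """

    quaternion: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        q = np.asarray(self.quaternion, dtype=float)
        t = _as_vec3(self.translation)
        if q.shape != (4,):
            raise InvalidPoseError(f"quaternion must have 4 components, got {q.shape}")
        n = np.linalg.norm(q)
        if abs(n - 1.0) > 1e-6:
            raise InvalidPoseError(f"quaternion norm {n:.3e} differs from 1 beyond tolerance")
        q = q / n
        if q[0] < 0:  # canonical hemisphere, w >= 0
            q = -q
        object.__setattr__(self, "quaternion", q)
        object.__setattr__(self, "translation", t)

    # -- constructors ------------------------------------------------------
    @classmethod
    def identity(cls) -> "RigidPose":
        return cls(np.array([1.0, 0.0, 0.0, 0.0]), np.zeros(3))

    @classmethod
    def from_rotation(cls, rot: Rotation, translation=(0.0, 0.0, 0.0)) -> "RigidPose":
        return cls(rot.as_quat(scalar_first=True), np.asarray(translation, dtype=float))

    @classmethod
    def random(cls, rng: np.random.Generator, max_translation: float = 0.5) -> "RigidPose":
        rot = Rotation.random(rng=rng)
        t = rng.uniform(-max_translation, max_translation, size=3)
        return cls.from_rotation(rot, t)

    # -- algebra -----------------------------------------------------------
    @property
    def rotation(self) -> Rotation:
        return Rotation.from_quat(self.quaternion, scalar_first=True)

    def apply(self, points) -> np.ndarray:
        """Map body-frame point(s) to the lab frame."""
        return self.rotation.apply(points) + self.translation

    def apply_vector(self, vectors) -> np.ndarray:
        """Rotate free vector(s) (directions are translation-invariant)."""
        return self.rotation.apply(vectors)

    def inverse(self) -> "RigidPose":
        rinv = self.rotation.inv()
        return RigidPose.from_rotation(rinv, -rinv.apply(self.translation))


def compose(p1: RigidPose, p2: RigidPose) -> RigidPose:
    """Composite pose: applying the result equals applying ``p2`` then ``p1``."""
    rot = p1.rotation * p2.rotation
    return RigidPose.from_rotation(rot, p1.apply(p2.translation))


@dataclass(frozen=True)
class Plane:
    """Oriented plane given by a unit normal and a point on the plane."""

    normal: np.ndarray
    point: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        object.__setattr__(self, "normal", unit(self.normal))
        object.__setattr__(self, "point", _as_vec3(self.point))

    def signed_distance(self, p) -> float:
        return float(np.dot(_as_vec3(p) - self.point, self.normal))


# ---------------------------------------------------------------------------
# Angles


def angle_between(u, v) -> float:
    """Unsigned angle between two vectors, degrees in ``[0, 180]``."""
    uu, vv = unit(u), unit(v)
    return float(np.degrees(np.arccos(np.clip(np.dot(uu, vv), -1.0, 1.0))))


def vector_plane_angle(u, plane: Plane) -> float:
    """Elevation of a vector out of a plane: ``arcsin(|u·n|)``, degrees in ``[0, 90]``."""
    uu = unit(u)
    return float(np.degrees(np.arcsin(np.clip(abs(np.dot(uu, plane.normal)), 0.0, 1.0))))


def project_onto_plane(u, plane: Plane) -> np.ndarray:
    """Unit in-plane component of ``u``; error if ``u`` is parallel to the normal."""
    uu = unit(u)
    residual = uu - np.dot(uu, plane.normal) * plane.normal
    if np.linalg.norm(residual) < 1e-9:
        raise GeometryError("vector is parallel to the plane normal; projection degenerate")
    return unit(residual)


def signed_angle_in_plane(u, v, normal) -> float:
    """Signed angle from ``u`` to ``v`` about ``normal``, degrees in ``(-180, 180]``.

    Both vectors are projected into the plane orthogonal to ``normal`` first;
    the sign is positive for a right-handed rotation about ``normal``.
    """
    n = unit(normal)
    pl = Plane(n, np.zeros(3))
    up = project_onto_plane(u, pl)
    vp = project_onto_plane(v, pl)
    ang = np.degrees(np.arctan2(np.dot(np.cross(up, vp), n), np.dot(up, vp)))
    if ang <= -180.0:
        ang += 360.0
    return float(ang)


# ---------------------------------------------------------------------------
# Fitting


def fit_plane(points, hint=None) -> Plane:
    """Least-squares plane through ``points`` (>= 3, not collinear).

    For exactly three points the plane interpolates them; for more, the
    normal is the direction of smallest singular value of the centred cloud.
    If ``hint`` is given, the normal is oriented so the hint point lies on
    its positive side (needed to make "lateral" well defined); a hint lying
    in the plane is an error.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.shape[0] < 3 or pts.shape[1] != 3:
        raise GeometryError("fit_plane needs at least 3 points of dimension 3")
    centroid = pts.mean(axis=0)
    _, s, vt = np.linalg.svd(pts - centroid)
    # collinear (or coincident) clouds have two near-zero singular values
    scale = max(s[0], 1e-12)
    if s[1] / scale < 1e-9:
        raise GeometryError("points are collinear or coincident; plane undefined")
    plane = Plane(vt[-1], centroid)
    if hint is not None:
        d = plane.signed_distance(hint)
        if abs(d) < 1e-12:
            raise GeometryError("orientation hint lies in the plane")
        if d < 0:
            plane = Plane(-plane.normal, plane.point)
    return plane


def register_point_sets(src, dst) -> tuple[RigidPose, float]:
    """Closed-form least-squares rigid transform mapping ``src`` onto ``dst``.

    Uses the Kabsch/SVD solution (proper rotation, det = +1) on centred
    clouds. Returns the pose and the RMS residual in metres.

    Raises
    ------
    GeometryError
        Fewer than 3 correspondences, length mismatch, or a (near-)collinear
        source cloud, for which the rotation about the cloud axis is
        unobservable.
    """
    s = np.atleast_2d(np.asarray(src, dtype=float))
    d = np.atleast_2d(np.asarray(dst, dtype=float))
    if s.shape != d.shape or s.shape[0] < 3 or s.shape[1] != 3:
        raise GeometryError("registration needs >= 3 equal-length 3-D correspondences")
    sc, dc = s.mean(axis=0), d.mean(axis=0)
    s0, d0 = s - sc, d - dc
    sv = np.linalg.svd(s0, compute_uv=False)
    if sv[1] / max(sv[0], 1e-12) < 1e-9:
        raise GeometryError("source points are collinear; rotation unobservable")
    # a non-planar cloud whose optimal orthogonal map is a reflection cannot
    # have come from a rigid motion
    hu, hs, hvt = np.linalg.svd(d0.T @ s0)
    if np.linalg.det(hu @ hvt) < 0 and hs[2] > 1e-9 * hs[0]:
        raise GeometryError("correspondences require a reflection, not a rigid motion")
    rot, _ = Rotation.align_vectors(d0, s0)  # Kabsch, proper rotation guaranteed
    t = dc - rot.apply(sc)
    pose = RigidPose.from_rotation(rot, t)
    residual = pose.apply(s) - d
    rms = float(np.sqrt(np.mean(np.sum(residual**2, axis=1))))
    return pose, rms
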