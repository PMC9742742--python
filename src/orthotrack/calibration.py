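"""Segment calibration: landmarks recorded once, stored body-locally.

A wand (tracked pointer) touches an anatomical point while the owning body's
pose is known; the point is stored in the body's local frame so that it can
be reprojected into the lab after the bone or instrument moves. This is what
makes orientation measurements survive repositioning of the models between
calibration and measurement.

Anatomical frames are right-handed orthonormal triads
``(lateral, anterior, longitudinal)`` satisfying
``anterior x lateral = longitudinal`` (equivalently
``lateral x longitudinal = anterior``).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .geometry import GeometryError, Plane, RigidPose, fit_plane, unit

CALIBRATION_SCHEMA_VERSION = 1

#: Landmark names each segment kind must provide.
REQUIRED_LANDMARKS = {
    "pelvis": ("asis", "pt", "bp_1", "bp_2", "bp_3"),
    "baseplate": ("bp_1", "bp_2", "bp_3"),
    "femur": (
        "shaft_prox_med",
        "shaft_prox_lat",
        "shaft_dist_med",
        "shaft_dist_lat",
        "notch",
        "condyle_med",
        "condyle_lat",
    ),
    "cup_introducer": (
        "handle_near_ant",
        "handle_near_post",
        "handle_far_ant",
        "handle_far_post",
    ),
    "stem": ("trunnion", "tip", "shoulder_mid", "lat125"),
}


class CalibrationError(ValueError):
    """Missing landmarks, owner mismatch, or schema problems."""


@dataclass(frozen=True)
class VirtualLandmark:
    """A named point stored in the owning body's local frame (metres)."""

    name: str
    local_position: np.ndarray
    owner: str

    def __post_init__(self):
        object.__setattr__(
            self, "local_position", np.asarray(self.local_position, dtype=float)
        )


@dataclass
class SegmentCalibration:
    """One tracked segment's landmark set.

    ``sign_flags`` carries orientation conventions that cannot be inferred
    from the landmarks alone (e.g. which way "anterior" points for a left
    vs right hemi-pelvis); they default to +1.
    """

    body_id: str
    kind: str
    landmarks: list[VirtualLandmark] = field(default_factory=list)
    sign_flags: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        if self.kind not in REQUIRED_LANDMARKS:
            raise CalibrationError(f"unknown segment kind {self.kind!r}")
        names = [lm.name for lm in self.landmarks]
        if len(set(names)) != len(names):
            raise CalibrationError("landmark names must be unique")
        for lm in self.landmarks:
            if lm.owner != self.body_id:
                raise CalibrationError(
                    f"landmark {lm.name!r} owned by {lm.owner!r}, not {self.body_id!r}"
                )

    def landmark(self, name: str) -> VirtualLandmark:
        for lm in self.landmarks:
            if lm.name == name:
                return lm
        raise CalibrationError(f"segment {self.body_id!r} has no landmark {name!r}")

    def validate_complete(self) -> None:
        have = {lm.name for lm in self.landmarks}
        missing = [n for n in REQUIRED_LANDMARKS[self.kind] if n not in have]
        if missing:
            raise CalibrationError(
                f"{self.kind} calibration incomplete: missing {missing}"
            )

    def flag(self, name: str) -> int:
        return int(self.sign_flags.get(name, 1))

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "version": CALIBRATION_SCHEMA_VERSION,
            "body_id": self.body_id,
            "kind": self.kind,
            "landmarks": [
                {"name": lm.name, "local_xyz": [float(c) for c in lm.local_position]}
                for lm in self.landmarks
            ],
            "sign_flags": dict(self.sign_flags),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SegmentCalibration":
        try:
            version = d["version"]
            if version != CALIBRATION_SCHEMA_VERSION:
                raise CalibrationError(
                    f"calibration schema version {version} unsupported "
                    f"(expected {CALIBRATION_SCHEMA_VERSION})"
                )
            body_id = d["body_id"]
            lms = [
                VirtualLandmark(e["name"], np.asarray(e["local_xyz"], float), body_id)
                for e in d["landmarks"]
            ]
            return cls(body_id, d["kind"], lms, dict(d.get("sign_flags", {})))
        except KeyError as exc:
            raise CalibrationError(f"calibration file missing field {exc}") from exc


def save_calibration(cal: SegmentCalibration, path) -> None:
    Path(path).write_text(json.dumps(cal.to_dict(), indent=2) + "\n")


def load_calibration(path) -> SegmentCalibration:
    try:
        data = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise CalibrationError(f"cannot parse calibration JSON {path}: {exc}") from exc
    return SegmentCalibration.from_dict(data)


# ---------------------------------------------------------------------------
# Recording and reprojection


def record_virtual_point(wand_tip_lab, owner_pose: RigidPose, name: str,
                         owner: str) -> VirtualLandmark:
    """Store a wand-tip lab position in the owner body's local frame."""
    local = owner_pose.inverse().apply(np.asarray(wand_tip_lab, dtype=float))
    return VirtualLandmark(name, local, owner)


def localize_landmark(lm: VirtualLandmark, current_pose: RigidPose,
                      body_id: str | None = None) -> np.ndarray:
    """Reproject a stored landmark into the lab under the body's current pose."""
    if body_id is not None and body_id != lm.owner:
        raise CalibrationError(
            f"pose belongs to body {body_id!r} but landmark is owned by {lm.owner!r}"
        )
    return current_pose.apply(lm.local_position)


def localize_all(cal: SegmentCalibration, pose: RigidPose) -> dict[str, np.ndarray]:
    """Lab-frame positions of every landmark of a segment under ``pose``."""
    return {lm.name: localize_landmark(lm, pose) for lm in cal.landmarks}


# ---------------------------------------------------------------------------
# Anatomical frames


@dataclass(frozen=True)
class AnatomicalFrame:
    """Right-handed orthonormal anatomical triad with an origin (metres)."""

    lateral: np.ndarray
    anterior: np.ndarray
    longitudinal: np.ndarray
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        lat = unit(self.lateral)
        ant = unit(self.anterior)
        lon = unit(self.longitudinal)
        if (
            abs(np.dot(lat, ant)) > 1e-8
            or abs(np.dot(lat, lon)) > 1e-8
            or abs(np.dot(ant, lon)) > 1e-8
            or np.linalg.norm(np.cross(ant, lat) - lon) > 1e-8
        ):
            raise GeometryError(
                "anatomical frame axes must satisfy anterior x lateral = longitudinal "
                "and be orthonormal"
            )
        object.__setattr__(self, "lateral", lat)
        object.__setattr__(self, "anterior", ant)
        object.__setattr__(self, "longitudinal", lon)
        object.__setattr__(self, "origin", np.asarray(self.origin, dtype=float))

    def rotated(self, pose: RigidPose) -> "AnatomicalFrame":
        """Frame after a rigid motion of the underlying body."""
        return AnatomicalFrame(
            pose.apply_vector(self.lateral),
            pose.apply_vector(self.anterior),
            pose.apply_vector(self.longitudinal),
            pose.apply(self.origin),
        )


def build_pelvis_frame(asis, pt, baseplate: Plane, lateral_hint,
                       anterior_sign: int = 1) -> AnatomicalFrame:
    """Pelvis anatomical frame in the lateral-decubitus baseplate setup.

    The baseplate plane is the virtual sagittal plane; its normal, oriented
    toward ``lateral_hint`` (a point on the model side of the plate), is the
    lateral axis. The anterior pelvic plane is taken as the unique plane
    containing the ASIS-to-pubic-tubercle line and the lateral direction,
    so the anterior axis is ``unit((pt - asis) x lateral)`` up to
    ``anterior_sign``; the longitudinal (head-ward) axis completes the triad.
    """
    asis = np.asarray(asis, dtype=float)
    pt = np.asarray(pt, dtype=float)
    d = baseplate.signed_distance(lateral_hint)
    if abs(d) < 1e-12:
        raise GeometryError("lateral hint lies in the baseplate plane")
    lateral = baseplate.normal if d > 0 else -baseplate.normal
    app_line = pt - asis
    if np.linalg.norm(np.cross(app_line, lateral)) < 1e-9 * max(np.linalg.norm(app_line), 1e-12):
        raise GeometryError("ASIS-PT segment is parallel to the lateral axis (or degenerate)")
    anterior = anterior_sign * unit(np.cross(app_line, lateral))
    longitudinal = np.cross(anterior, lateral)
    return AnatomicalFrame(lateral, anterior, longitudinal, 0.5 * (asis + pt))


def build_femur_frame(shaft_pair_proximal, shaft_pair_distal, notch,
                      condyle_med, condyle_lat) -> AnatomicalFrame:
    """Femur anatomical frame from shaft marker pairs and wand points.

    The anatomical long axis runs from the centre of the intercondylar notch
    to the midpoint of the proximal shaft-marker pair. The lateral axis is
    the posterior condylar axis (medial condyle to lateral condyle)
    orthogonalised against the long axis; anterior completes the triad.
    The distal pair is kept for shaft QC only: it must not be coincident
    with the proximal pair.
    """
    prox = np.asarray(shaft_pair_proximal, dtype=float).reshape(2, 3)
    dist = np.asarray(shaft_pair_distal, dtype=float).reshape(2, 3)
    notch = np.asarray(notch, dtype=float)
    mid_prox = prox.mean(axis=0)
    mid_dist = dist.mean(axis=0)
    if np.linalg.norm(mid_prox - mid_dist) < 1e-9:
        raise GeometryError("proximal and distal shaft midpoints coincide")
    longitudinal = unit(mid_prox - notch)
    condylar = np.asarray(condyle_lat, dtype=float) - np.asarray(condyle_med, dtype=float)
    if np.linalg.norm(condylar) < 1e-12:
        raise GeometryError("condylar wand points coincide")
    lat_raw = condylar - np.dot(condylar, longitudinal) * longitudinal
    if np.linalg.norm(lat_raw) < 1e-9 * np.linalg.norm(condylar):
        raise GeometryError("condylar axis parallel to the long axis")
    lateral = unit(lat_raw)
    anterior = np.cross(lateral, longitudinal)
    return AnatomicalFrame(lateral, anterior, longitudinal, notch)


# ---------------------------------------------------------------------------
# Implant axes from calibrated instruments


def cup_axis(introducer_cal: SegmentCalibration, pose: RigidPose) -> np.ndarray:
    """Lab-frame acetabular axis, oriented out of the cup opening.

    The four introducer handle markers (anterior/posterior near and far
    pairs) reduce to two on-axis points by pairwise midpoints; the axis runs
    from the near (cup-end) midpoint toward the far (handle-end) midpoint,
    times the ``axis`` sign flag.
    """
    introducer_cal.validate_complete()
    p = localize_all(introducer_cal, pose)
    near = 0.5 * (p["handle_near_ant"] + p["handle_near_post"])
    far = 0.5 * (p["handle_far_ant"] + p["handle_far_post"])
    return introducer_cal.flag("axis") * unit(far - near)


def stem_axes(stem_cal: SegmentCalibration, pose: RigidPose) -> tuple[np.ndarray, np.ndarray]:
    """Lab-frame (stem_axis, neck_axis) of a calibrated femoral stem.

    ``stem_axis`` runs from the stem tip up to the shoulder midline
    (distal to proximal); ``neck_axis`` runs from the lateral-stem point at
    the neck-axis intersection toward the trunnion apex.
    """
    stem_cal.validate_complete()
    p = localize_all(stem_cal, pose)
    stem_axis = unit(p["shoulder_mid"] - p["tip"])
    neck_axis = unit(p["trunnion"] - p["lat125"])
    return stem_axis, neck_axis


def pelvis_frame_from_landmarks(pelvis_cal: SegmentCalibration,
                                pose: RigidPose) -> AnatomicalFrame:
    """Pelvis frame from a calibrated pelvis+baseplate segment under ``pose``."""
    pelvis_cal.validate_complete()
    p = localize_all(pelvis_cal, pose)
    baseplate = fit_plane([p["bp_1"], p["bp_2"], p["bp_3"]], hint=p["asis"])
    return build_pelvis_frame(
        p["asis"], p["pt"], baseplate, p["asis"],
        anterior_sign=pelvis_cal.flag("anterior"),
    )


def femur_frame_from_landmarks(femur_cal: SegmentCalibration,
                               pose: RigidPose) -> AnatomicalFrame:
    """Femur frame from a calibrated femur segment under ``pose``."""
    femur_cal.validate_complete()
    p = localize_all(femur_cal, pose)
    return build_femur_frame(
        [p["shaft_prox_med"], p["shaft_prox_lat"]],
        [p["shaft_dist_med"], p["shaft_dist_lat"]],
        p["notch"],
        p["condyle_med"],
        p["condyle_lat"],
    )


def condylar_axis_from_landmarks(femur_cal: SegmentCalibration,
                                 pose: RigidPose) -> np.ndarray:
    """Lab-frame posterior condylar axis (medial-to-lateral wand points)."""
    p = localize_all(femur_cal, pose)
    return unit(p["condyle_lat"] - p["condyle_med"])
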