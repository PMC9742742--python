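"""Synthetic bench study: implants placed on orientation grids, observed by
two virtual measurement systems.

The generator emulates the lateral-decubitus bench setup: a hemi-pelvis (or
femur) model fixed to a level baseplate, an instrument rigidly attached to
the implant, and two tracking systems measuring both bodies simultaneously.

* **System A** (optical motion-capture stand-in, the reference) sees the
  physical marker clouds. It perturbs every lab-frame marker with isotropic
  Gaussian noise of ``marker_sigma_m`` and re-estimates each body pose by
  closed-form rigid registration against the body-local marker template.
* **System B** (headset-tracker stand-in, the test system) reads body poses
  directly. Each pose is perturbed by a small random rotation whose rotation
  vector has i.i.d. normal components with SD ``tracker_rot_sigma_deg``.
  For the cup, a systematic anterior-pelvic-plane calibration error of
  ``app_bias_deg`` (a rotation of B's pelvis reference about the lateral
  axis) makes B read operative anteversion lower than truth by exactly the
  bias, so the reference-minus-test difference equals ``+app_bias_deg``.

Ground-truth placements are generated through the same frame-construction
and forward-model code used for measurement, so a noiseless scene reproduces
its truth to machine precision across the whole grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .angles import (
    CupOrientation,
    StemOrientation,
    cup_axis_from_angles,
    cup_orientation,
    stem_orientation,
)
from .calibration import (
    AnatomicalFrame,
    SegmentCalibration,
    VirtualLandmark,
    condylar_axis_from_landmarks,
    cup_axis,
    femur_frame_from_landmarks,
    pelvis_frame_from_landmarks,
    stem_axes,
)
from .geometry import RigidPose, compose, register_point_sets, unit

NECK_SHAFT_ANGLE_DEG = 125.0  # fixed neck-axis angle of the modelled stem


def _frange(start: float, stop: float, step: float) -> list[float]:
    n = int(round((stop - start) / step)) + 1
    return [start + i * step for i in range(n)]


@dataclass
class ScenarioConfig:
    """Study conditions: orientation grids, noise magnitudes, replication.

    Defaults reproduce the intended bench grids — cup operative anteversion
    10–40 deg and inclination 35–60 deg in 5-deg steps; stem neck anteversion
    0–30 deg in 5-deg steps with neutral / maximal-varus / maximal-valgus
    alignment (3 deg either way for the modelled stem).
    """

    cup_oa_deg: list[float] = field(default_factory=lambda: _frange(10, 40, 5))
    cup_oi_deg: list[float] = field(default_factory=lambda: _frange(35, 60, 5))
    stem_fna_deg: list[float] = field(default_factory=lambda: _frange(0, 30, 5))
    varus_max_deg: float = 3.0
    valgus_max_deg: float = 3.0
    marker_sigma_m: float = 5e-4
    tracker_rot_sigma_deg: float = 0.25
    app_bias_deg: float = 0.0
    pelvic_tilt_deg: float = 0.0
    replicates: int = 1
    seed: int = 0

    def __post_init__(self):
        if self.marker_sigma_m < 0 or self.tracker_rot_sigma_deg < 0:
            raise ValueError("noise SDs must be non-negative")
        if not self.cup_oa_deg or not self.cup_oi_deg or not self.stem_fna_deg:
            raise ValueError("orientation grids must be non-empty")
        if self.replicates < 1:
            raise ValueError("replicate count must be >= 1")

    @property
    def stem_fsa_deg(self) -> list[float]:
        return [0.0, self.varus_max_deg, -self.valgus_max_deg]

    def cup_grid(self) -> list[CupOrientation]:
        return [CupOrientation(oa, oi) for oa in self.cup_oa_deg for oi in self.cup_oi_deg]

    def stem_grid(self) -> list[StemOrientation]:
        return [StemOrientation(fna, fsa) for fna in self.stem_fna_deg for fsa in self.stem_fsa_deg]

    def to_dict(self) -> dict:
        return {
            "cup_oa_deg": list(self.cup_oa_deg),
            "cup_oi_deg": list(self.cup_oi_deg),
            "stem_fna_deg": list(self.stem_fna_deg),
            "varus_max_deg": self.varus_max_deg,
            "valgus_max_deg": self.valgus_max_deg,
            "marker_sigma_m": self.marker_sigma_m,
            "tracker_rot_sigma_deg": self.tracker_rot_sigma_deg,
            "app_bias_deg": self.app_bias_deg,
            "pelvic_tilt_deg": self.pelvic_tilt_deg,
            "replicates": self.replicates,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioConfig":
        return cls(**d)


# ---------------------------------------------------------------------------
# Scene construction


@dataclass
class TrackedBody:
    """A rigid body in a scene: its true pose, physical markers, landmarks."""

    name: str
    pose: RigidPose
    markers_local: np.ndarray
    calibration: SegmentCalibration


@dataclass
class Scene:
    """One implant placement with ground truth and all tracked bodies."""

    kind: str  # "cup" | "stem"
    truth: CupOrientation | StemOrientation
    bodies: dict[str, TrackedBody]

    def true_poses(self) -> dict[str, RigidPose]:
        return {name: b.pose for name, b in self.bodies.items()}

    def transformed(self, motion: RigidPose) -> "Scene":
        """Scene after one common rigid motion of every body (bench moved)."""
        bodies = {
            name: TrackedBody(b.name, compose(motion, b.pose), b.markers_local, b.calibration)
            for name, b in self.bodies.items()
        }
        return Scene(self.kind, self.truth, bodies)


def _make_body(name: str, kind: str, lab_landmarks: dict[str, np.ndarray],
               lab_markers: np.ndarray, pose: RigidPose,
               sign_flags: dict[str, int] | None = None) -> TrackedBody:
    inv = pose.inverse()
    lms = [VirtualLandmark(n, inv.apply(p), name) for n, p in lab_landmarks.items()]
    cal = SegmentCalibration(name, kind, lms, sign_flags or {})
    cal.validate_complete()
    return TrackedBody(name, pose, inv.apply(lab_markers), cal)


def _perp_pair(axis: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    helper = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(helper, axis)) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    u = unit(np.cross(axis, helper))
    return u, np.cross(axis, u)


def generate_cup_scene(truth: CupOrientation, config: ScenarioConfig,
                       rng: np.random.Generator) -> Scene:
    """Pelvis-on-baseplate scene with the cup introducer at ``truth``.

    Canonical bench axes before the optional pelvic tilt and the random body
    poses: longitudinal +x, anterior +y, lateral (away from the baseplate,
    toward the model) +z.
    """
    if not (0.0 <= truth.oi < 90.0):
        raise ValueError("cup scenes require operative inclination in [0, 90)")
    landmarks = {
        "bp_1": np.array([0.10, 0.10, 0.0]),
        "bp_2": np.array([-0.10, 0.10, 0.0]),
        "bp_3": np.array([0.0, -0.10, 0.0]),
        "asis": np.array([0.06, 0.04, 0.10]),
        "pt": np.array([-0.05, 0.04, 0.05]),
    }
    if config.pelvic_tilt_deg:
        tilt = Rotation.from_rotvec(np.radians(config.pelvic_tilt_deg) * np.array([0.0, 1.0, 0.0]))
        landmarks = {n: tilt.apply(p) for n, p in landmarks.items()}

    pelvis_pose = RigidPose.random(rng)
    pelvis = _make_body(
        "pelvis", "pelvis", landmarks,
        np.array(list(landmarks.values())), pelvis_pose,
    )
    frame = pelvis_frame_from_landmarks(pelvis.calibration, pelvis_pose)
    axis = cup_axis_from_angles(truth.oa, truth.oi, frame)

    cup_centre = frame.origin + 0.06 * frame.lateral - 0.02 * frame.longitudinal
    u, _ = _perp_pair(axis)
    half = 0.015
    intro_landmarks = {
        "handle_near_ant": cup_centre + 0.12 * axis + half * u,
        "handle_near_post": cup_centre + 0.12 * axis - half * u,
        "handle_far_ant": cup_centre + 0.30 * axis + half * u,
        "handle_far_post": cup_centre + 0.30 * axis - half * u,
    }
    intro_pose = RigidPose.random(rng)
    introducer = _make_body(
        "introducer", "cup_introducer", intro_landmarks,
        np.array(list(intro_landmarks.values())), intro_pose,
    )
    return Scene("cup", truth, {"pelvis": pelvis, "introducer": introducer})


def _neck_axis_direction(fna_deg: float, fsa_deg: float,
                         frame: AnatomicalFrame) -> np.ndarray:
    """Unit neck axis realising the given neck anteversion at the fixed
    neck-shaft angle, for a stem tilted ``fsa_deg`` in the coronal plane."""
    theta, phi = np.radians(fna_deg), np.radians(fsa_deg)
    # axial direction: condylar (lateral) axis rotated anteriorly by theta
    nk_p = np.cos(theta) * frame.lateral + np.sin(theta) * frame.anterior
    # polar angle psi from the long axis satisfying
    # cos(psi) cos(phi) - sin(psi) cos(theta) sin(phi) = cos(NSA)
    amp = np.hypot(np.cos(phi), np.cos(theta) * np.sin(phi))
    delta = np.arctan2(np.cos(theta) * np.sin(phi), np.cos(phi))
    psi = np.arccos(np.clip(np.cos(np.radians(NECK_SHAFT_ANGLE_DEG)) / amp, -1, 1)) - delta
    return unit(np.cos(psi) * frame.longitudinal + np.sin(psi) * nk_p)


def generate_stem_scene(truth: StemOrientation, config: ScenarioConfig,
                        rng: np.random.Generator) -> Scene:
    """Femur scene with the stem at ``truth`` and a 125-degree neck axis."""
    landmarks = {
        "shaft_prox_med": np.array([0.25, 0.0, -0.03]),
        "shaft_prox_lat": np.array([0.25, 0.0, 0.03]),
        "shaft_dist_med": np.array([0.10, 0.0, -0.03]),
        "shaft_dist_lat": np.array([0.10, 0.0, 0.03]),
        "notch": np.array([0.0, 0.0, 0.0]),
        "condyle_med": np.array([0.0, -0.02, -0.025]),
        "condyle_lat": np.array([0.0, -0.02, 0.025]),
    }
    femur_pose = RigidPose.random(rng)
    femur = _make_body(
        "femur", "femur", landmarks,
        np.array([landmarks[k] for k in
                  ("shaft_prox_med", "shaft_prox_lat", "shaft_dist_med", "shaft_dist_lat")]),
        femur_pose,
    )
    frame = femur_frame_from_landmarks(femur.calibration, femur_pose)

    phi = np.radians(truth.fsa)
    stem_dir = np.cos(phi) * frame.longitudinal - np.sin(phi) * frame.lateral
    neck_dir = _neck_axis_direction(truth.fna, truth.fsa, frame)

    tip = frame.origin + 0.08 * frame.longitudinal
    shoulder = tip + 0.10 * stem_dir
    lat125 = tip + 0.09 * stem_dir
    trunnion = lat125 + 0.035 * neck_dir
    stem_landmarks = {
        "tip": tip, "shoulder_mid": shoulder, "lat125": lat125, "trunnion": trunnion,
    }
    # physical markers: tri-cluster at the trunnion apex + introducer handle
    u, v = _perp_pair(stem_dir)
    markers = np.array([
        trunnion + 0.010 * u,
        trunnion - 0.005 * u + 0.008 * v,
        trunnion - 0.005 * u - 0.008 * v,
        shoulder + 0.15 * stem_dir + 0.015 * u,
        shoulder + 0.15 * stem_dir - 0.015 * u,
        shoulder + 0.30 * stem_dir + 0.015 * u,
        shoulder + 0.30 * stem_dir - 0.015 * u,
    ])
    stem_pose = RigidPose.random(rng)
    stem = _make_body("stem", "stem", stem_landmarks, markers, stem_pose)
    return Scene("stem", truth, {"femur": femur, "stem": stem})


def generate_scene(truth: CupOrientation | StemOrientation, config: ScenarioConfig,
                   rng: np.random.Generator) -> Scene:
    if isinstance(truth, CupOrientation):
        return generate_cup_scene(truth, config, rng)
    if isinstance(truth, StemOrientation):
        return generate_stem_scene(truth, config, rng)
    raise TypeError(f"unsupported truth type {type(truth).__name__}")


# ---------------------------------------------------------------------------
# Measurement


def measure_scene(scene: Scene, poses: dict[str, RigidPose],
                  app_bias_deg: float = 0.0) -> CupOrientation | StemOrientation:
    """Measure the implant orientation from estimated body poses.

    ``app_bias_deg`` rotates the pelvis reference axes about lateral to model
    a systematic anterior-pelvic-plane calibration error of the measuring
    system (cup scenes only): a positive bias lowers the measured operative
    anteversion by that amount.
    """
    if scene.kind == "cup":
        frame = pelvis_frame_from_landmarks(scene.bodies["pelvis"].calibration,
                                            poses["pelvis"])
        if app_bias_deg:
            rot = Rotation.from_rotvec(np.radians(app_bias_deg) * frame.lateral)
            frame = AnatomicalFrame(
                frame.lateral, rot.apply(frame.anterior), rot.apply(frame.longitudinal),
                frame.origin,
            )
        axis = cup_axis(scene.bodies["introducer"].calibration, poses["introducer"])
        return cup_orientation(axis, frame)
    if scene.kind == "stem":
        femur = scene.bodies["femur"]
        frame = femur_frame_from_landmarks(femur.calibration, poses["femur"])
        condylar = condylar_axis_from_landmarks(femur.calibration, poses["femur"])
        s_axis, n_axis = stem_axes(scene.bodies["stem"].calibration, poses["stem"])
        return stem_orientation(s_axis, n_axis, condylar, frame)
    raise ValueError(f"unknown scene kind {scene.kind!r}")


def _jittered_pose(pose: RigidPose, sigma_deg: float,
                   rng: np.random.Generator) -> RigidPose:
    rotvec = np.radians(rng.normal(0.0, sigma_deg, size=3))
    return RigidPose.from_rotation(Rotation.from_rotvec(rotvec) * pose.rotation,
                                   pose.translation)


def observe(scene: Scene, system: str, config: ScenarioConfig,
            rng: np.random.Generator) -> CupOrientation | StemOrientation:
    """One reading of a scene by system ``"A"`` (marker-based reference) or
    ``"B"`` (direct pose tracking with optional systematic cup bias)."""
    if system == "A":
        poses = {}
        for name, body in scene.bodies.items():
            lab = body.pose.apply(body.markers_local)
            noisy = lab + rng.normal(0.0, config.marker_sigma_m, size=lab.shape)
            poses[name], _ = register_point_sets(body.markers_local, noisy)
        return measure_scene(scene, poses)
    if system == "B":
        poses = {
            name: _jittered_pose(body.pose, config.tracker_rot_sigma_deg, rng)
            for name, body in scene.bodies.items()
        }
        bias = config.app_bias_deg if scene.kind == "cup" else 0.0
        return measure_scene(scene, poses, app_bias_deg=bias)
    raise ValueError(f"unknown system {system!r} (expected 'A' or 'B')")


# ---------------------------------------------------------------------------
# Study runner


def run_study(config: ScenarioConfig, model: str) -> pd.DataFrame:
    """Simulate the full paired study for one implant model.

    Every grid point is re-implanted ``config.replicates`` times (a fresh
    scene with fresh body poses each time) and read simultaneously by both
    systems. Deterministic given ``config.seed``.

    Returns a table with one row per reading:
    ``scenario_id, replicate, truth_*, sysA_*, sysB_*`` (angles in degrees).
    """
    rng = np.random.default_rng(config.seed)
    rows = []
    if model == "cup":
        grid: list = config.cup_grid()
        cols = ("oa", "oi")
        get = lambda r: (r.oa, r.oi)  # noqa: E731
    elif model == "stem":
        grid = config.stem_grid()
        cols = ("fna", "fsa")
        get = lambda r: (r.fna, r.fsa)  # noqa: E731
    else:
        raise ValueError("model must be 'cup' or 'stem'")

    for truth in grid:
        t1, t2 = get(truth)
        scenario_id = f"{model}_{cols[0]}{t1:+05.1f}_{cols[1]}{t2:+05.1f}"
        for rep in range(config.replicates):
            scene = generate_scene(truth, config, rng)
            reading_a = observe(scene, "A", config, rng)
            reading_b = observe(scene, "B", config, rng)
            a1, a2 = get(reading_a)
            b1, b2 = get(reading_b)
            rows.append({
                "scenario_id": scenario_id,
                "replicate": rep,
                f"truth_{cols[0]}_deg": t1,
                f"truth_{cols[1]}_deg": t2,
                f"sysA_{cols[0]}_deg": a1,
                f"sysA_{cols[1]}_deg": a2,
                f"sysB_{cols[0]}_deg": b1,
                f"sysB_{cols[1]}_deg": b2,
            })
    return pd.DataFrame(rows)
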