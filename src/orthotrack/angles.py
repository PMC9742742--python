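"""The four component-orientation metrics, plus exact forward models.

Definitions (all in degrees at the API boundary):

* **Operative inclination (OI)** — angle between the acetabular axis and the
  sagittal plane: ``arcsin(axis . lateral)``, reported unsigned in [0, 90]
  after orienting the axis laterally.
* **Operative anteversion (OA)** — angle between the patient's longitudinal
  axis and the sagittal-plane projection of the acetabular axis, signed
  positive toward anterior: ``atan2(axis . anterior, axis . longitudinal)``.
* **Femoral neck anteversion (FNA)** — axial-plane angle from the posterior
  bicondylar axis to the neck axis, positive for anterior rotation of the
  neck.
* **Femoral stem alignment (FSA)** — coronal-plane angle between the femoral
  long axis and the stem (tip-to-shoulder) axis, signed positive for varus
  (proximal stem tilted medially). A magnitude-only mode is available for
  reports that do not distinguish varus from valgus.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .calibration import AnatomicalFrame
from .geometry import GeometryError, signed_angle_in_plane, unit


class UndefinedAnteversionError(GeometryError):
    """Anteversion is undefined when the cup axis is parallel to lateral (OI = 90)."""


@dataclass(frozen=True)
class CupOrientation:
    """Acetabular cup orientation: operative anteversion and inclination, degrees."""

    oa: float
    oi: float

    def __post_init__(self):
        if not (0.0 <= self.oi <= 90.0):
            raise ValueError(f"operative inclination {self.oi} outside [0, 90]")
        if not (-180.0 < self.oa <= 180.0):
            raise ValueError(f"operative anteversion {self.oa} outside (-180, 180]")


@dataclass(frozen=True)
class StemOrientation:
    """Femoral stem orientation: neck anteversion and stem alignment, degrees."""

    fna: float
    fsa: float

    def __post_init__(self):
        for name, v in (("fna", self.fna), ("fsa", self.fsa)):
            if not (-180.0 < v <= 180.0):
                raise ValueError(f"{name}={v} outside (-180, 180]")


# ---------------------------------------------------------------------------
# Cup


def operative_inclination(axis, frame: AnatomicalFrame) -> float:
    """OI in degrees: elevation of the acetabular axis out of the sagittal plane."""
    a = unit(axis)
    s = np.clip(abs(np.dot(a, frame.lateral)), 0.0, 1.0)
    return float(np.degrees(np.arcsin(s)))


def operative_anteversion(axis, frame: AnatomicalFrame) -> float:
    """OA in degrees, measured from longitudinal toward anterior.

    Raises
    ------
    UndefinedAnteversionError
        If the axis is (numerically) parallel to the lateral axis, i.e.
        OI = 90 and the sagittal projection vanishes.
    """
    a = unit(axis)
    lon = np.dot(a, frame.longitudinal)
    ant = np.dot(a, frame.anterior)
    if np.hypot(lon, ant) < 1e-9:
        raise UndefinedAnteversionError(
            "acetabular axis is parallel to lateral; anteversion undefined at OI = 90"
        )
    return float(np.degrees(np.arctan2(ant, lon)))


def cup_orientation(axis, frame: AnatomicalFrame) -> CupOrientation:
    """Measure (OA, OI) of an acetabular axis in a pelvis frame."""
    return CupOrientation(
        oa=operative_anteversion(axis, frame), oi=operative_inclination(axis, frame)
    )


def cup_axis_from_angles(oa: float, oi: float, frame: AnatomicalFrame) -> np.ndarray:
    """Forward model: the unit acetabular axis realising (OA, OI) in ``frame``.

    ``axis = sin(OI) lateral + cos(OI) (cos(OA) longitudinal + sin(OA) anterior)``.
    OI must lie in [0, 90); at 90 the inverse problem is degenerate.
    """
    if not (0.0 <= oi < 90.0):
        raise ValueError(f"operative inclination {oi} outside [0, 90)")
    oa_r, oi_r = np.radians(oa), np.radians(oi)
    axis = (
        np.sin(oi_r) * frame.lateral
        + np.cos(oi_r) * (np.cos(oa_r) * frame.longitudinal + np.sin(oa_r) * frame.anterior)
    )
    return unit(axis)


# ---------------------------------------------------------------------------
# Stem


def femoral_neck_anteversion(neck_axis, condylar_axis, frame: AnatomicalFrame) -> float:
    """FNA in degrees: axial-plane angle from condylar axis to neck axis.

    Both axes are projected into the axial plane (normal = longitudinal);
    positive values mean the neck is rotated anteriorly relative to the
    posterior condylar axis.
    """
    return signed_angle_in_plane(neck_axis, condylar_axis, frame.longitudinal)


def femoral_stem_alignment(stem_axis, frame: AnatomicalFrame,
                           signed: bool = True) -> float:
    """FSA in degrees: coronal-plane tilt of the stem from the femoral long axis.

    The stem axis (tip to shoulder) is projected into the coronal plane
    (spanned by longitudinal and lateral, normal = anterior); positive
    values are varus (proximal tilt toward medial). With ``signed=False``
    the magnitude is returned.
    """
    ang = signed_angle_in_plane(frame.longitudinal, stem_axis, frame.anterior)
    return ang if signed else abs(ang)


def stem_orientation(stem_axis, neck_axis, condylar_axis,
                     frame: AnatomicalFrame) -> StemOrientation:
    """Measure (FNA, FSA) of a femoral stem in a femur frame."""
    return StemOrientation(
        fna=femoral_neck_anteversion(neck_axis, condylar_axis, frame),
        fsa=femoral_stem_alignment(stem_axis, frame),
    )
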