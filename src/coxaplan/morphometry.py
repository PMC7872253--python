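"""Femoral coordinate frame and 3D alignment measurements.

The femoral frame is anchored to the bone, not the scanner: the proximal
diaphyseal axis and the transcondylar axis define the frontal plane
(spanned by the proximal and mediolateral axes) and the transverse plane
(normal to the proximal axis), so all measurements are invariant to limb
pose during imaging.

Measurements follow total-hip-morphometry practice: the femoral head is a
best-fit sphere over the head mesh region, the diaphysis a best-fit cylinder
axis, and the neck axis runs from the head center through the centroid of
the neck region.  Inclination (neck–shaft angle) is the unsigned
frontal-plane angle between the neck axis and the distally-pointing
diaphyseal direction (≈135° for a normal canine femur); version is the
signed transverse-plane angle of the neck relative to the transcondylar
axis, anteversion (cranially directed neck) positive for both sides; neck
length is the distance from head center to the neck/diaphyseal axis
intersection (closest approach when skew).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import BoneMesh, LandmarkSet
from .geometry import (
    DegenerateInputError,
    Line,
    closest_approach,
    fit_axis,
    fit_sphere,
    projected_angle,
    unit,
)

__all__ = [
    "FemoralFrame",
    "MorphometryResult",
    "AcetabularMeasure",
    "build_femoral_frame",
    "compute_neck_axis",
    "compute_inclination",
    "compute_version",
    "compute_neck_length",
    "acetabular_diameter",
    "measure_femur",
]


@dataclass(frozen=True)
class FemoralFrame:
    """Right-handed orthonormal femoral frame.

    ``axis_prox`` points proximally along the diaphysis, ``axis_ml``
    medially along the (orthogonalized) transcondylar direction, and
    ``axis_cc = axis_prox × axis_ml``.  The anatomic cranial direction is
    ``axis_cc`` for a right femur and ``−axis_cc`` for a left one
    (``axis_cranial``), which keeps "cranial" consistent across sides while
    the stored triad stays right-handed.
    """

    origin: np.ndarray
    axis_prox: np.ndarray
    axis_ml: np.ndarray
    axis_cc: np.ndarray
    side: str

    def __post_init__(self):
        M = np.stack([self.axis_prox, self.axis_ml, self.axis_cc])
        if not np.allclose(M @ M.T, np.eye(3), atol=1e-9):
            raise ValueError("frame axes must be orthonormal")
        if np.linalg.det(M) < 0:
            raise ValueError("frame must be right-handed")
        if self.side not in ("left", "right"):
            raise ValueError("side must be 'left' or 'right'")

    @property
    def axis_cranial(self) -> np.ndarray:
        return self.axis_cc if self.side == "right" else -self.axis_cc

    @property
    def side_sign(self) -> float:
        return 1.0 if self.side == "right" else -1.0


@dataclass
class MorphometryResult:
    """Complete femoral alignment measurement for one hip."""

    head_center: np.ndarray
    head_radius: float
    neck_axis: Line
    inclination: float
    version: float
    neck_length: float
    side: str = "right"

    def __post_init__(self):
        if not 0.0 < self.inclination < 180.0:
            raise ValueError(f"inclination {self.inclination} outside (0, 180)")
        if self.neck_length < 0:
            raise ValueError("neck length must be >= 0")


@dataclass(frozen=True)
class AcetabularMeasure:
    """Bilateral acetabular diameters (cranial-to-caudal border distance)."""

    left_diameter: float
    right_diameter: float

    @property
    def mean_diameter(self) -> float:
        return 0.5 * (self.left_diameter + self.right_diameter)


def build_femoral_frame(diaphyseal_axis: Line, condyle_medial, condyle_lateral,
                        side: str) -> FemoralFrame:
    """Construct the femoral frame from the diaphyseal and transcondylar axes.

    The mediolateral axis is the transcondylar direction (medial − lateral)
    orthogonalized against the proximal diaphyseal direction; the two must
    subtend more than 10°.
    """
    prox = diaphyseal_axis.direction
    tc = np.asarray(condyle_medial, dtype=float) - np.asarray(condyle_lateral, dtype=float)
    tc_n = np.linalg.norm(tc)
    if tc_n < 1e-9:
        raise DegenerateInputError("condylar points coincide")
    cosang = abs(tc @ prox) / tc_n
    if cosang > np.cos(np.radians(10.0)):
        raise DegenerateInputError(
            "transcondylar axis nearly parallel to diaphyseal axis "
            f"({np.degrees(np.arccos(np.clip(cosang, -1, 1))):.1f}° apart); "
            "frame is ill-conditioned"
        )
    ml = unit(tc - (tc @ prox) * prox)
    cc = np.cross(prox, ml)
    return FemoralFrame(origin=diaphyseal_axis.point, axis_prox=prox,
                        axis_ml=ml, axis_cc=cc, side=side)


def compute_neck_axis(head_center, neck_points, diaphyseal_axis: Line) -> Line:
    """Neck axis: from the head-sphere center through the neck centroid.

    Direction points from the diaphysis toward the head.
    """
    pts = np.asarray(neck_points, dtype=float)
    if pts.ndim != 2 or len(pts) < 10:
        raise DegenerateInputError(
            f"need >= 10 neck points, got {0 if pts.ndim != 2 else len(pts)}"
        )
    head_center = np.asarray(head_center, dtype=float)
    centroid = pts.mean(axis=0)
    d = head_center - centroid
    if np.linalg.norm(d) < 1e-9:
        raise DegenerateInputError("neck centroid coincides with head center")
    return Line(point=head_center, direction=unit(d))


def compute_inclination(frame: FemoralFrame, neck_axis: Line) -> float:
    """Neck–shaft angle: frontal-plane angle (deg) between the neck direction
    (toward the head) and the distal diaphyseal direction; range (0, 180)."""
    ang = projected_angle(neck_axis.direction, -frame.axis_prox,
                          plane_normal=frame.axis_cc)
    return abs(ang)


def compute_version(frame: FemoralFrame, neck_axis: Line) -> float:
    """Femoral version: signed transverse-plane angle (deg) between the neck
    direction and the mediolateral axis; anteversion positive for both sides."""
    ang = projected_angle(neck_axis.direction, frame.axis_ml,
                          plane_normal=frame.axis_prox)
    return frame.side_sign * ang


def compute_neck_length(head_center, neck_axis: Line,
                        diaphyseal_axis: Line) -> float:
    """Distance (mm) from the head center to the point where the neck axis
    meets the diaphyseal axis (closest-approach point on the neck axis when
    the lines are skew; exact intersection when coplanar)."""
    on_neck, _, _ = closest_approach(neck_axis, diaphyseal_axis)
    return float(np.linalg.norm(np.asarray(head_center, dtype=float) - on_neck))


def acetabular_diameter(left_borders: dict, right_borders: dict) -> AcetabularMeasure:
    """Per-side cranial–caudal border distance and their mean.

    Each side is a mapping with ``cranial`` and ``caudal`` points.
    """
    dias = {}
    for side, borders in (("left", left_borders), ("right", right_borders)):
        if borders is None or "cranial" not in borders or "caudal" not in borders:
            raise ValueError(f"missing acetabular borders for side {side!r}")
        dias[side] = float(np.linalg.norm(
            np.asarray(borders["cranial"], dtype=float)
            - np.asarray(borders["caudal"], dtype=float)
        ))
    return AcetabularMeasure(left_diameter=dias["left"], right_diameter=dias["right"])


def measure_femur(bone: BoneMesh, landmarks: LandmarkSet) -> MorphometryResult:
    """Full mesh-based measurement: fit head sphere and diaphyseal axis from
    labeled regions, build the frame from the condylar landmarks, and derive
    inclination, version and neck length."""
    if landmarks.condyle_medial is None or landmarks.condyle_lateral is None:
        raise ValueError("condylar landmarks are required to build the frame")
    head_pts = bone.region_points("head")
    neck_pts = bone.region_points("neck")
    shaft_pts = bone.region_points("diaphysis")

    sphere = fit_sphere(head_pts)
    hint = sphere.center - 0.5 * (landmarks.condyle_medial + landmarks.condyle_lateral)
    diaph = fit_axis(shaft_pts, proximal_hint=hint)
    frame = build_femoral_frame(diaph, landmarks.condyle_medial,
                                landmarks.condyle_lateral, landmarks.side)
    neck = compute_neck_axis(sphere.center, neck_pts, diaph)
    return MorphometryResult(
        head_center=sphere.center,
        head_radius=sphere.radius,
        neck_axis=neck,
        inclination=compute_inclination(frame, neck),
        version=compute_version(frame, neck),
        neck_length=compute_neck_length(sphere.center, neck, diaph),
        side=landmarks.side,
    )
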