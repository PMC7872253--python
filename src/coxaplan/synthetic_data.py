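"""Parametric synthetic bone geometry with recorded ground truth.

No canine CT data are publicly deposited for this procedure, so every
pipeline stage is validated against generated geometry whose anatomy is
known analytically:

* :func:`generate_femur` — a stylized canine proximal femur: spherical head
  on an angled cylindrical neck on a cylindrical shaft with condylar
  prominences.  Neck inclination, version and length are free parameters and
  are recorded, together with the physeal-scar landmark ring, the chevron
  osteotomy plan it induces and the true anatomic axes.
* :func:`generate_graft_scene` — a donor graft apposed to a recipient bed as
  concentric spherical caps separated by a known gap, with the closed-form
  gap volume recorded.
* :func:`rasterize` — converts meshes with Hounsfield-unit assignments into
  a CT volume (background −1000 HU), recording exact per-mesh voxel counts.

Default dimensions approximate a 20–40 kg dog (femoral head radius ~10 mm,
neck length ~35 mm, inclination ~135°, anteversion ~20°); HU assignments are
plausible constants (cortical/subchondral bone 1200, marrow 200, soft tissue
40), not a scanner model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import trimesh

from ._mesh import mesh_from_primitives, voxelize_parity
from .core import BoneMesh, LandmarkSet, RigidTransform
from .geometry import Line, Plane, plane_from_points, unit
from .segmentation import CTVolume

__all__ = [
    "FemurParams",
    "GroundTruth",
    "generate_femur",
    "generate_acetabulum",
    "generate_graft_scene",
    "GraftScene",
    "rasterize",
    "spherical_cap_solid",
    "spherical_shell_cap",
    "cap_shell_volume",
    "neck_direction",
    "HU_BONE",
    "HU_MARROW",
    "HU_SOFT_TISSUE",
    "HU_BACKGROUND",
    "transform_scene",
]

HU_BONE = 1200.0
HU_MARROW = 200.0
HU_SOFT_TISSUE = 40.0
HU_BACKGROUND = -1000.0


@dataclass
class FemurParams:
    """Generator parameters for one proximal femur (lengths mm, angles deg)."""

    head_radius: float = 10.0
    neck_radius: float = 5.0
    neck_length: float = 35.0
    inclination: float = 135.0
    version: float = 20.0
    shaft_radius: float = 7.0
    shaft_length: float = 80.0
    condyle_radius: float = 7.0
    condyle_offset: float = 10.0
    cortex_thickness: float = 2.0
    physeal_offsets: tuple[float, float] = (2.0, 1.5)
    side: str = "right"
    vertex_noise_sd: float = 0.0
    seed: int = 0
    mesh_pitch: float = 0.4

    def __post_init__(self):
        for name in ("head_radius", "neck_radius", "neck_length", "shaft_radius",
                     "shaft_length", "mesh_pitch"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if not 90.0 < self.inclination < 180.0:
            raise ValueError("inclination must lie in (90, 180) degrees")
        if self.side not in ("left", "right"):
            raise ValueError("side must be 'left' or 'right'")
        if self.neck_radius >= self.head_radius:
            raise ValueError("neck radius must be smaller than head radius")


@dataclass
class GroundTruth:
    """Analytic truth recorded by a generator, for downstream validation."""

    head_center: np.ndarray
    neck_axis: Line
    diaphyseal_axis: Line
    axis_ml: np.ndarray
    axis_cranial: np.ndarray
    version: float
    inclination: float
    neck_length: float
    side: str
    landmarks: LandmarkSet | None = None
    chevron_plane_a: Plane | None = None
    chevron_plane_b: Plane | None = None
    chevron_dihedral: float | None = None
    analytic_gap_volume: float | None = None
    bone_voxel_count: int | None = None
    extras: dict = field(default_factory=dict)


def _anatomic_basis(side: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Canonical per-bone frame: x = medial, z = proximal, cranial side-aware."""
    ml = np.array([1.0, 0.0, 0.0])
    prox = np.array([0.0, 0.0, 1.0])
    cranial = np.cross(prox, ml) * (1.0 if side == "right" else -1.0)
    return ml, prox, cranial


def neck_direction(inclination: float, version: float, side: str) -> np.ndarray:
    """Unit neck-axis direction (toward the head) realizing the requested
    frontal-plane inclination and transverse-plane version."""
    ml, prox, cranial = _anatomic_basis(side)
    th = math.radians(inclination)
    v = math.radians(version)
    d = math.sin(th) * ml + math.sin(th) * math.tan(v) * cranial - math.cos(th) * prox
    return unit(d)


def _neck_band(p: FemurParams, d: np.ndarray) -> tuple[float, float]:
    """Axial interval along the neck axis whose lateral surface is exposed
    (clear of the shaft proximally and of the head sphere distally)."""
    sin_alpha = float(np.linalg.norm(d[:2]))
    dz = float(d[2])
    t_junction = p.neck_length - math.sqrt(p.head_radius**2 - p.neck_radius**2)
    t_min = max(
        (p.shaft_radius + 0.5) / max(sin_alpha, 1e-6),
        (p.neck_radius + 0.5) / max(dz, 1e-6),
    ) + 0.5
    t_max = t_junction - 1.0
    if t_max - t_min < 1.0:
        raise ValueError(
            "parameter combination leaves no exposed neck surface "
            f"(band [{t_min:.1f}, {t_max:.1f}] mm); the primitives self-intersect"
        )
    return t_min, t_max


def generate_femur(p: FemurParams) -> tuple[BoneMesh, LandmarkSet, GroundTruth]:
    """Build one labeled proximal-femur mesh with full analytic ground truth.

    The watertight union surface of the primitives is extracted by marching
    cubes over their exact signed-distance minimum.  Vertex regions ``head``
    (= ``articular``), ``neck`` and ``diaphysis`` are labeled from the known
    primitives; optional Gaussian vertex noise is applied after labeling.
    Deterministic for a given parameter set and seed.
    """
    ml, prox, cranial = _anatomic_basis(p.side)
    d = neck_direction(p.inclination, p.version, p.side)
    origin = np.zeros(3)  # neck/diaphyseal axes intersection
    head_center = origin + p.neck_length * d
    t_min, t_max = _neck_band(p, d)

    shaft_p0 = np.array([0.0, 0.0, -p.shaft_length])
    shaft_p1 = np.array([0.0, 0.0, 0.0])
    cond_z = -p.shaft_length + 3.0
    cond_m = np.array([p.condyle_offset, 0.0, cond_z])
    cond_l = np.array([-p.condyle_offset, 0.0, cond_z])

    primitives = [
        ("sphere", head_center, p.head_radius),
        ("cylinder", origin, head_center, p.neck_radius),
        ("cylinder", shaft_p0, shaft_p1, p.shaft_radius),
        ("sphere", cond_m, p.condyle_radius),
        ("sphere", cond_l, p.condyle_radius),
    ]
    pad = 3.0
    ext = max(p.condyle_offset + p.condyle_radius, p.shaft_radius)
    z_lo = min(-p.shaft_length, cond_z - p.condyle_radius)
    lo = np.minimum(np.array([-ext, -ext, z_lo]),
                    head_center - p.head_radius) - pad
    hi = np.maximum(np.array([ext, ext, 0.0]),
                    head_center + p.head_radius) + pad
    mesh = mesh_from_primitives(primitives, (lo, hi), pitch=p.mesh_pitch)

    regions = _label_femur_vertices(mesh.vertices, p, head_center, d, t_min, t_max)

    if p.vertex_noise_sd > 0:
        rng = np.random.default_rng(p.seed)
        mesh = mesh.copy()
        mesh.vertices = mesh.vertices + rng.normal(
            0.0, p.vertex_noise_sd, size=mesh.vertices.shape
        )

    landmarks = _physeal_landmarks(p, head_center, d, cond_m, cond_l)
    gt = _ground_truth(p, head_center, d, landmarks)
    gt.extras["neck_band"] = (t_min, t_max)
    return BoneMesh(mesh=mesh, regions=regions), landmarks, gt


def _label_femur_vertices(verts, p: FemurParams, head_center, d, t_min, t_max):
    tol = 0.8 * p.mesh_pitch
    r_head = np.linalg.norm(verts - head_center, axis=1)
    head = np.abs(r_head - p.head_radius) < tol

    t = (verts - np.zeros(3)) @ d
    radial_neck = np.linalg.norm(verts - np.outer(t, d), axis=1)
    neck = (
        (np.abs(radial_neck - p.neck_radius) < tol)
        & (t > t_min)
        & (t < t_max)
        & ~head
    )

    radial_shaft = np.linalg.norm(verts[:, :2], axis=1)
    shaft = (
        (np.abs(radial_shaft - p.shaft_radius) < tol)
        & (verts[:, 2] > -p.shaft_length + p.condyle_radius + 7.0)
        & (verts[:, 2] < -5.0)
    )
    idx = np.arange(len(verts))
    return {
        "head": idx[head],
        "articular": idx[head],
        "neck": idx[neck],
        "diaphysis": idx[shaft],
    }


def _physeal_landmarks(p: FemurParams, head_center, d, cond_m, cond_l) -> LandmarkSet:
    ml, prox, cranial = _anatomic_basis(p.side)
    t_junction = p.neck_length - math.sqrt(p.head_radius**2 - p.neck_radius**2)
    center = t_junction * d
    m_hat = unit(ml - (ml @ d) * d)
    u_hat = unit(np.cross(d, m_hat))  # orthonormal ring basis
    if u_hat @ cranial < 0:
        u_hat = -u_hat
    a, b = p.physeal_offsets

    def ring(phi_deg, axial):
        phi = math.radians(phi_deg)
        e = math.cos(phi) * m_hat + math.sin(phi) * u_hat
        return center + p.neck_radius * e + axial * d

    return LandmarkSet(
        craniomedial=ring(45.0, -a),
        craniolateral=ring(135.0, +a),
        caudomedial=ring(-45.0, +b),
        caudolateral=ring(-135.0, -b),
        condyle_medial=cond_m + np.array([p.condyle_radius, 0.0, 0.0]),
        condyle_lateral=cond_l - np.array([p.condyle_radius, 0.0, 0.0]),
        side=p.side,
    )


def _ground_truth(p: FemurParams, head_center, d, lm: LandmarkSet) -> GroundTruth:
    ml, prox, cranial = _anatomic_basis(p.side)
    plane_a = _oriented_plane(lm.craniomedial, lm.caudomedial, lm.craniolateral, head_center)
    plane_b = _oriented_plane(lm.caudomedial, lm.caudolateral, lm.craniolateral, head_center)
    dihedral = math.degrees(math.acos(np.clip(plane_a.normal @ plane_b.normal, -1, 1)))
    return GroundTruth(
        head_center=head_center,
        neck_axis=Line(point=head_center, direction=d),
        diaphyseal_axis=Line(point=np.zeros(3), direction=prox),
        axis_ml=ml,
        axis_cranial=cranial,
        version=p.version,
        inclination=p.inclination,
        neck_length=p.neck_length,
        side=p.side,
        landmarks=lm,
        chevron_plane_a=plane_a,
        chevron_plane_b=plane_b,
        chevron_dihedral=dihedral,
    )


def _oriented_plane(p1, p2, p3, toward) -> Plane:
    pl = plane_from_points(p1, p2, p3)
    if pl.signed_distance(toward) < 0:
        pl = Plane(point=pl.point, normal=-pl.normal)
    return pl


def transform_scene(t: RigidTransform, bone: BoneMesh, lm: LandmarkSet,
                    gt: GroundTruth) -> tuple[BoneMesh, LandmarkSet, GroundTruth]:
    """Apply one rigid pose jointly to mesh, landmarks and ground truth."""
    bone_t = bone.transformed(t)
    lm_t = lm.transformed(t)
    gt_t = GroundTruth(
        head_center=t.apply(gt.head_center),
        neck_axis=Line(t.apply(gt.neck_axis.point), t.apply_vector(gt.neck_axis.direction)),
        diaphyseal_axis=Line(
            t.apply(gt.diaphyseal_axis.point), t.apply_vector(gt.diaphyseal_axis.direction)
        ),
        axis_ml=t.apply_vector(gt.axis_ml),
        axis_cranial=t.apply_vector(gt.axis_cranial),
        version=gt.version,
        inclination=gt.inclination,
        neck_length=gt.neck_length,
        side=gt.side,
        landmarks=lm_t,
        chevron_plane_a=None if gt.chevron_plane_a is None else Plane(
            t.apply(gt.chevron_plane_a.point), t.apply_vector(gt.chevron_plane_a.normal)
        ),
        chevron_plane_b=None if gt.chevron_plane_b is None else Plane(
            t.apply(gt.chevron_plane_b.point), t.apply_vector(gt.chevron_plane_b.normal)
        ),
        chevron_dihedral=gt.chevron_dihedral,
        analytic_gap_volume=gt.analytic_gap_volume,
        bone_voxel_count=gt.bone_voxel_count,
        extras=dict(gt.extras),
    )
    return bone_t, lm_t, gt_t


# ---------------------------------------------------------------------------
# acetabulum and graft/bed scenes


def spherical_cap_solid(radius: float, half_angle_deg: float = 90.0,
                        n_theta: int = 24, n_phi: int = 48) -> trimesh.Trimesh:
    """Watertight solid spherical cap about −z (dome plus flat top disk).

    ``half_angle_deg`` is the polar angle from the −z pole; 90° gives a
    half-ball with its flat face in the z = 0 plane.
    """
    alpha = math.radians(half_angle_deg)
    thetas = np.linspace(0.0, alpha, n_theta + 1)  # 0 at pole
    phis = np.linspace(0.0, 2 * math.pi, n_phi, endpoint=False)
    verts = [np.array([0.0, 0.0, -radius])]
    rows = []
    for th in thetas[1:]:
        base = len(verts)
        for ph in phis:
            verts.append(radius * np.array(
                [math.sin(th) * math.cos(ph), math.sin(th) * math.sin(ph), -math.cos(th)]
            ))
        rows.append(base)
    faces = []
    # pole fan (outward = away from center, i.e. downward): wind accordingly
    first = rows[0]
    for j in range(n_phi):
        faces.append([0, first + (j + 1) % n_phi, first + j])
    for r in range(len(rows) - 1):
        a, b = rows[r], rows[r + 1]
        for j in range(n_phi):
            j2 = (j + 1) % n_phi
            faces.append([a + j, b + j, b + j2])
            faces.append([a + j, b + j2, a + j2])
    # flat cap: fan from rim centroid
    rim = rows[-1]
    zc = -radius * math.cos(alpha)
    c = len(verts)
    verts.append(np.array([0.0, 0.0, zc]))
    for j in range(n_phi):
        j2 = (j + 1) % n_phi
        faces.append([c, rim + j, rim + j2])
    m = trimesh.Trimesh(vertices=np.asarray(verts), faces=np.asarray(faces), process=False)
    if m.volume < 0:
        m.invert()
    return m


def spherical_shell_cap(r_inner: float, r_outer: float, half_angle_deg: float = 90.0,
                        n_theta: int = 24, n_phi: int = 48) -> trimesh.Trimesh:
    """Watertight cap-shaped shell between two concentric sphere radii.

    Outer dome, inner dome and the flat annulus joining the rims; used for
    recipient beds and for constructed interface-gap phantoms.
    """
    if not 0 < r_inner < r_outer:
        raise ValueError("need 0 < r_inner < r_outer")
    alpha = math.radians(half_angle_deg)
    thetas = np.linspace(0.0, alpha, n_theta + 1)
    phis = np.linspace(0.0, 2 * math.pi, n_phi, endpoint=False)

    def dome(radius):
        vs = [np.array([0.0, 0.0, -radius])]
        rows = []
        for th in thetas[1:]:
            rows.append(len(vs))
            for ph in phis:
                vs.append(radius * np.array(
                    [math.sin(th) * math.cos(ph), math.sin(th) * math.sin(ph), -math.cos(th)]
                ))
        return vs, rows

    vo, rows_o = dome(r_outer)
    verts = list(vo)
    off = len(verts)
    vi, rows_i = dome(r_inner)
    verts.extend(vi)
    rows_i = [r + off for r in rows_i]

    faces = []
    first = rows_o[0]
    for j in range(n_phi):
        faces.append([0, first + (j + 1) % n_phi, first + j])
    for r in range(len(rows_o) - 1):
        a, b = rows_o[r], rows_o[r + 1]
        for j in range(n_phi):
            j2 = (j + 1) % n_phi
            faces.append([a + j, b + j, b + j2])
            faces.append([a + j, b + j2, a + j2])
    # inner dome, reversed orientation (outward normal points toward center)
    first_i = rows_i[0]
    for j in range(n_phi):
        faces.append([off, first_i + j, first_i + (j + 1) % n_phi])
    for r in range(len(rows_i) - 1):
        a, b = rows_i[r], rows_i[r + 1]
        for j in range(n_phi):
            j2 = (j + 1) % n_phi
            faces.append([a + j, b + j2, b + j])
            faces.append([a + j, a + j2, b + j2])
    # annulus between rims
    ro, ri = rows_o[-1], rows_i[-1]
    for j in range(n_phi):
        j2 = (j + 1) % n_phi
        faces.append([ro + j, ri + j, ri + j2])
        faces.append([ro + j, ri + j2, ro + j2])
    m = trimesh.Trimesh(vertices=np.asarray(verts), faces=np.asarray(faces), process=False)
    if m.volume < 0:
        m.invert()
    return m


def cap_shell_volume(r_inner: float, r_outer: float, half_angle_deg: float = 90.0) -> float:
    """Closed-form volume of the spherical shell restricted to the cap's
    solid angle: (4/3)π(r_o³ − r_i³) · (1 − cos α)/2."""
    frac = (1.0 - math.cos(math.radians(half_angle_deg))) / 2.0
    return 4.0 / 3.0 * math.pi * (r_outer**3 - r_inner**3) * frac


@dataclass
class GraftScene:
    """Donor graft apposed to a recipient bed with a known interface gap.

    ``graft`` is a solid spherical cap; ``bed`` a concentric shell whose
    concave surface sits ``gap_width`` further out; ``plug`` is the bone
    that encloses the open face of the scene (in vivo the interface is
    surrounded by bone, so the gap region is bounded); ``filler`` occupies
    the interface shell at soft-tissue HU (absent when the apposition is
    perfect).  The closed-form gap volume is recorded in the ground truth.
    """

    graft: BoneMesh
    bed: BoneMesh
    plug: BoneMesh
    filler: BoneMesh | None
    ground_truth: GroundTruth

    @property
    def bone_meshes(self) -> list[BoneMesh]:
        return [self.graft, self.bed, self.plug]

    def all_meshes(self) -> tuple[list[BoneMesh], list[float]]:
        meshes = [self.graft, self.bed, self.plug]
        hu = [HU_BONE, HU_BONE, HU_BONE]
        if self.filler is not None:
            meshes.append(self.filler)
            hu.append(HU_SOFT_TISSUE)
        return meshes, hu


def generate_graft_scene(bed_radius: float = 11.0, gap_width: float = 1.0,
                         extent_deg: float = 90.0,
                         bed_thickness: float = 6.0) -> GraftScene:
    """Build the donor-graft/recipient-bed interface scene.

    The gap is the spherical shell between the graft's convex surface
    (radius ``bed_radius``) and the bed's concave surface (radius
    ``bed_radius + gap_width``) over the cap's solid angle.
    """
    if gap_width < 0:
        raise ValueError("gap_width must be >= 0")
    graft = spherical_cap_solid(bed_radius, extent_deg)
    r_bed = bed_radius + gap_width
    # gap_width 0: the bed's concave surface coincides exactly with the
    # graft surface (identical tessellation), i.e. perfect apposition
    bed = spherical_shell_cap(r_bed, r_bed + bed_thickness, extent_deg)
    # bone plug sealing the open face, flush with the graft's cap plane
    z_top = -bed_radius * math.cos(math.radians(extent_deg))
    plug = trimesh.creation.cylinder(
        radius=r_bed + 2.0, height=2.0,
        transform=trimesh.transformations.translation_matrix(
            [0.0, 0.0, z_top + 1.0]),
    )
    filler = None
    if gap_width > 0:
        filler = spherical_shell_cap(bed_radius, r_bed, extent_deg)
    vol = cap_shell_volume(bed_radius, r_bed, extent_deg)
    gt = GroundTruth(
        head_center=np.zeros(3),
        neck_axis=Line(np.zeros(3), np.array([0.0, 0.0, -1.0])),
        diaphyseal_axis=Line(np.zeros(3), np.array([0.0, 0.0, 1.0])),
        axis_ml=np.array([1.0, 0.0, 0.0]),
        axis_cranial=np.array([0.0, 1.0, 0.0]),
        version=0.0,
        inclination=0.0,
        neck_length=0.0,
        side="right",
        analytic_gap_volume=vol,
        extras={"bed_radius": bed_radius, "gap_width": gap_width,
                "extent_deg": extent_deg},
    )
    return GraftScene(
        graft=BoneMesh(mesh=graft),
        bed=BoneMesh(mesh=bed),
        plug=BoneMesh(mesh=plug),
        filler=None if filler is None else BoneMesh(mesh=filler),
        ground_truth=gt,
    )


def generate_acetabulum(radius: float = 11.0, thickness: float = 4.0,
                        side: str = "right"):
    """Hemispherical acetabular shell with cranial/caudal border landmarks.

    The border landmarks sit on the rim along ±y (cranial/caudal), a true
    diameter (2 × radius) apart.
    """
    shell = spherical_shell_cap(radius, radius + thickness, 90.0)
    borders = {
        "cranial": np.array([0.0, radius, 0.0]),
        "caudal": np.array([0.0, -radius, 0.0]),
    }
    return BoneMesh(mesh=shell), borders


# ---------------------------------------------------------------------------
# rasterization


def rasterize(meshes, hu_values, spacing, padding: float = 2.0,
              origin=None, shape=None) -> tuple[CTVolume, dict[int, int]]:
    """Rasterize watertight meshes into a CT volume in Hounsfield units.

    Each voxel center takes the HU of the innermost (smallest-volume)
    containing mesh; uncovered voxels are background (−1000 HU).  Returns the
    volume and exact per-mesh exclusive voxel counts keyed by mesh index.
    """
    meshes = [m.mesh if isinstance(m, BoneMesh) else m for m in meshes]
    hu_values = list(hu_values)
    if len(meshes) != len(hu_values):
        raise ValueError("need one HU value per mesh")
    for i, m in enumerate(meshes):
        if not m.is_watertight:
            raise ValueError(f"mesh {i} is not watertight; cannot rasterize")
    spacing = np.broadcast_to(np.asarray(spacing, dtype=float), (3,)).copy()
    if np.any(spacing <= 0):
        raise ValueError("spacing must be positive")

    if origin is None or shape is None:
        if not meshes:
            raise ValueError("empty scene needs explicit origin and shape")
        lo = np.min([m.bounds[0] for m in meshes], axis=0) - padding
        hi = np.max([m.bounds[1] for m in meshes], axis=0) + padding
        origin = lo + spacing / 2.0
        shape = np.ceil((hi - lo) / spacing).astype(int)
    origin = np.asarray(origin, dtype=float)
    shape = tuple(int(s) for s in shape)

    hu = np.full(shape, HU_BACKGROUND, dtype=np.float32)
    owner = np.full(shape, -1, dtype=np.int16)
    # largest first so that smaller (inner) meshes overwrite
    order = sorted(range(len(meshes)), key=lambda i: -abs(meshes[i].volume))
    for i in order:
        mask = voxelize_parity(meshes[i], origin, shape, spacing)
        hu[mask] = hu_values[i]
        owner[mask] = i
    counts = {i: int(np.sum(owner == i)) for i in range(len(meshes))}
    vol = CTVolume(voxels=hu, spacing=spacing, origin=origin, direction=np.eye(3))
    return vol, counts
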