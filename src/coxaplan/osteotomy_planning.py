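"""Chevron osteotomy planning, virtual osteotomy execution and graft fit.

The femoral-head osteotomy is planned from the four physeal-scar landmarks:
one plane through the craniomedial, caudomedial and craniolateral points
(craniodistal-to-caudoproximal) and one through the caudomedial,
caudolateral and craniolateral points (cranioproximal-to-caudodistal).  The
two planes share the caudomedial and craniolateral landmarks, so the
chevron ridge is the line through those two points — asserted, not assumed.
Both normals are oriented so the femoral-head side is positive.

Virtual osteotomies clip a watertight bone mesh by both planes; cut faces
are capped with deterministically ear-clipped triangles so outputs are
bit-reproducible.  Donor-to-recipient superimposition is a least-squares
proper rigid alignment of the four landmarks (Kabsch); a reflection optimum
is treated as probable landmark mislabeling and rejected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import trimesh

from ._mesh import (
    cap_boundary_loops,
    point_mesh_distance,
    ray_first_hit_distance,
    weld_vertices,
)
from .core import BoneMesh, LandmarkSet, RigidTransform
from .geometry import DegenerateInputError, Plane, fit_sphere, plane_from_points

__all__ = [
    "OsteotomyPlan",
    "chevron_planes",
    "clip_mesh",
    "max_subchondral_thickness",
    "superimpose_landmarks",
    "interface_fit",
    "ThicknessResult",
    "InterfaceFit",
    "SUBCHONDRAL_THICKNESS_LIMIT_MM",
]

# upper bound on graft subchondral bone thickness (immune-load constraint)
SUBCHONDRAL_THICKNESS_LIMIT_MM = 8.0


@dataclass(frozen=True)
class OsteotomyPlan:
    """Two oriented planes in chevron configuration plus their landmarks.

    ``plane_a`` is the craniodistal-to-caudoproximal cut, ``plane_b`` the
    cranioproximal-to-caudodistal cut; the head side is positive for both.
    """

    plane_a: Plane
    plane_b: Plane
    source_landmarks: LandmarkSet

    @property
    def dihedral_angle(self) -> float:
        """Angle in degrees between the two plane normals."""
        c = float(np.clip(self.plane_a.normal @ self.plane_b.normal, -1.0, 1.0))
        return float(np.degrees(np.arccos(c)))


def chevron_planes(lm: LandmarkSet, head_reference=None) -> OsteotomyPlan:
    """Build the chevron osteotomy plan from the four physeal landmarks.

    When ``head_reference`` (a point on the femoral-head side, e.g. the head
    center) is given, both normals are oriented positive toward it;
    otherwise orientation follows the right-hand rule on the landmark order.
    The shared-landmark ridge property is asserted.
    """
    try:
        plane_a = plane_from_points(lm.craniomedial, lm.caudomedial, lm.craniolateral)
    except DegenerateInputError as e:
        raise DegenerateInputError(
            f"craniomedial/caudomedial/craniolateral triple is degenerate: {e}"
        ) from e
    try:
        plane_b = plane_from_points(lm.caudomedial, lm.caudolateral, lm.craniolateral)
    except DegenerateInputError as e:
        raise DegenerateInputError(
            f"caudomedial/caudolateral/craniolateral triple is degenerate: {e}"
        ) from e
    if head_reference is not None:
        ref = np.asarray(head_reference, dtype=float)
        if plane_a.signed_distance(ref) < 0:
            plane_a = Plane(plane_a.point, -plane_a.normal)
        if plane_b.signed_distance(ref) < 0:
            plane_b = Plane(plane_b.point, -plane_b.normal)
    # ridge property: the two shared landmarks lie on both planes
    diag = float(np.linalg.norm(np.ptp(lm.physeal_points(), axis=0)))
    for shared in (lm.caudomedial, lm.craniolateral):
        assert abs(plane_a.signed_distance(shared)) < 1e-9 * max(diag, 1.0)
        assert abs(plane_b.signed_distance(shared)) < 1e-9 * max(diag, 1.0)
    return OsteotomyPlan(plane_a=plane_a, plane_b=plane_b, source_landmarks=lm)


def _clip_halfspace(mesh: trimesh.Trimesh, plane: Plane,
                    keep_positive: bool) -> trimesh.Trimesh:
    n = plane.normal if keep_positive else -plane.normal
    sd = (mesh.vertices - plane.point) @ n
    if np.all(sd >= 0):
        return mesh.copy()
    if np.all(sd <= 0):
        return trimesh.Trimesh(vertices=np.zeros((0, 3)), faces=np.zeros((0, 3), int))
    cut = trimesh.intersections.slice_mesh_plane(
        mesh, plane_normal=n, plane_origin=plane.point, cap=False
    )
    if len(cut.faces) == 0:
        return cut
    # slicing leaves duplicate vertices along the cut; weld before capping
    return cap_boundary_loops(weld_vertices(cut), -n)


def clip_mesh(bone: BoneMesh | trimesh.Trimesh,
              plan: OsteotomyPlan) -> tuple[BoneMesh, BoneMesh]:
    """Execute the biplanar osteotomy: split a mesh into graft and remainder.

    The graft is the region on the positive (head) side of both planes; the
    remainder is everything else (possibly two pieces, returned as one
    multi-body mesh).  Both outputs are capped watertight, and
    ``volume(graft) + volume(remainder)`` equals the input volume to within
    0.1 %.
    """
    mesh = bone.mesh if isinstance(bone, BoneMesh) else bone
    if not mesh.is_watertight:
        raise ValueError("clip_mesh requires a watertight input mesh")
    pos_a = _clip_halfspace(mesh, plan.plane_a, keep_positive=True)
    rem_a = _clip_halfspace(mesh, plan.plane_a, keep_positive=False)
    if len(pos_a.faces):
        graft = _clip_halfspace(pos_a, plan.plane_b, keep_positive=True)
        rem_b = _clip_halfspace(pos_a, plan.plane_b, keep_positive=False)
    else:
        graft = pos_a
        rem_b = pos_a
    pieces = [m for m in (rem_a, rem_b) if len(m.faces)]
    remainder = trimesh.util.concatenate(pieces) if pieces else \
        trimesh.Trimesh(vertices=np.zeros((0, 3)), faces=np.zeros((0, 3), int))
    if len(graft.faces) == 0:
        warnings.warn("osteotomy planes do not intersect the mesh: empty graft",
                      stacklevel=2)
    return BoneMesh(mesh=graft), BoneMesh(mesh=remainder)


@dataclass(frozen=True)
class ThicknessResult:
    max_thickness: float
    thickness_ok: bool


def max_subchondral_thickness(graft: BoneMesh,
                              articular_region: str = "articular",
                              limit: float = SUBCHONDRAL_THICKNESS_LIMIT_MM
                              ) -> ThicknessResult:
    """Maximum subchondral bone thickness of an osteotomized graft.

    For every articular vertex the distance to the cut surface is measured
    by casting a ray along the inward surface normal (the radial direction
    of the best-fit articular sphere); the maximum over vertices is reported
    together with the ``< limit`` flag (default 8 mm).
    """
    mesh = graft.mesh
    if len(mesh.faces) == 0:
        return ThicknessResult(max_thickness=0.0, thickness_ok=True)
    if articular_region not in graft.regions:
        raise ValueError(
            f"graft has no {articular_region!r} vertex labels; "
            "thickness needs the articular region"
        )
    art_idx = np.asarray(graft.regions[articular_region], dtype=int)
    if len(art_idx) == 0:
        raise ValueError("articular region is empty")
    # the articular surface is spherical by construction of the procedure,
    # so its inward normal is the radial direction toward the fitted head
    # sphere center; per-vertex averaged mesh normals are corrupted at the
    # cut rim (cap faces share rim vertices) and are not used
    origins = mesh.vertices[art_idx]
    sphere = fit_sphere(origins)
    directions = sphere.center - origins
    norms = np.linalg.norm(directions, axis=1)
    good = norms > 1e-9
    origins = origins[good]
    directions = directions[good] / norms[good, None]
    # first surface hit along the inward radial ray is the cut (or far)
    # surface; t_min skips faces incident to the origin vertex itself
    dist = ray_first_hit_distance(origins, directions, mesh.triangles,
                                  t_min=1e-4)
    dist = dist[np.isfinite(dist)]
    tmax = float(dist.max()) if len(dist) else 0.0
    return ThicknessResult(max_thickness=tmax, thickness_ok=tmax < limit)


def superimpose_landmarks(src, dst) -> tuple[RigidTransform, float]:
    """Least-squares proper rigid alignment of corresponding landmarks.

    Kabsch algorithm on the (typically four physeal) point pairs; no scaling
    and no reflection.  If the optimal orthogonal transform is a reflection
    the landmark correspondence is probably mislabeled and an error is
    raised rather than silently flipping the bone.  Returns the transform
    mapping ``src`` onto ``dst`` and the post-alignment RMSD in mm.
    """
    src = np.asarray(src, dtype=float)
    dst = np.asarray(dst, dtype=float)
    if src.shape != dst.shape or src.ndim != 2 or src.shape[1] != 3:
        raise ValueError("src and dst must be matching (n, 3) arrays")
    if len(src) < 3:
        raise DegenerateInputError("need at least 3 landmark pairs")
    for name, pts in (("src", src), ("dst", dst)):
        c = pts - pts.mean(axis=0)
        if np.linalg.svd(c, compute_uv=False)[1] < 1e-9:
            raise DegenerateInputError(f"{name} landmarks are collinear")
    cs, cd = src.mean(axis=0), dst.mean(axis=0)
    H = (src - cs).T @ (dst - cd)
    U, _, Vt = np.linalg.svd(H)
    R = Vt.T @ U.T
    if np.linalg.det(R) < 0:
        raise DegenerateInputError(
            "optimal alignment is a reflection; landmark labels are probably "
            "mirrored between donor and recipient"
        )
    t = cd - R @ cs
    transform = RigidTransform(rotation=R, translation=t)
    rmsd = float(np.sqrt(np.mean(np.sum((transform.apply(src) - dst) ** 2, axis=1))))
    return transform, rmsd


def _sample_triangles(tris: np.ndarray, n: int, seed: int) -> np.ndarray:
    """Area-weighted uniform samples on a triangle soup (deterministic)."""
    rng = np.random.default_rng(seed)
    area = 0.5 * np.linalg.norm(
        np.cross(tris[:, 1] - tris[:, 0], tris[:, 2] - tris[:, 0]), axis=1)
    probs = area / area.sum()
    pick = rng.choice(len(tris), size=n, p=probs)
    r1 = np.sqrt(rng.random(n))
    r2 = rng.random(n)
    a, b, c = tris[pick, 0], tris[pick, 1], tris[pick, 2]
    return (1 - r1)[:, None] * a + (r1 * (1 - r2))[:, None] * b + (r1 * r2)[:, None] * c


@dataclass(frozen=True)
class InterfaceFit:
    mean_separation: float
    max_separation: float
    rms_separation: float


def interface_fit(donor_graft: BoneMesh, recipient_bed: BoneMesh,
                  transform: RigidTransform | None = None,
                  donor_faces=None, recipient_faces=None,
                  n_samples: int = 1000, seed: int = 0) -> InterfaceFit:
    """Mesh-space preview of donor–recipient apposition.

    Symmetric surface separation: points sampled on each (cut) surface are
    scored by their exact distance to the other surface (point-to-triangle),
    after applying ``transform`` to the donor.  ``donor_faces`` /
    ``recipient_faces`` restrict the statistic to the apposing cut faces;
    by default the whole surfaces are compared.  This is a planning-time
    check; the post-operative CT gap is measured volumetrically by
    :func:`coxaplan.segmentation.segment_gap`.
    """
    for name, b in (("donor graft", donor_graft), ("recipient bed", recipient_bed)):
        if not b.is_watertight:
            raise ValueError(f"{name} mesh is not watertight")
    dm = donor_graft.mesh
    if transform is not None:
        dm = dm.copy()
        dm.vertices = transform.apply(dm.vertices)
    rm = recipient_bed.mesh
    dt = dm.triangles if donor_faces is None else dm.triangles[np.asarray(donor_faces)]
    rt = rm.triangles if recipient_faces is None else rm.triangles[np.asarray(recipient_faces)]
    pd = _sample_triangles(dt, n_samples, seed)
    pr = _sample_triangles(rt, n_samples, seed + 1)
    d = np.concatenate([
        point_mesh_distance(pd, rt),
        point_mesh_distance(pr, dt),
    ])
    return InterfaceFit(
        mean_separation=float(d.mean()),
        max_separation=float(d.max()),
        rms_separation=float(np.sqrt(np.mean(d**2))),
    )
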