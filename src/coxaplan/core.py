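"""Shared domain containers: labeled bone meshes, anatomic landmark sets,
rigid transforms and reflections.

Region labels on a :class:`BoneMesh` are named vertex-index lists (``head``,
``neck``, ``diaphysis``, ``articular`` ...) supplied by the synthetic
generator or by manual annotation files; no automatic anatomical
parcellation is attempted anywhere in the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh

from .geometry import DegenerateInputError, Plane

__all__ = [
    "BoneMesh",
    "LandmarkSet",
    "RigidTransform",
    "reflect_points",
    "reflect_vectors",
]

PHYSEAL_NAMES = ("craniomedial", "craniolateral", "caudomedial", "caudolateral")


@dataclass
class BoneMesh:
    """Watertight triangulated bone surface with optional region labels."""

    mesh: trimesh.Trimesh
    regions: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def vertices(self) -> np.ndarray:
        return self.mesh.vertices

    @property
    def faces(self) -> np.ndarray:
        return self.mesh.faces

    @property
    def volume(self) -> float:
        return float(self.mesh.volume)

    @property
    def is_watertight(self) -> bool:
        return bool(self.mesh.is_watertight)

    def region_points(self, name: str) -> np.ndarray:
        """Vertex coordinates of a named region."""
        if name not in self.regions:
            raise KeyError(
                f"mesh has no region {name!r}; available: {sorted(self.regions)}"
            )
        return self.mesh.vertices[np.asarray(self.regions[name], dtype=int)]

    def transformed(self, t: "RigidTransform") -> "BoneMesh":
        m = self.mesh.copy()
        m.vertices = t.apply(m.vertices)
        return BoneMesh(mesh=m, regions={k: v.copy() for k, v in self.regions.items()})


@dataclass
class LandmarkSet:
    """Named anatomic points for one femur plus acetabular border points.

    The four physeal-scar points define the chevron osteotomy; the condylar
    points define the transcondylar axis; the acetabular border points (per
    side, cranial and caudal) define acetabular diameter.
    """

    craniomedial: np.ndarray
    craniolateral: np.ndarray
    caudomedial: np.ndarray
    caudolateral: np.ndarray
    condyle_medial: np.ndarray | None = None
    condyle_lateral: np.ndarray | None = None
    # {"left": {"cranial": p, "caudal": p}, "right": {...}}
    acetabular_borders: dict[str, dict[str, np.ndarray]] = field(default_factory=dict)
    side: str = "right"

    def __post_init__(self):
        for name in PHYSEAL_NAMES:
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        for name in ("condyle_medial", "condyle_lateral"):
            v = getattr(self, name)
            if v is not None:
                object.__setattr__(self, name, np.asarray(v, dtype=float))
        if self.side not in ("left", "right"):
            raise ValueError(f"side must be 'left' or 'right', got {self.side!r}")
        self._validate_physeal()

    def _validate_physeal(self):
        pts = self.physeal_points()
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        if np.any(d[np.triu_indices(4, 1)] < 1e-9):
            raise DegenerateInputError("physeal landmarks must be pairwise distinct")
        scale = d.max()
        # no three collinear
        import itertools

        for i, j, k in itertools.combinations(range(4), 3):
            v1 = pts[j] - pts[i]
            v2 = pts[k] - pts[i]
            if np.linalg.norm(np.cross(v1, v2)) < 1e-8 * scale**2:
                names = [PHYSEAL_NAMES[m] for m in (i, j, k)]
                raise DegenerateInputError(f"physeal landmarks {names} are collinear")

    def physeal_points(self) -> np.ndarray:
        return np.stack([getattr(self, n) for n in PHYSEAL_NAMES])

    def transformed(self, t: "RigidTransform") -> "LandmarkSet":
        ab = {
            s: {k: t.apply(p) for k, p in d.items()}
            for s, d in self.acetabular_borders.items()
        }
        return LandmarkSet(
            *(t.apply(getattr(self, n)) for n in PHYSEAL_NAMES),
            condyle_medial=None if self.condyle_medial is None else t.apply(self.condyle_medial),
            condyle_lateral=None if self.condyle_lateral is None else t.apply(self.condyle_lateral),
            acetabular_borders=ab,
            side=self.side,
        )


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid transform x ↦ R x + t (no scaling, no reflection)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        if R.shape != (3, 3) or t.shape != (3,):
            raise ValueError("rotation must be 3x3 and translation a 3-vector")
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-9):
            raise ValueError("rotation matrix is not orthogonal")
        if not np.isclose(np.linalg.det(R), 1.0, atol=1e-9):
            raise ValueError("rotation matrix has det != +1 (reflection?)")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points) -> np.ndarray:
        p = np.asarray(points, dtype=float)
        return p @ self.rotation.T + self.translation

    def apply_vector(self, v) -> np.ndarray:
        return np.asarray(v, dtype=float) @ self.rotation.T

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self ∘ other (apply ``other`` first)."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)


def reflect_points(points, plane: Plane) -> np.ndarray:
    """Mirror point(s) across a plane (Householder reflection)."""
    p = np.asarray(points, dtype=float)
    n = plane.normal
    d = (p - plane.point) @ n
    return p - 2.0 * np.multiply.outer(d, n)


def reflect_vectors(v, plane: Plane) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = plane.normal
    return v - 2.0 * np.multiply.outer(v @ n, n)
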