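"""HU thresholding, isosurface extraction, and donor–recipient gap volumetry.

Conventions: bone thresholding is inclusive (voxel ≥ ``hu_min``; default
300 HU, typical bone-window practice); gap thresholding is inclusive
(voxel ≤ ``hu_max``; default 250 HU).  The gap mask is restricted to
26-connected components that touch both a donor-side and a recipient-side
bone surface, a reproducible stand-in for manual cleanup of the thresholded
interface region.  No subvoxel/partial-volume estimation is performed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh
from scipy import ndimage
from skimage.measure import marching_cubes

from .core import BoneMesh

__all__ = [
    "CTVolume",
    "BinaryMask",
    "GapResult",
    "threshold_bone",
    "extract_surface",
    "roi_between_bones",
    "segment_gap",
    "DEFAULT_BONE_HU",
    "DEFAULT_GAP_HU",
]

DEFAULT_BONE_HU = 300.0
DEFAULT_GAP_HU = 250.0

_CONN26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class CTVolume:
    """Scalar HU voxel grid with physical-space metadata.

    ``voxels[i, j, k]`` sits at ``origin + direction @ (spacing * (i, j, k))``
    in a right-handed patient frame (mm).
    """

    voxels: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray
    direction: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError("voxels must be a 3D array")
        self.spacing = np.broadcast_to(
            np.asarray(self.spacing, dtype=float), (3,)).copy()
        if np.any(self.spacing <= 0):
            raise ValueError("spacing must be positive per axis")
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        self.direction = np.asarray(self.direction, dtype=float).reshape(3, 3)
        if not np.allclose(self.direction.T @ self.direction, np.eye(3), atol=1e-6):
            raise ValueError("direction must be orthonormal")

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape


@dataclass
class BinaryMask:
    """Boolean voxel grid sharing a CTVolume's geometry."""

    voxels: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray
    direction: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels, dtype=bool)
        self.spacing = np.broadcast_to(
            np.asarray(self.spacing, dtype=float), (3,)).copy()
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        self.direction = np.asarray(self.direction, dtype=float).reshape(3, 3)

    @classmethod
    def like(cls, vol: CTVolume, voxels: np.ndarray) -> "BinaryMask":
        if voxels.shape != vol.voxels.shape:
            raise ValueError(
                f"mask shape {voxels.shape} does not match volume {vol.voxels.shape}"
            )
        return cls(voxels=voxels, spacing=vol.spacing, origin=vol.origin,
                   direction=vol.direction)

    @property
    def count(self) -> int:
        return int(self.voxels.sum())

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def volume(self) -> float:
        """Total true-voxel volume in mm³."""
        return self.count * self.voxel_volume


@dataclass
class GapResult:
    """Segmented donor–recipient interface gap."""

    mask: BinaryMask
    volume: float
    component_count: int


def threshold_bone(vol: CTVolume, hu_min: float = DEFAULT_BONE_HU) -> BinaryMask:
    """Binary bone mask: voxels with HU ≥ ``hu_min`` (inclusive)."""
    if not -1024.0 <= hu_min <= 4000.0:
        raise ValueError(f"bone threshold {hu_min} HU outside sane range [-1024, 4000]")
    return BinaryMask.like(vol, vol.voxels >= hu_min)


def extract_surface(mask: BinaryMask) -> BoneMesh:
    """Triangulated isosurface of a binary mask in physical coordinates.

    Marching cubes at the 0.5 level of the binarized field; the mask is
    zero-padded first so surfaces at the grid border close, making the
    result watertight.
    """
    if mask.count == 0:
        raise ValueError("cannot extract a surface from an empty mask")
    padded = np.pad(mask.voxels.astype(np.float32), 1)
    verts, faces, _, _ = marching_cubes(padded, level=0.5, spacing=tuple(mask.spacing))
    verts = verts - mask.spacing  # undo pad offset
    verts = verts @ mask.direction.T + mask.origin
    # process=False keeps the marching-cubes topology closed
    mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=False)
    if mesh.volume < 0:
        mesh.invert()
    return BoneMesh(mesh=mesh)


def roi_between_bones(donor_mask: BinaryMask, recipient_mask: BinaryMask,
                      dilation_mm: float = 2.0) -> BinaryMask:
    """Region between two bone masks: both dilations overlap, minus the bones.

    The dilation radius (mm) is converted to an ellipsoidal voxel structuring
    element per axis, so anisotropic spacings behave isotropically in
    physical space.
    """
    if donor_mask.voxels.shape != recipient_mask.voxels.shape:
        raise ValueError("masks must share one voxel grid")
    if np.any(donor_mask.voxels & recipient_mask.voxels):
        raise ValueError("donor and recipient masks overlap; they must be disjoint")
    struct = _ellipsoid_structure(dilation_mm, donor_mask.spacing)
    d = ndimage.binary_dilation(donor_mask.voxels, structure=struct)
    r = ndimage.binary_dilation(recipient_mask.voxels, structure=struct)
    roi = d & r & ~donor_mask.voxels & ~recipient_mask.voxels
    return BinaryMask(voxels=roi, spacing=donor_mask.spacing,
                      origin=donor_mask.origin, direction=donor_mask.direction)


def _ellipsoid_structure(radius_mm: float, spacing) -> np.ndarray:
    rad = np.maximum(np.floor(radius_mm / np.asarray(spacing)).astype(int), 0)
    grids = np.meshgrid(*[np.arange(-r, r + 1) for r in rad], indexing="ij")
    dist2 = sum((g * s) ** 2 for g, s in zip(grids, spacing))
    return dist2 <= radius_mm**2 + 1e-9


def segment_gap(vol: CTVolume, roi: BinaryMask, hu_max: float = DEFAULT_GAP_HU,
                *, donor_mask: BinaryMask | None = None,
                recipient_mask: BinaryMask | None = None,
                bone_hu_min: float = DEFAULT_BONE_HU) -> GapResult:
    """Segment the donor–recipient interface gap inside an ROI.

    Candidate gap voxels are those within the ROI with HU ≤ ``hu_max``
    (inclusive; default 250 HU).  Only 26-connected components in contact
    with both the donor-side and the recipient-side bone are kept.  When the
    two bone masks are not supplied they are derived by thresholding at
    ``bone_hu_min`` and requiring contact with at least two distinct bone
    components.
    """
    if roi.count == 0:
        raise ValueError("gap ROI is empty")
    if roi.voxels.shape != vol.voxels.shape:
        raise ValueError("ROI does not share the volume's voxel grid")
    cand = roi.voxels & (vol.voxels <= hu_max)
    labels, n = ndimage.label(cand, structure=_CONN26)
    keep = np.zeros(n + 1, dtype=bool)
    if n > 0:
        if donor_mask is not None and recipient_mask is not None:
            touch_d = _touching_labels(labels, n, donor_mask.voxels)
            touch_r = _touching_labels(labels, n, recipient_mask.voxels)
            keep[1:] = touch_d & touch_r
        else:
            bone = vol.voxels >= bone_hu_min
            bone_labels, nb = ndimage.label(bone, structure=_CONN26)
            # a genuine interface gap borders at least two distinct bones
            for comp in range(1, n + 1):
                ring = ndimage.binary_dilation(labels == comp, structure=_CONN26)
                adj = np.unique(bone_labels[ring])
                keep[comp] = np.count_nonzero(adj) >= 2
    gap = keep[labels]
    mask = BinaryMask.like(vol, gap)
    return GapResult(mask=mask, volume=mask.volume,
                     component_count=int(keep[1:].sum()))


def _touching_labels(labels: np.ndarray, n: int, bone: np.ndarray) -> np.ndarray:
    ring = ndimage.binary_dilation(bone, structure=_CONN26)
    touched = np.unique(labels[ring & (labels > 0)])
    out = np.zeros(n, dtype=bool)
    out[touched - 1] = True
    return out
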