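"""Internal mesh utilities: implicit-surface meshing, planar capping, voxelization.

These are deliberately self-contained numpy implementations:

* ``mesh_from_sdf`` extracts a watertight surface from a signed-distance
  field by marching cubes (scikit-image) — used to build union-of-primitive
  bone shapes without a mesh boolean engine.
* ``cap_boundary_loops`` closes the planar boundary left by a plane cut with
  deterministically ear-clipped triangles.
* ``voxelize_parity`` converts a closed triangulated surface into an
  inside/outside voxel mask by counting triangle crossings along z-columns,
  vectorized over (triangle, column) pairs.  Exact for watertight input and
  fast enough for sub-millimetre grids of tens of millions of voxels.
"""

from __future__ import annotations

import numpy as np
import trimesh
from skimage.measure import marching_cubes


# ---------------------------------------------------------------------------
# implicit surface -> mesh


def mesh_from_sdf(sdf, bounds, pitch: float, level: float = 0.0) -> trimesh.Trimesh:
    """Triangulate the ``level`` isosurface of a signed-distance function.

    ``sdf`` maps an (n, 3) array of points (mm) to signed distances
    (negative inside).  ``bounds`` is ((xmin, ymin, zmin), (xmax, ymax, zmax));
    it must enclose the surface with at least one voxel margin.
    """
    lo = np.asarray(bounds[0], dtype=float)
    hi = np.asarray(bounds[1], dtype=float)
    shape = np.maximum(np.ceil((hi - lo) / pitch).astype(int) + 1, 2)
    axes = [lo[i] + pitch * np.arange(shape[i]) for i in range(3)]
    grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1)
    vals = sdf(grid.reshape(-1, 3)).reshape(shape)
    verts, faces, _, _ = marching_cubes(vals, level=level, spacing=(pitch,) * 3)
    # process=False: marching-cubes output is already manifold and watertight;
    # vertex merging/degenerate-face removal can open it up
    mesh = trimesh.Trimesh(vertices=verts + lo, faces=faces, process=False)
    if mesh.volume < 0:
        mesh.invert()
    return mesh


def mesh_from_primitives(primitives, bounds, pitch: float) -> trimesh.Trimesh:
    """Watertight union surface of sphere/cylinder primitives.

    ``primitives`` is a list of ``("sphere", center, radius)`` or
    ``("cylinder", p0, p1, radius)`` tuples.  The union SDF (pointwise
    minimum) is evaluated only inside each primitive's padded bounding slab,
    which makes sub-half-millimetre grids over whole-bone extents cheap.
    """
    lo = np.asarray(bounds[0], dtype=float)
    hi = np.asarray(bounds[1], dtype=float)
    shape = np.maximum(np.ceil((hi - lo) / pitch).astype(int) + 1, 2)
    axes = [lo[i] + pitch * np.arange(shape[i]) for i in range(3)]
    far = 4.0 * pitch + 1.0
    vals = np.full(tuple(shape), far, dtype=np.float32)
    for prim in primitives:
        kind = prim[0]
        if kind == "sphere":
            _, center, radius = prim
            center = np.asarray(center, dtype=float)
            blo = center - radius - far
            bhi = center + radius + far
        elif kind == "cylinder":
            _, p0, p1, radius = prim
            p0 = np.asarray(p0, dtype=float)
            p1 = np.asarray(p1, dtype=float)
            blo = np.minimum(p0, p1) - radius - far
            bhi = np.maximum(p0, p1) + radius + far
        else:
            raise ValueError(f"unknown primitive kind {kind!r}")
        i0 = np.maximum(np.floor((blo - lo) / pitch).astype(int), 0)
        i1 = np.minimum(np.ceil((bhi - lo) / pitch).astype(int) + 1, shape)
        if np.any(i0 >= i1):
            continue
        sub = np.stack(np.meshgrid(
            *[axes[d][i0[d]:i1[d]] for d in range(3)], indexing="ij"), axis=-1)
        pts = sub.reshape(-1, 3)
        if kind == "sphere":
            sd = sdf_sphere(pts, center, radius)
        else:
            sd = sdf_capped_cylinder(pts, p0, p1, radius)
        view = vals[i0[0]:i1[0], i0[1]:i1[1], i0[2]:i1[2]]
        np.minimum(view, sd.reshape(view.shape).astype(np.float32), out=view)
    verts, faces, _, _ = marching_cubes(vals, level=0.0, spacing=(pitch,) * 3)
    mesh = trimesh.Trimesh(vertices=verts + lo, faces=faces, process=False)
    if mesh.volume < 0:
        mesh.invert()
    return mesh


# primitive SDFs (exact)


def sdf_sphere(points, center, radius):
    return np.linalg.norm(points - np.asarray(center), axis=1) - radius


def sdf_capped_cylinder(points, p0, p1, radius):
    """Exact SDF of a finite cylinder with flat caps from p0 to p1."""
    p0 = np.asarray(p0, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    axis = p1 - p0
    h = np.linalg.norm(axis)
    d = axis / h
    rel = points - p0
    t = rel @ d
    radial = np.linalg.norm(rel - np.outer(t, d), axis=1)
    dr = radial - radius            # >0 outside lateral surface
    dz = np.maximum(-t, t - h)      # >0 beyond a cap
    outside = np.sqrt(np.maximum(dr, 0) ** 2 + np.maximum(dz, 0) ** 2)
    inside = np.minimum(np.maximum(dr, dz), 0.0)
    return outside + inside


# ---------------------------------------------------------------------------
# planar capping


def weld_vertices(mesh: trimesh.Trimesh, tol: float = 1e-7) -> trimesh.Trimesh:
    """Merge positionally identical vertices and drop degenerate faces.

    Plane slicing emits unmerged duplicate vertices along the cut, which
    breaks boundary-loop chaining; welding restores shared topology.
    """
    key = np.round(mesh.vertices / tol).astype(np.int64)
    _, idx, inv = np.unique(key, axis=0, return_index=True, return_inverse=True)
    # keep original coordinates (first occurrence), not the rounded ones
    order = np.argsort(idx)
    rank = np.empty_like(order)
    rank[order] = np.arange(len(order))
    verts = mesh.vertices[idx[order]]
    faces = rank[inv][mesh.faces]
    ok = (
        (faces[:, 0] != faces[:, 1])
        & (faces[:, 1] != faces[:, 2])
        & (faces[:, 0] != faces[:, 2])
    )
    return trimesh.Trimesh(vertices=verts, faces=faces[ok], process=False)


def boundary_loops(mesh: trimesh.Trimesh) -> list[np.ndarray]:
    """Closed vertex loops of the open boundary, each as an index array."""
    edges = mesh.edges_sorted
    order = np.lexsort(edges.T[::-1])
    es = edges[order]
    # edges appearing exactly once are boundary
    uniq, counts = np.unique(es, axis=0, return_counts=True)
    bedges = uniq[counts == 1]
    if len(bedges) == 0:
        return []
    nxt: dict[int, list[int]] = {}
    for a, b in bedges:
        nxt.setdefault(int(a), []).append(int(b))
        nxt.setdefault(int(b), []).append(int(a))
    unused = {tuple(e) for e in bedges.tolist()}
    loops = []
    while unused:
        a, b = min(unused)   # deterministic start
        unused.discard((a, b))
        loop = [a, b]
        while loop[-1] != loop[0]:
            cur, prev = loop[-1], loop[-2]
            cands = [
                v for v in nxt[cur]
                if tuple(sorted((cur, v))) in unused
            ]
            if not cands:
                break  # open chain: drop (non-manifold input)
            v = min(cands)
            unused.discard(tuple(sorted((cur, v))))
            loop.append(v)
        if loop[-1] == loop[0] and len(loop) > 3:
            loops.append(np.asarray(loop[:-1], dtype=int))
    return loops


def _ear_clip(poly2d: np.ndarray) -> list[tuple[int, int, int]]:
    """Deterministic ear clipping of a simple CCW polygon; returns index triples.

    Convex polygons (the common cut cross-section) take a linear fan path;
    the general path runs ear clipping with vectorized containment tests.
    """
    n = len(poly2d)
    if n < 3:
        return []
    v = poly2d
    nxt = np.roll(np.arange(n), -1)
    prv = np.roll(np.arange(n), 1)
    a2, b2 = v[nxt] - v, v[prv] - v
    crossz = a2[:, 0] * b2[:, 1] - a2[:, 1] * b2[:, 0]  # >0: convex corner (CCW)
    if np.all(crossz >= -1e-12):
        # convex: fan from vertex 0
        return [(0, k, k + 1) for k in range(1, n - 1)]

    def corner_cross(i0, i1, i2):
        o, a, b = v[i0], v[i1], v[i2]
        return (a[0] - o[0]) * (b[1] - o[1]) - (a[1] - o[1]) * (b[0] - o[0])

    idx = list(range(n))
    tris: list[tuple[int, int, int]] = []
    guard = 0
    while len(idx) > 3 and guard < 10 * n:
        guard += 1
        m = len(idx)
        clipped = False
        arr = np.asarray(idx)
        for k in range(m):
            i0, i1, i2 = idx[(k - 1) % m], idx[k], idx[(k + 1) % m]
            if corner_cross(i0, i1, i2) <= 1e-12:
                continue  # reflex or degenerate corner
            others = arr[(arr != i0) & (arr != i1) & (arr != i2)]
            p = v[others]
            o, a, b = v[i0], v[i1], v[i2]
            d1 = (a[0] - o[0]) * (p[:, 1] - o[1]) - (a[1] - o[1]) * (p[:, 0] - o[0])
            d2 = (b[0] - a[0]) * (p[:, 1] - a[1]) - (b[1] - a[1]) * (p[:, 0] - a[0])
            d3 = (o[0] - b[0]) * (p[:, 1] - b[1]) - (o[1] - b[1]) * (p[:, 0] - b[0])
            if np.any((d1 >= -1e-12) & (d2 >= -1e-12) & (d3 >= -1e-12)):
                continue  # another vertex inside the candidate ear
            tris.append((i0, i1, i2))
            idx.pop(k)
            clipped = True
            break
        if not clipped:
            break  # fall through to fan on pathological input
    if len(idx) == 3:
        tris.append((idx[0], idx[1], idx[2]))
    elif len(idx) > 3:
        for k in range(1, len(idx) - 1):
            tris.append((idx[0], idx[k], idx[k + 1]))
    return tris


def cap_boundary_loops(mesh: trimesh.Trimesh, plane_normal) -> trimesh.Trimesh:
    """Close planar boundary loops of ``mesh`` lying in a cut plane.

    ``plane_normal`` is the outward direction of the solid at the cut (i.e.
    it points out of the retained half-space); cap faces are oriented so
    their outward normal aligns with it.
    """
    n = np.asarray(plane_normal, dtype=float)
    n = n / np.linalg.norm(n)
    loops = boundary_loops(mesh)
    if not loops:
        return mesh
    # 2D basis in the cut plane
    e1 = np.cross(n, [0.0, 0.0, 1.0])
    if np.linalg.norm(e1) < 1e-6:
        e1 = np.cross(n, [1.0, 0.0, 0.0])
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(n, e1)

    verts = mesh.vertices.copy()
    new_faces = []
    for loop in loops:
        pts = verts[loop]
        poly = np.column_stack([pts @ e1, pts @ e2])
        area2 = np.sum(poly[:, 0] * np.roll(poly[:, 1], -1)
                       - np.roll(poly[:, 0], -1) * poly[:, 1])
        want_ccw = loop if area2 > 0 else loop[::-1]
        pts = verts[want_ccw]
        poly = np.column_stack([pts @ e1, pts @ e2])
        for (a, b, c) in _ear_clip(poly):
            va, vb, vc = want_ccw[a], want_ccw[b], want_ccw[c]
            tri_n = np.cross(verts[vb] - verts[va], verts[vc] - verts[va])
            if tri_n @ n >= 0:
                new_faces.append([va, vb, vc])
            else:
                new_faces.append([va, vc, vb])
    faces = np.vstack([mesh.faces, np.asarray(new_faces, dtype=int)])
    return trimesh.Trimesh(vertices=verts, faces=faces, process=False)


# ---------------------------------------------------------------------------
# point-to-surface distance


def _point_segment_distance2(p, a, b):
    """Squared distance from points p (n,3) to segments a-b (n,3)."""
    ab = b - a
    denom = np.einsum("ij,ij->i", ab, ab)
    t = np.einsum("ij,ij->i", p - a, ab) / np.where(denom > 0, denom, 1.0)
    t = np.clip(t, 0.0, 1.0)
    d = p - (a + t[:, None] * ab)
    return np.einsum("ij,ij->i", d, d)


def point_mesh_distance(points, triangles, chunk_tris: int = 2000) -> np.ndarray:
    """Distance from each point to a triangle soup (exact, vectorized).

    Closest point per (point, triangle) pair is either the in-plane
    projection (when its barycentric coordinates are inside) or the nearest
    point on one of the three edges; the minimum over triangles is returned.
    """
    points = np.asarray(points, dtype=float)
    tris = np.asarray(triangles, dtype=float)
    best = np.full(len(points), np.inf)
    for s in range(0, len(tris), chunk_tris):
        t = tris[s:s + chunk_tris]
        v0, v1, v2 = t[:, 0], t[:, 1], t[:, 2]
        n = np.cross(v1 - v0, v2 - v0)
        nn = np.einsum("ij,ij->i", n, n)
        # pairs (p, tri)
        P = points[:, None, :]
        d0 = P - v0[None, :, :]
        n_len = np.sqrt(np.where(nn > 0, nn, 1.0))
        dist_plane = np.einsum("ptj,tj->pt", d0, n) / n_len
        proj = P - dist_plane[..., None] * (n / n_len[:, None])[None, :, :]
        # barycentric inside test of projection
        def edge_sign(a, b):
            return np.einsum("ptj,tj->pt", np.cross(b[None, :, :] - a[None, :, :],
                                                    proj - a[None, :, :]), n)
        s1 = edge_sign(v0, v1)
        s2 = edge_sign(v1, v2)
        s3 = edge_sign(v2, v0)
        inside = ((s1 >= 0) & (s2 >= 0) & (s3 >= 0)) | ((s1 <= 0) & (s2 <= 0) & (s3 <= 0))
        d2 = np.where(inside, dist_plane**2, np.inf)
        # edge distances for all pairs (cheap enough, keeps logic simple)
        npts, ntri = d2.shape
        pp = np.repeat(points, ntri, axis=0)
        for a, b in ((v0, v1), (v1, v2), (v2, v0)):
            aa = np.tile(a, (npts, 1))
            bb = np.tile(b, (npts, 1))
            d2e = _point_segment_distance2(pp, aa, bb).reshape(npts, ntri)
            d2 = np.minimum(d2, d2e)
        best = np.minimum(best, np.sqrt(d2.min(axis=1)))
    return best


# ---------------------------------------------------------------------------
# ray casting


def ray_first_hit_distance(origins, directions, triangles,
                           t_min: float = 1e-6) -> np.ndarray:
    """First-hit distance of each ray against a triangle soup.

    Vectorized Möller–Trumbore over (ray, triangle) pairs, chunked over
    rays.  Returns +inf where a ray hits nothing.
    """
    origins = np.asarray(origins, dtype=float)
    directions = np.asarray(directions, dtype=float)
    tris = np.asarray(triangles, dtype=float)
    out = np.full(len(origins), np.inf)
    if len(tris) == 0 or len(origins) == 0:
        return out
    v0, v1, v2 = tris[:, 0], tris[:, 1], tris[:, 2]
    e1 = v1 - v0
    e2 = v2 - v0
    chunk = max(1, 2_000_000 // len(tris))
    for s in range(0, len(origins), chunk):
        o = origins[s:s + chunk][:, None, :]
        d = directions[s:s + chunk][:, None, :]
        p = np.cross(d, e2[None, :, :])
        det = np.einsum("rtj,tj->rt", p, e1)
        with np.errstate(divide="ignore", invalid="ignore"):
            inv = 1.0 / det
            tvec = o - v0[None, :, :]
            u = np.einsum("rtj,rtj->rt", tvec, p) * inv
            q = np.cross(tvec, e1[None, :, :])
            v = np.einsum("rtj,rj->rt", q, directions[s:s + chunk]) * inv
            t = np.einsum("rtj,tj->rt", q, e2) * inv
            hit = (np.abs(det) > 1e-12) & (u >= -1e-9) & (v >= -1e-9) \
                & (u + v <= 1 + 1e-9) & (t > t_min)
        t = np.where(hit, t, np.inf)
        out[s:s + chunk] = t.min(axis=1)
    return out


# ---------------------------------------------------------------------------
# voxelization


def voxelize_parity(mesh: trimesh.Trimesh, origin, shape, spacing) -> np.ndarray:
    """Boolean inside-mask of a closed surface on a regular voxel grid.

    Voxel center (i, j, k) sits at ``origin + (i, j, k) * spacing`` (physical
    mm, axis-aligned).  A center is inside when an odd number of triangle
    crossings lie above it along +z.  Exact for watertight meshes; voxel
    centers are jittered by a fixed sub-nanometre epsilon so that mesh edges
    passing exactly through sample columns cannot be double counted.
    """
    origin = np.asarray(origin, dtype=float)
    spacing = np.broadcast_to(np.asarray(spacing, dtype=float), (3,))
    nx, ny, nz = (int(s) for s in shape)
    tri = mesh.triangles  # (T, 3, 3)
    if len(tri) == 0:
        return np.zeros((nx, ny, nz), dtype=bool)

    eps = np.array([1.17e-7, 2.31e-7])  # mm; deterministic jitter
    xs = origin[0] + spacing[0] * np.arange(nx) + eps[0]
    ys = origin[1] + spacing[1] * np.arange(ny) + eps[1]
    zs = origin[2] + spacing[2] * np.arange(nz)

    counts = np.zeros((nx * ny, nz + 1), dtype=np.int32)

    # map triangles to the column-index ranges their xy-bbox covers
    txy = tri[:, :, :2]
    lo = txy.min(axis=1)
    hi = txy.max(axis=1)
    ix0 = np.clip(np.ceil((lo[:, 0] - xs[0]) / spacing[0]), 0, nx - 1).astype(int)
    ix1 = np.clip(np.floor((hi[:, 0] - xs[0]) / spacing[0]), -1, nx - 1).astype(int)
    iy0 = np.clip(np.ceil((lo[:, 1] - ys[0]) / spacing[1]), 0, ny - 1).astype(int)
    iy1 = np.clip(np.floor((hi[:, 1] - ys[0]) / spacing[1]), -1, ny - 1).astype(int)
    wx = np.maximum(ix1 - ix0 + 1, 0)
    wy = np.maximum(iy1 - iy0 + 1, 0)
    npairs = wx * wy
    keep = npairs > 0
    if not np.any(keep):
        return np.zeros((nx, ny, nz), dtype=bool)
    tri = tri[keep]
    ix0, iy0, wx, wy = ix0[keep], iy0[keep], wx[keep], wy[keep]
    npairs = npairs[keep]

    # expand to flat (triangle, column) pairs, chunked to bound memory
    order = np.argsort(npairs, kind="stable")
    tri, ix0, iy0, wx, wy, npairs = (
        a[order] for a in (tri, ix0, iy0, wx, wy, npairs))
    total = int(npairs.sum())
    chunk = max(1, 4_000_000 // max(int(npairs.max()), 1))
    for start in range(0, len(tri), chunk):
        sl = slice(start, start + chunk)
        t = tri[sl]
        reps = npairs[sl]
        tidx = np.repeat(np.arange(len(t)), reps)
        # local pair index -> (dx, dy) offsets within each triangle's bbox
        offs = np.arange(reps.sum()) - np.repeat(np.cumsum(reps) - reps, reps)
        w = wx[sl][tidx]
        dx = offs % w
        dy = offs // w
        cx = ix0[sl][tidx] + dx
        cy = iy0[sl][tidx] + dy
        px = xs[cx]
        py = ys[cy]

        a, b, c = t[tidx, 0], t[tidx, 1], t[tidx, 2]
        d1 = (b[:, 0] - a[:, 0]) * (py - a[:, 1]) - (b[:, 1] - a[:, 1]) * (px - a[:, 0])
        d2 = (c[:, 0] - b[:, 0]) * (py - b[:, 1]) - (c[:, 1] - b[:, 1]) * (px - b[:, 0])
        d3 = (a[:, 0] - c[:, 0]) * (py - c[:, 1]) - (a[:, 1] - c[:, 1]) * (px - c[:, 0])
        inside = ((d1 > 0) & (d2 > 0) & (d3 > 0)) | ((d1 < 0) & (d2 < 0) & (d3 < 0))
        if not np.any(inside):
            continue
        a, b, c = a[inside], b[inside], c[inside]
        px, py = px[inside], py[inside]
        cx, cy = cx[inside], cy[inside]
        # barycentric z of the crossing
        det = (b[:, 1] - c[:, 1]) * (a[:, 0] - c[:, 0]) + \
              (c[:, 0] - b[:, 0]) * (a[:, 1] - c[:, 1])
        l1 = ((b[:, 1] - c[:, 1]) * (px - c[:, 0]) + (c[:, 0] - b[:, 0]) * (py - c[:, 1])) / det
        l2 = ((c[:, 1] - a[:, 1]) * (px - c[:, 0]) + (a[:, 0] - c[:, 0]) * (py - c[:, 1])) / det
        zc = l1 * a[:, 2] + l2 * b[:, 2] + (1 - l1 - l2) * c[:, 2]
        # first voxel-center index strictly above the crossing
        iz = np.clip(np.ceil((zc - zs[0]) / spacing[2] + 1e-12), 0, nz).astype(int)
        np.add.at(counts, (cx * ny + cy, iz), 1)

    below = np.cumsum(counts[:, ::-1], axis=1)[:, ::-1]  # crossings at/above each center
    mask = (below[:, 1:] % 2 == 1)
    # crossings above center -> center below surface top an odd number of times
    return mask.reshape(nx, ny, nz)
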