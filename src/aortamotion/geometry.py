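"""Vectorized closest-point and ray-casting queries against triangle meshes.

All queries are brute-force-exact on a candidate set found with a KD-tree
broad phase, chunked to bound memory.  They are deterministic and depend
only on vertex/face arrays, which keeps registration runs bit-reproducible.
"""

from __future__ import annotations

import numba
import numpy as np
import trimesh
from scipy.spatial import cKDTree


class SurfaceQuery:
    """Reusable closest-point query structure for one triangle mesh.

    Broad phase: the ``k`` triangles with nearest centroids (KD-tree),
    plus all triangles incident to the nearest vertex; narrow phase: exact
    point-to-triangle projection.  For well-shaped surface meshes (triangle
    size comparable to its neighbours') this finds the true closest point.
    """

    def __init__(self, mesh: trimesh.Trimesh, k: int = 8):
        self.mesh = mesh
        self.triangles = mesh.triangles.view(np.ndarray)
        self.faces = mesh.faces.view(np.ndarray)
        self.k = min(k, len(self.triangles))
        self._centroid_tree = cKDTree(self.triangles.mean(axis=1))
        self._vertex_tree = cKDTree(mesh.vertices.view(np.ndarray))
        # vertex -> incident faces, padded ragged array
        n_v = len(mesh.vertices)
        counts = np.bincount(self.faces.ravel(), minlength=n_v)
        self._max_deg = int(counts.max()) if len(counts) else 0
        vf = np.full((n_v, self._max_deg), -1, dtype=np.int64)
        cursor = np.zeros(n_v, dtype=np.int64)
        for fi, face in enumerate(self.faces):
            for v in face:
                vf[v, cursor[v]] = fi
                cursor[v] += 1
        self._vertex_faces = vf

    def closest_point(
        self, points: np.ndarray, chunk: int = 2048
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Closest point on the surface for each query point.

        Returns ``(closest, distance, face_index)`` with shapes
        (n, 3), (n,), (n,).
        """
        points = np.atleast_2d(np.asarray(points, dtype=float))
        n = len(points)
        out_pt = np.empty((n, 3))
        out_d = np.empty(n)
        out_f = np.empty(n, dtype=np.int64)
        for lo in range(0, n, chunk):
            hi = min(lo + chunk, n)
            self._closest_chunk(points[lo:hi], out_pt[lo:hi], out_d[lo:hi], out_f[lo:hi])
        return out_pt, out_d, out_f

    def _closest_chunk(self, pts, out_pt, out_d, out_f) -> None:
        m = len(pts)
        _, cand = self._centroid_tree.query(pts, k=self.k)
        cand = np.atleast_2d(cand)
        _, nearest_v = self._vertex_tree.query(pts)
        incident = self._vertex_faces[nearest_v]  # (m, max_deg), -1 padded
        cand = np.hstack([cand, np.where(incident < 0, cand[:, :1], incident)])
        kk = cand.shape[1]
        tris = self.triangles[cand.ravel()]  # (m*kk, 3, 3)
        rep = np.repeat(pts, kk, axis=0)
        cp = trimesh.triangles.closest_point(tris, rep).reshape(m, kk, 3)
        d2 = ((cp - pts[:, None, :]) ** 2).sum(axis=2)
        best = d2.argmin(axis=1)
        rows = np.arange(m)
        out_pt[:] = cp[rows, best]
        out_d[:] = np.sqrt(d2[rows, best])
        out_f[:] = cand[rows, best]


def closest_point_on_surface(
    mesh: trimesh.Trimesh, points: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """One-shot :class:`SurfaceQuery` convenience wrapper."""
    return SurfaceQuery(mesh).closest_point(points)


@numba.njit(fastmath=True)
def _mt_first_hit(origins, directions, v0, e1, e2, min_t, max_t):  # pragma: no cover
    n_rays = origins.shape[0]
    n_tri = v0.shape[0]
    best = np.full(n_rays, np.inf)
    for i in range(n_rays):
        ox, oy, oz = origins[i, 0], origins[i, 1], origins[i, 2]
        dx, dy, dz = directions[i, 0], directions[i, 1], directions[i, 2]
        b = np.inf
        for j in range(n_tri):
            e1x, e1y, e1z = e1[j, 0], e1[j, 1], e1[j, 2]
            e2x, e2y, e2z = e2[j, 0], e2[j, 1], e2[j, 2]
            px = dy * e2z - dz * e2y
            py = dz * e2x - dx * e2z
            pz = dx * e2y - dy * e2x
            det = e1x * px + e1y * py + e1z * pz
            if -1e-12 < det < 1e-12:
                continue
            inv = 1.0 / det
            tx = ox - v0[j, 0]
            ty = oy - v0[j, 1]
            tz = oz - v0[j, 2]
            u = (tx * px + ty * py + tz * pz) * inv
            if u < -1e-9 or u > 1.0 + 1e-9:
                continue
            qx = ty * e1z - tz * e1y
            qy = tz * e1x - tx * e1z
            qz = tx * e1y - ty * e1x
            v = (dx * qx + dy * qy + dz * qz) * inv
            if v < -1e-9 or u + v > 1.0 + 1e-9:
                continue
            t = (e2x * qx + e2y * qy + e2z * qz) * inv
            if min_t < t <= max_t and t < b:
                b = t
        best[i] = b
    return best


def ray_cast_first_hit(
    mesh: trimesh.Trimesh,
    origins: np.ndarray,
    directions: np.ndarray,
    min_t: float = 0.0,
    max_t: float = np.inf,
) -> tuple[np.ndarray, np.ndarray]:
    """First ray-triangle intersection distance per ray (Möller–Trumbore).

    Returns ``(t, hit)``: distance along each (unit) direction to the first
    triangle hit with ``min_t < t <= max_t``, and a validity flag.  Rays with
    no such hit get ``t = inf`` and ``hit = False``.
    """
    origins = np.ascontiguousarray(np.atleast_2d(origins), dtype=np.float64)
    directions = np.ascontiguousarray(np.atleast_2d(directions), dtype=np.float64)
    tri = mesh.triangles.view(np.ndarray)
    v0 = np.ascontiguousarray(tri[:, 0])
    e1 = np.ascontiguousarray(tri[:, 1] - tri[:, 0])
    e2 = np.ascontiguousarray(tri[:, 2] - tri[:, 0])
    best = _mt_first_hit(origins, directions, v0, e1, e2, float(min_t), float(max_t))
    hit = np.isfinite(best)
    return best, hit
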