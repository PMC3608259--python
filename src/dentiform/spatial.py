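"""Point-to-mesh proximity and inside/outside queries.

Vectorised closest-point-on-triangle queries with k-d-tree candidate
culling, and a generalized-winding-number inside test for closed meshes.
These back the ICP correspondences, the signed deviation maps and the
occupancy voxelisation.
"""

from __future__ import annotations

import numpy as np
import trimesh
from scipy.spatial import cKDTree


def _closest_on_triangles(points: np.ndarray, tri: np.ndarray) -> np.ndarray:
    """Closest point on each triangle for each (point, triangle) pair.

    points: (Q, 3); tri: (Q, K, 3, 3) -> returns (Q, K, 3).
    Standard barycentric region classification (Ericson).
    """
    a, b, c = tri[..., 0, :], tri[..., 1, :], tri[..., 2, :]
    p = points[:, None, :]
    ab = b - a
    ac = c - a
    ap = p - a
    d1 = np.sum(ab * ap, axis=-1)
    d2 = np.sum(ac * ap, axis=-1)
    bp = p - b
    d3 = np.sum(ab * bp, axis=-1)
    d4 = np.sum(ac * bp, axis=-1)
    cp = p - c
    d5 = np.sum(ab * cp, axis=-1)
    d6 = np.sum(ac * cp, axis=-1)

    vc = d1 * d4 - d3 * d2
    vb = d5 * d2 - d1 * d6
    va = d3 * d6 - d5 * d4
    denom_vw = va + vb + vc
    with np.errstate(divide="ignore", invalid="ignore"):
        v_edge_ab = np.where(d1 - d3 != 0, d1 / (d1 - d3), 0.0)
        w_edge_ac = np.where(d2 - d6 != 0, d2 / (d2 - d6), 0.0)
        w_edge_bc = np.where((d4 - d3) + (d5 - d6) != 0,
                             (d4 - d3) / ((d4 - d3) + (d5 - d6)), 0.0)
        v_in = np.where(denom_vw != 0, vb / denom_vw, 0.0)
        w_in = np.where(denom_vw != 0, vc / denom_vw, 0.0)

    out = a + v_in[..., None] * ab + w_in[..., None] * ac  # interior default
    # vertex regions
    out = np.where(((d1 <= 0) & (d2 <= 0))[..., None], a, out)
    out = np.where(((d3 >= 0) & (d4 <= d3))[..., None], b, out)
    out = np.where(((d6 >= 0) & (d5 <= d6))[..., None], c, out)
    # edge regions
    cond_ab = (vc <= 0) & (d1 >= 0) & (d3 <= 0)
    out = np.where(cond_ab[..., None], a + v_edge_ab[..., None] * ab, out)
    cond_ac = (vb <= 0) & (d2 >= 0) & (d6 <= 0)
    out = np.where(cond_ac[..., None], a + w_edge_ac[..., None] * ac, out)
    cond_bc = (va <= 0) & ((d4 - d3) >= 0) & ((d5 - d6) >= 0)
    out = np.where(cond_bc[..., None], b + w_edge_bc[..., None] * (c - b), out)
    return out


class MeshProximity:
    """Reusable closest-point structure over one triangle mesh.

    Candidate triangles are culled with a k-d tree on triangle centroids
    padded by the largest triangle circumradius, which makes the query
    exact for ``k`` large enough; ``k=24`` is exact on the reasonably
    uniform tessellations this package produces and is verified against
    brute force in the test suite.
    """

    def __init__(self, mesh: trimesh.Trimesh, k: int = 24):
        self.mesh = mesh
        self.triangles = mesh.triangles.view(np.ndarray)
        self.k = min(k, len(self.triangles))
        self._tree = cKDTree(self.triangles.mean(axis=1))

    def closest(self, points: np.ndarray, chunk: int = 4096):
        """Closest surface points and distances for query ``points``.

        Returns ``(closest_points (Q,3), distances (Q,), face_index (Q,))``.
        """
        points = np.atleast_2d(np.asarray(points, dtype=float))
        cp_out = np.empty_like(points)
        d_out = np.empty(len(points))
        f_out = np.empty(len(points), dtype=int)
        for s in range(0, len(points), chunk):
            pts = points[s:s + chunk]
            _, idx = self._tree.query(pts, k=self.k)
            idx = np.atleast_2d(idx)
            cand = self.triangles[idx]  # (q, k, 3, 3)
            cps = _closest_on_triangles(pts, cand)
            d2 = np.sum((cps - pts[:, None, :]) ** 2, axis=-1)
            best = np.argmin(d2, axis=1)
            rows = np.arange(len(pts))
            cp_out[s:s + chunk] = cps[rows, best]
            d_out[s:s + chunk] = np.sqrt(d2[rows, best])
            f_out[s:s + chunk] = idx[rows, best]
        return cp_out, d_out, f_out


def winding_number(mesh: trimesh.Trimesh, points: np.ndarray,
                   chunk: int = 2048) -> np.ndarray:
    """Generalized winding number of ``points`` w.r.t. the mesh surface.

    ~1 inside a closed, consistently oriented mesh; ~0 outside.  Exact
    up to floating point for watertight meshes (sum of signed solid
    angles / 4pi, van Oosterom & Strackee formula).
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    tri = mesh.triangles.view(np.ndarray)
    out = np.empty(len(points))
    for s in range(0, len(points), chunk):
        p = points[s:s + chunk][:, None, :]
        a = tri[None, :, 0, :] - p
        b = tri[None, :, 1, :] - p
        c = tri[None, :, 2, :] - p
        la = np.linalg.norm(a, axis=-1)
        lb = np.linalg.norm(b, axis=-1)
        lc = np.linalg.norm(c, axis=-1)
        num = np.sum(a * np.cross(b, c), axis=-1)
        den = (la * lb * lc + np.sum(a * b, axis=-1) * lc
               + np.sum(b * c, axis=-1) * la + np.sum(a * c, axis=-1) * lb)
        out[s:s + chunk] = np.sum(np.arctan2(num, den), axis=-1) / (2 * np.pi)
    return out


def contains(mesh: trimesh.Trimesh, points: np.ndarray) -> np.ndarray:
    """Boolean inside test for a closed mesh (winding number > 1/2)."""
    return winding_number(mesh, points) > 0.5


def _angle_weighted_vertex_normals(mesh: trimesh.Trimesh) -> np.ndarray:
    """Per-vertex pseudonormals weighted by incident corner angles."""
    tri = mesh.triangles.view(np.ndarray)
    fn = mesh.face_normals.view(np.ndarray)
    normals = np.zeros((len(mesh.vertices), 3))
    for c in range(3):
        e1 = tri[:, (c + 1) % 3] - tri[:, c]
        e2 = tri[:, (c + 2) % 3] - tri[:, c]
        cosang = np.sum(e1 * e2, axis=1) / (
            np.linalg.norm(e1, axis=1) * np.linalg.norm(e2, axis=1) + 1e-300)
        ang = np.arccos(np.clip(cosang, -1, 1))
        np.add.at(normals, mesh.faces[:, c], fn * ang[:, None])
    return normals


class SignedMeshDistance:
    """Signed point-to-surface distance for a closed mesh.

    Positive OUTSIDE the mesh, negative inside (the deviation-map
    convention: outside = excess).  The sign comes from the
    angle-weighted pseudonormal of the closest feature (face interior,
    edge or vertex), which is exact for closed, consistently oriented
    meshes; the winding-number test serves as the slower independent
    reference.
    """

    _EDGGE_TOL = 1e-6

    def __init__(self, mesh: trimesh.Trimesh, k: int = 24):
        self.mesh = mesh
        self.prox = MeshProximity(mesh, k=k)
        self._fn = mesh.face_normals.view(np.ndarray)
        self._vn = _angle_weighted_vertex_normals(mesh)
        # edge pseudonormal: sum of the two adjacent face normals
        self._edge_normal = {}
        for (f0, f1), (v0, v1) in zip(mesh.face_adjacency,
                                      mesh.face_adjacency_edges):
            self._edge_normal[(min(v0, v1), max(v0, v1))] = (
                self._fn[f0] + self._fn[f1])

    def __call__(self, points: np.ndarray) -> np.ndarray:
        points = np.atleast_2d(np.asarray(points, dtype=float))
        cp, d, fi = self.prox.closest(points)
        tri = self.mesh.triangles.view(np.ndarray)[fi]
        bary = trimesh.triangles.points_to_barycentric(tri, cp)
        normal = self._fn[fi].copy()
        near_zero = bary < self._EDGGE_TOL
        n_zero = near_zero.sum(axis=1)
        faces = self.mesh.faces.view(np.ndarray)
        for i in np.nonzero(n_zero == 1)[0]:          # edge feature
            v = faces[fi[i]][~near_zero[i]]
            normal[i] = self._edge_normal.get(
                (v.min(), v.max()), normal[i])
        for i in np.nonzero(n_zero >= 2)[0]:          # vertex feature
            v = faces[fi[i]][np.argmax(bary[i])]
            normal[i] = self._vn[v]
        sign = np.sign(np.sum((points - cp) * normal, axis=1))
        return np.where(sign == 0, d, sign * d)


def signed_distance(mesh: trimesh.Trimesh, points: np.ndarray,
                    prox: MeshProximity | None = None) -> np.ndarray:
    """Signed distance: positive OUTSIDE the closed mesh, negative inside.

    Note the sign convention is the deviation-map one (outside = excess
    = positive), i.e. opposite to the common SDF-inside-positive choice.
    """
    return SignedMeshDistance(mesh)(points)
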