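"""Minimal spline/surface kernel.

B-spline curves (open clamped and closed periodic), lofted section
surfaces, bilinearly blended Coons patches, surfaces of revolution, and
tessellation of any of these into triangle meshes.

All coordinates are millimetres.  Curves and surfaces are parameterised
on [0, 1] (surfaces on the unit square).  Curve evaluation is delegated
to :class:`scipy.interpolate.BSpline`; the value added here is the
closed/periodic handling, the surface constructions and the watertight
tessellation (seam and pole welding).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import trimesh
from scipy.interpolate import BSpline, PchipInterpolator


class GeometryError(ValueError):
    """Invalid geometric input (bad parameter domain, open boundary loop...)."""


# ---------------------------------------------------------------------------
# curves
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BSplineCurve:
    """Polynomial B-spline curve in 3-space.

    Parameters
    ----------
    control_points : (n, 3) array
        Ordered de Boor control points, mm.
    degree : int
        Polynomial degree, >= 1.  Open curves use a clamped knot vector
        (end-knot multiplicity ``degree + 1``) so the curve interpolates
        its end control points; closed curves are periodic with
        C^(degree-1) continuity at the seam.
    closed : bool
        Periodic curve if True.
    knots : array, optional
        Explicit non-decreasing knot vector for open curves (advanced
        use, e.g. curves produced by spline interpolation).  Ignored for
        closed curves.  When given it must have ``n + degree + 1``
        entries and is rescaled to span [0, 1].
    """

    control_points: np.ndarray
    degree: int = 3
    closed: bool = False
    knots: np.ndarray | None = None
    _spline: BSpline = field(init=False, repr=False, compare=False)

    def __post_init__(self):
        cp = np.atleast_2d(np.asarray(self.control_points, dtype=float))
        if cp.ndim != 2 or cp.shape[1] != 3:
            raise GeometryError("control_points must be an (n, 3) array")
        p = int(self.degree)
        if p < 1:
            raise GeometryError("degree must be >= 1")
        n = len(cp)
        if n < p + 1:
            raise GeometryError(
                f"need at least degree+1={p + 1} control points, got {n}")
        object.__setattr__(self, "control_points", cp)
        object.__setattr__(self, "degree", p)

        if self.closed:
            # periodic: wrap the first `degree` control points and use a
            # uniform knot vector; evaluation domain [0, 1] maps to one
            # full period.
            coeffs = np.vstack([cp, cp[:p]])
            knots = (np.arange(-p, n + p + 1)) / n
            object.__setattr__(self, "knots", knots)
            spline = BSpline(knots, coeffs, p, extrapolate=False)
        else:
            if self.knots is not None:
                knots = np.asarray(self.knots, dtype=float)
                if len(knots) != n + p + 1:
                    raise GeometryError(
                        f"knot vector must have n+degree+1={n + p + 1} entries")
                if np.any(np.diff(knots) < 0):
                    raise GeometryError("knot vector must be non-decreasing")
                lo, hi = knots[p], knots[-p - 1]
                knots = (knots - lo) / (hi - lo)
            else:
                interior = np.linspace(0.0, 1.0, n - p + 1)
                knots = np.concatenate([np.zeros(p), interior, np.ones(p)])
            object.__setattr__(self, "knots", knots)
            spline = BSpline(knots, cp, p, extrapolate=False)
        object.__setattr__(self, "_spline", spline)

    def evaluate(self, t) -> np.ndarray:
        """Evaluate the curve at parameter(s) ``t`` in [0, 1]."""
        t = np.asarray(t, dtype=float)
        scalar = t.ndim == 0
        t = np.atleast_1d(t)
        if self.closed:
            t = np.mod(t, 1.0)
        else:
            if np.any(t < -1e-12) or np.any(t > 1 + 1e-12):
                raise GeometryError("curve parameter t outside [0, 1]")
            t = np.clip(t, 0.0, 1.0)
        out = self._spline(t)
        return out[0] if scalar else out

    __call__ = evaluate


def evaluate_curve(curve: BSplineCurve, t) -> np.ndarray:
    """Functional alias for :meth:`BSplineCurve.evaluate`."""
    return curve.evaluate(t)


def interpolating_open_curve(points: Sequence, degree: int = 3) -> BSplineCurve:
    """Open B-spline passing exactly through ``points`` (chord-length parameters)."""
    from scipy.interpolate import make_interp_spline

    pts = np.asarray(points, dtype=float)
    k = min(degree, len(pts) - 1)
    d = np.r_[0.0, np.cumsum(np.linalg.norm(np.diff(pts, axis=0), axis=1))]
    if d[-1] == 0:
        raise GeometryError("interpolation points are coincident")
    spl = make_interp_spline(d / d[-1], pts, k=k)
    return BSplineCurve(spl.c, degree=k, closed=False, knots=spl.t)


# ---------------------------------------------------------------------------
# surfaces
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ParametricSurface:
    """Surface S(u, v) on the unit square backed by a vectorised evaluator.

    ``kind`` is one of ``{"loft", "coons", "revolution", "custom"}``.
    ``closed_u`` marks rotational / sectional periodicity in u (seam is
    welded during tessellation).
    """

    kind: str
    evaluator: Callable[[np.ndarray, np.ndarray], np.ndarray]
    closed_u: bool = False
    generators: tuple = ()

    def evaluate(self, u, v) -> np.ndarray:
        u = np.asarray(u, dtype=float)
        v = np.asarray(v, dtype=float)
        scalar = u.ndim == 0 and v.ndim == 0
        u, v = np.broadcast_arrays(np.atleast_1d(u), np.atleast_1d(v))
        pts = self.evaluator(u.ravel(), v.ravel()).reshape(u.shape + (3,))
        if not np.all(np.isfinite(pts)):
            raise GeometryError("surface evaluation produced non-finite points")
        return pts[0] if scalar else pts

    __call__ = evaluate


def _section_winding_ccw(curve: BSplineCurve) -> bool:
    """Signed area test (about +z) on a dense polygon of the section."""
    u = np.linspace(0, 1, 128, endpoint=False)
    p = curve.evaluate(u)
    x, y = p[:, 0], p[:, 1]
    area2 = np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)
    return area2 > 0


def _reverse_closed(curve: BSplineCurve) -> BSplineCurve:
    return BSplineCurve(curve.control_points[::-1].copy(), degree=curve.degree,
                        closed=True)


def loft_sections(sections: Sequence[BSplineCurve],
                  v_levels: Sequence[float] | None = None) -> ParametricSurface:
    """Skin an ordered stack of closed section curves.

    u runs around each section, v along the stack.  The surface
    interpolates section ``k`` exactly at ``v = v_levels[k]`` (default:
    uniformly spaced levels).  The along-stack interpolation is a
    shape-preserving piecewise-cubic (monotone) spline, so sections are
    reproduced without overshoot; two sections give a ruled surface.
    Sections are auto-reoriented counter-clockwise about +z.
    """
    sections = list(sections)
    if len(sections) < 2:
        raise GeometryError("loft needs at least 2 sections")
    if not all(c.closed for c in sections):
        raise GeometryError("loft sections must all be closed curves")
    sections = [c if _section_winding_ccw(c) else _reverse_closed(c)
                for c in sections]
    if v_levels is None:
        v_levels = np.linspace(0.0, 1.0, len(sections))
    v_levels = np.asarray(v_levels, dtype=float)
    if len(v_levels) != len(sections) or np.any(np.diff(v_levels) <= 0):
        raise GeometryError("v_levels must be strictly increasing, one per section")

    def ev(u, v):
        rings = np.stack([c.evaluate(u) for c in sections])  # (K, N, 3)
        if len(sections) == 2:
            w = (v - v_levels[0]) / (v_levels[1] - v_levels[0])
            return rings[0] * (1 - w)[:, None] + rings[1] * w[:, None]
        interp = PchipInterpolator(v_levels, rings, axis=0)
        uniq, inv = np.unique(np.clip(v, v_levels[0], v_levels[-1]),
                              return_inverse=True)
        vals = interp(uniq)  # (U, N, 3)
        return vals[inv, np.arange(len(u))]

    return ParametricSurface("loft", ev, closed_u=True, generators=tuple(sections))


def ruled_surface(bottom: BSplineCurve, top: BSplineCurve,
                  closed_u: bool = False) -> ParametricSurface:
    """Straight-line blend between two curves sharing a parameterisation."""

    def ev(u, v):
        return bottom.evaluate(u) * (1 - v)[:, None] + top.evaluate(u) * v[:, None]

    return ParametricSurface("loft", ev, closed_u=closed_u,
                             generators=(bottom, top))


def coons_patch(boundary: Sequence[BSplineCurve],
                tol: float = 1e-6) -> ParametricSurface:
    """Bilinearly blended Coons patch from 4 boundary curves.

    Boundary order and orientation: ``c0`` = bottom edge (v=0, u left to
    right), ``c1`` = right edge (u=1, v bottom to top), ``c2`` = top edge
    (v=1, u left to right), ``c3`` = left edge (u=0, v bottom to top).
    Consecutive curves must share corner points within ``tol``.
    """
    if len(boundary) != 4:
        raise GeometryError("coons_patch needs exactly 4 boundary curves")
    c0, c1, c2, c3 = boundary
    p00, p10 = c0.evaluate(0.0), c0.evaluate(1.0)
    p01, p11 = c2.evaluate(0.0), c2.evaluate(1.0)
    corners = [
        (p00, c3.evaluate(0.0)), (p10, c1.evaluate(0.0)),
        (p01, c3.evaluate(1.0)), (p11, c1.evaluate(1.0)),
    ]
    for a, b in corners:
        if np.linalg.norm(a - b) > tol:
            raise GeometryError(
                "coons_patch boundary loop not closed within tolerance "
                f"({np.linalg.norm(a - b):.3g} mm gap)")

    def ev(u, v):
        u1 = u[:, None]
        v1 = v[:, None]
        ruledu = (1 - v1) * c0.evaluate(u) + v1 * c2.evaluate(u)
        ruledv = (1 - u1) * c3.evaluate(v) + u1 * c1.evaluate(v)
        bilin = ((1 - u1) * (1 - v1) * p00 + u1 * (1 - v1) * p10
                 + (1 - u1) * v1 * p01 + u1 * v1 * p11)
        return ruledu + ruledv - bilin

    return ParametricSurface("coons", ev, closed_u=False,
                             generators=tuple(boundary))


def revolve_profile(profile: BSplineCurve,
                    axis_point=(0.0, 0.0, 0.0),
                    axis_direction=(0.0, 0.0, 1.0)) -> ParametricSurface:
    """Surface of revolution of a half-plane profile about an axis.

    The profile is interpreted in the local x-z half-plane of the axis
    frame (x = radial distance >= 0, z = position along the axis); u is
    the rotation-angle fraction, v the profile parameter.  A profile
    crossing the axis (negative radius) is rejected.
    """
    axis_point = np.asarray(axis_point, dtype=float)
    d = np.asarray(axis_direction, dtype=float)
    d = d / np.linalg.norm(d)
    # local frame: e1, e2 span the plane normal to the axis
    tmp = np.array([1.0, 0.0, 0.0]) if abs(d[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e1 = np.cross(tmp, d)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(d, e1)

    vv = np.linspace(0, 1, 256)
    prof = profile.evaluate(vv)
    if np.any(prof[:, 0] < -1e-9):
        raise GeometryError("revolution profile crosses the axis (negative radius)")

    def ev(u, v):
        p = profile.evaluate(v)
        r, z = p[:, 0], p[:, 2]
        ang = 2 * np.pi * u
        return (axis_point
                + np.outer(r * np.cos(ang), e1)
                + np.outer(r * np.sin(ang), e2)
                + np.outer(z, d))

    return ParametricSurface("revolution", ev, closed_u=True,
                             generators=(profile, (axis_point, d)))


# ---------------------------------------------------------------------------
# tessellation
# ---------------------------------------------------------------------------

def tessellate(surface: ParametricSurface, nu: int = 64, nv: int = 48,
               weld_tol: float = 1e-8) -> trimesh.Trimesh:
    """Sample the surface on an (nu x nv) grid and triangulate.

    Vertices are exact surface evaluations.  Surfaces closed in u are
    seam-welded by index wrapping; degenerate end rings (poles, e.g. a
    revolution profile tapering onto the axis) collapse to a single apex
    vertex with a triangle fan.
    """
    if nu < 3 or nv < 3:
        raise GeometryError("tessellation needs nu, nv >= 3")
    if surface.closed_u:
        u = np.arange(nu) / nu
    else:
        u = np.linspace(0.0, 1.0, nu)
    v = np.linspace(0.0, 1.0, nv)
    uu, vv = np.meshgrid(u, v, indexing="ij")
    grid = surface.evaluate(uu, vv)  # (nu, nv, 3)

    verts, faces = grid_to_mesh(grid, closed_u=surface.closed_u,
                                weld_tol=weld_tol)
    mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=False)
    mesh.update_faces(mesh.nondegenerate_faces(height=1e-10))
    mesh.remove_unreferenced_vertices()
    if mesh.is_watertight:
        orient_outward(mesh)
    return mesh


def grid_to_mesh(grid: np.ndarray, closed_u: bool,
                 weld_tol: float = 1e-8):
    """Triangulate a (nu, nv, 3) sample grid; weld poles and the u-seam."""
    nu, nv, _ = grid.shape
    ring_span = np.array([np.ptp(grid[:, j, :], axis=0).max() for j in range(nv)])
    pole_lo = closed_u and ring_span[0] < max(weld_tol, 1e-6)
    pole_hi = closed_u and ring_span[-1] < max(weld_tol, 1e-6)

    j0 = 1 if pole_lo else 0
    j1 = nv - 1 if pole_hi else nv
    body = grid[:, j0:j1, :]
    nvb = j1 - j0
    verts = [body.reshape(-1, 3)]
    idx = np.arange(nu * nvb).reshape(nu, nvb)
    nxt = 0

    faces = []
    iu = np.arange(nu) if closed_u else np.arange(nu - 1)
    iu1 = (iu + 1) % nu if closed_u else iu + 1
    for j in range(nvb - 1):
        a = idx[iu, j]
        b = idx[iu1, j]
        c = idx[iu1, j + 1]
        dd = idx[iu, j + 1]
        faces.append(np.stack([a, b, c], axis=1))
        faces.append(np.stack([a, c, dd], axis=1))
    nxt = nu * nvb
    if pole_lo:
        apex = grid[:, 0, :].mean(axis=0)
        verts.append(apex[None])
        a = idx[iu, 0]
        b = idx[iu1, 0]
        faces.append(np.stack([np.full(len(iu), nxt), b, a], axis=1))
        nxt += 1
    if pole_hi:
        apex = grid[:, -1, :].mean(axis=0)
        verts.append(apex[None])
        a = idx[iu, nvb - 1]
        b = idx[iu1, nvb - 1]
        faces.append(np.stack([np.full(len(iu), nxt), a, b], axis=1))
        nxt += 1
    return np.vstack(verts), np.vstack(faces)


def weld_meshes(parts: Sequence[trimesh.Trimesh],
                tol: float = 1e-6) -> trimesh.Trimesh:
    """Concatenate meshes and merge coincident vertices within ``tol``.

    Used to assemble multi-patch solids whose patches share boundary
    curves sampled at identical parameters: shared-ring vertices
    coincide to machine precision and fuse into a single watertight
    shell.
    """
    verts = []
    faces = []
    off = 0
    for m in parts:
        verts.append(m.vertices)
        faces.append(m.faces + off)
        off += len(m.vertices)
    mesh = trimesh.Trimesh(vertices=np.vstack(verts), faces=np.vstack(faces),
                           process=False)
    mesh.merge_vertices(digits_vertex=int(-np.log10(tol)))
    mesh.update_faces(mesh.nondegenerate_faces(height=1e-10))
    mesh.remove_unreferenced_vertices()
    if mesh.is_watertight:
        orient_outward(mesh)
    return mesh


def orient_outward(mesh: trimesh.Trimesh) -> None:
    """Make face windings consistent and outward-pointing, in place.

    Vectorised replacement for per-face traversal repair: computes the
    winding parity of every adjacent face pair, propagates flips along a
    breadth-first spanning forest of the face-adjacency graph, then uses
    the signed volume to point normals outward.  Assumes an edge-manifold
    mesh (every edge shared by at most two faces).
    """
    from scipy.sparse import coo_matrix
    from scipy.sparse.csgraph import breadth_first_order, connected_components

    faces = mesh.faces.view(np.ndarray)
    adj = mesh.face_adjacency
    if len(adj) == 0:
        return
    edges = mesh.face_adjacency_edges  # (E, 2) vertex ids of shared edge

    def direction(face_ids):
        f = faces[face_ids]
        a, b = edges[:, 0], edges[:, 1]
        # True where the shared edge appears as a->b in the face cycle
        fwd = (((f[:, 0] == a) & (f[:, 1] == b))
               | ((f[:, 1] == a) & (f[:, 2] == b))
               | ((f[:, 2] == a) & (f[:, 0] == b)))
        return fwd

    # consistent orientation = shared edge traversed in opposite directions
    same = direction(adj[:, 0]) == direction(adj[:, 1])
    n = len(faces)
    graph = coo_matrix((np.ones(len(adj)), (adj[:, 0], adj[:, 1])),
                       shape=(n, n)).tocsr()
    parity = {}
    for (f0, f1), s in zip(adj, same):
        parity[f0 * n + f1] = s
        parity[f1 * n + f0] = s
    n_comp, labels = connected_components(graph, directed=False)
    flip = np.zeros(n, dtype=bool)
    for comp in range(n_comp):
        start = int(np.argmax(labels == comp))
        order, pred = breadth_first_order(graph, start, directed=False)
        for node in order[1:]:
            p = pred[node]
            flip[node] = flip[p] ^ parity[p * n + node]
    new_faces = faces.copy()
    new_faces[flip] = new_faces[flip][:, ::-1]
    mesh.faces = new_faces
    if mesh.is_watertight and mesh.volume < 0:
        mesh.invert()


def is_closed(mesh: trimesh.Trimesh) -> bool:
    """Every edge shared by exactly two faces (edge-manifold, watertight)."""
    return bool(mesh.is_watertight)
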