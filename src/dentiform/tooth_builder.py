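"""Parametric tooth construction.

Two builders assemble watertight triangle meshes from the named
panoramic-radiograph control parameters plus a fixed, dimensionless
shape template:

* :func:`build_monoradicular` — maxillary-incisor-like tooth: root
  lofted through closed B-spline sections, crown made of four Coons
  patches bounded by B-spline profile curves, a connection loft joining
  crown base to the cervical section.
* :func:`build_multiradicular` — mandibular-molar-like tooth: roots as
  surfaces of revolution with B-spline-style profile curves, a root
  trunk, and an explicit furcation (pant-leg) junction; an optional
  third (palatal) root supports maxillary molars.

Canonical frame: tooth axis = +z (occlusal up), mesial = +x,
buccal/labial = +y, origin at the centre of the cement-enamel junction
(CEJ) plane.  All linear quantities in mm.  The template holds only
dimensionless ratios, so builds are exactly scale-equivariant.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import trimesh

from .geometry import (
    BSplineCurve,
    ParametricSurface,
    coons_patch,
    grid_to_mesh,
    loft_sections,
    tessellate,
    weld_meshes,
)


class ParameterError(ValueError):
    """A control parameter violates an invariant; names the offending field."""


# ---------------------------------------------------------------------------
# parameter records
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MonoradicularParams:
    """Control parameters of a single-rooted tooth (mm).

    T_H total height (apex to incisal edge), C_H crown height (CEJ to
    incisal edge), CEJ cervical width, EQU crown equator width, RAD
    root width at half root length.
    """

    T_H: float
    C_H: float
    CEJ: float
    EQU: float
    RAD: float

    def validate(self) -> None:
        for name in ("T_H", "C_H", "CEJ", "EQU", "RAD"):
            if not getattr(self, name) > 0:
                raise ParameterError(f"{name} must be positive")
        if not self.C_H < self.T_H:
            raise ParameterError("C_H must be smaller than T_H")
        if not self.RAD <= self.CEJ:
            raise ParameterError("RAD must not exceed CEJ")
        if not self.CEJ <= self.EQU:
            raise ParameterError("CEJ must not exceed EQU")


@dataclass(frozen=True)
class MultiradicularParams:
    """Control parameters of a multi-rooted tooth (mm).

    Heights are cusp-to-apex (MT_H, DT_H) and cusp-to-CEJ (MC_H, DC_H)
    for the mesial/distal sides; MRAD/DRAD are root widths at half root
    length; H_FURC is the furcation-to-(shorter-root-)apex distance.
    PRAD/PT_H add an optional palatal root.
    """

    EQU: float
    CEJ: float
    MC_H: float
    DC_H: float
    MT_H: float
    DT_H: float
    MRAD: float
    DRAD: float
    H_FURC: float | None = None
    PRAD: float | None = None
    PT_H: float | None = None

    def validate(self) -> None:
        required = ("EQU", "CEJ", "MC_H", "DC_H", "MT_H", "DT_H", "MRAD", "DRAD")
        for name in required:
            if not getattr(self, name) > 0:
                raise ParameterError(f"{name} must be positive")
        for name in ("H_FURC", "PRAD", "PT_H"):
            val = getattr(self, name)
            if val is not None and not val > 0:
                raise ParameterError(f"{name} must be positive when given")
        if not self.MC_H < self.MT_H:
            raise ParameterError("MC_H must be smaller than MT_H")
        if not self.DC_H < self.DT_H:
            raise ParameterError("DC_H must be smaller than DT_H")
        if not self.CEJ <= self.EQU:
            raise ParameterError("CEJ must not exceed EQU")
        if (self.PRAD is None) != (self.PT_H is None):
            raise ParameterError("PRAD and PT_H must be given together")
        if self.PT_H is not None and not self.PT_H > max(self.MC_H, self.DC_H):
            raise ParameterError("PT_H must exceed the crown heights")
        root_lengths = [self.MT_H - self.MC_H, self.DT_H - self.DC_H]
        if self.H_FURC is not None and not self.H_FURC < min(root_lengths):
            raise ParameterError(
                "H_FURC must be smaller than the shortest root length")


# ---------------------------------------------------------------------------
# shape templates
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ShapeTemplate:
    """Immutable dimensionless proportions closing the parameter gap.

    The radiograph supplies a handful of lengths; everything else about
    the shape (section roundness, crown depth/width ratio, blend
    heights, inter-root spacing...) is fixed here, playing the role of
    literature-average tooth proportions.
    """

    template_id: str
    ratios: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self):
        object.__setattr__(self, "ratios", dict(self.ratios))
        for key, val in self.ratios.items():
            if not 0 < val <= 2:
                raise ParameterError(
                    f"template ratio {key}={val} outside (0, 2]")

    def __getitem__(self, key: str) -> float:
        return self.ratios[key]


_INCISOR_TEMPLATE = ShapeTemplate("incisor-default", {
    # cross sections
    "crown_depth_ratio": 0.80,       # section depth / width in the crown
    "root_depth_ratio": 0.92,
    "section_squareness": 0.10,
    "labial_bias": 0.14,             # labial (+y) fullness of sections
    # axial layout
    "equator_height_fraction": 0.32,  # z of equator / C_H
    "collar_width_ratio": 1.03,       # subcervical flare / CEJ
    "collar_depth_fraction": 0.08,    # collar depth below CEJ / root length
    "apex_taper": 0.01,               # apex section width / RAD
    # incisal edge
    "tip_width_fraction_mesial": 0.40,   # mesial half-width of edge / EQU
    "tip_width_fraction_distal": 0.30,   # distal (more rounded) / EQU
    "tip_arch_fraction": 0.12,           # labial bow of the edge / EQU
    "profile_bulge_fraction": 0.07,      # crown profile bulge / EQU
})

_MOLAR_TEMPLATE = ShapeTemplate("molar-default", {
    # cross sections
    "crown_depth_ratio": 0.96,
    "trunk_depth_ratio": 0.90,
    "section_squareness": 0.45,
    "labial_bias": 0.05,
    # crown layout
    "equator_height_fraction": 0.42,  # z of equator / mean crown height
    "rim_width_fraction": 0.72,       # occlusal rim width / EQU
    "cusp_dome_fraction": 0.14,       # cusp rise above the rim / mean crown h
    "fossa_depth_fraction": 0.10,     # central fossa dip / mean crown h
    "cusp_x_fraction": 0.26,          # cusp x offset / EQU
    # cervix and roots
    "collar_width_ratio": 1.03,
    "collar_depth_fraction": 0.18,    # of trunk length
    "root_flare": 1.04,               # root radius at furcation / (RAD/2)
    "trunk_width_fraction": 0.95,     # furcation-level trunk width / CEJ
    "web_gap_fraction": 0.08,         # junction web gap / root radius
    "min_root_gap_fraction": 0.02,    # min inter-root clearance / CEJ
    "furcation_default_fraction": 0.72,  # H_FURC default / shorter root len
    "apex_taper": 0.015,
    # third (palatal) root placement, fractions of CEJ
    "buccal_shift_fraction": 0.16,
    "palatal_shift_fraction": 0.30,
    "palatal_furcation_lift": 0.12,   # palatal furcation above m/d one, / CEJ
})


def default_template(tooth_class: str) -> ShapeTemplate:
    """Packaged constant template for a recognised tooth class."""
    try:
        return {"incisor": _INCISOR_TEMPLATE, "molar": _MOLAR_TEMPLATE}[tooth_class]
    except KeyError:
        raise ParameterError(
            f"unknown tooth class {tooth_class!r}; expected 'incisor' or 'molar'"
        ) from None


# ---------------------------------------------------------------------------
# curve helpers
# ---------------------------------------------------------------------------

class _ParamCurve:
    """Duck-typed curve backed by an arbitrary vectorised evaluator."""

    def __init__(self, fn, closed: bool):
        self._fn = fn
        self.closed = closed

    def evaluate(self, t):
        t = np.asarray(t, dtype=float)
        scalar = t.ndim == 0
        t = np.atleast_1d(t)
        if self.closed:
            t = np.mod(t, 1.0)
        out = self._fn(t)
        return out[0] if scalar else out

    __call__ = evaluate


def _segment(curve, t0: float, t1: float) -> _ParamCurve:
    """Reparameterised sub-curve: exact restriction to [t0, t1]."""
    return _ParamCurve(lambda t: curve.evaluate(t0 + (t1 - t0) * t), closed=False)


def _pchip_curve(points: np.ndarray) -> _ParamCurve:
    """Open shape-preserving (no-overshoot) curve through ``points``."""
    from scipy.interpolate import PchipInterpolator

    points = np.asarray(points, dtype=float)
    d = np.r_[0.0, np.cumsum(np.linalg.norm(np.diff(points, axis=0), axis=1))]
    interp = PchipInterpolator(d / d[-1], points, axis=0)
    return _ParamCurve(lambda t: interp(np.clip(t, 0, 1)), closed=False)


def closed_section(width: float, depth: float, z: float,
                   squareness: float = 0.0, labial_bias: float = 0.0
                   ) -> BSplineCurve:
    """Closed cubic B-spline cross-section in the plane at height ``z``.

    Superellipse-like: ``squareness`` pushes the diagonal control points
    outward, ``labial_bias`` makes the +y (labial/buccal) side fuller.
    The curve is affinely normalised so its exact x- and y-extents equal
    ``width`` and ``depth`` and are centred on the axis.
    """
    ang = np.linspace(0, 2 * np.pi, 8, endpoint=False)
    r = 1.0 + 0.41 * squareness * (np.abs(np.sin(2 * ang)))
    x = r * np.cos(ang)
    y = r * np.sin(ang)
    y = np.where(y > 0, y * (1 + labial_bias), y)
    cp = np.c_[x, y, np.zeros(8)]
    base = BSplineCurve(cp, degree=3, closed=True)
    dense = base.evaluate(np.linspace(0, 1, 512, endpoint=False))
    x0, x1 = dense[:, 0].min(), dense[:, 0].max()
    y0, y1 = dense[:, 1].min(), dense[:, 1].max()
    sx = width / (x1 - x0)
    sy = depth / (y1 - y0)
    cp2 = np.c_[(cp[:, 0] - (x0 + x1) / 2) * sx,
                (cp[:, 1] - (y0 + y1) / 2) * sy,
                np.full(8, float(z))]
    return BSplineCurve(cp2, degree=3, closed=True)


def _circle_ring(center_xy, radius: float, z: float, nu: int) -> np.ndarray:
    ang = 2 * np.pi * np.arange(nu) / nu
    return np.c_[center_xy[0] + radius * np.cos(ang),
                 center_xy[1] + radius * np.sin(ang),
                 np.full(nu, float(z))]


def _root_surface(center_xy, top_radius: float, z_top: float,
                  half_radius: float, z_half: float, z_apex: float,
                  apex_taper: float) -> ParametricSurface:
    """Revolution surface of a monotone root profile about a vertical axis.

    v runs apex (0) to the furcation-level ring (1); the profile passes
    exactly through ``half_radius`` at ``z_half``.
    """
    from scipy.interpolate import PchipInterpolator

    zs = np.array([z_apex, z_half, z_top])
    rs = np.array([apex_taper * half_radius, half_radius, top_radius])
    rfun = PchipInterpolator(zs, rs)

    cx, cy = float(center_xy[0]), float(center_xy[1])

    def ev(u, v):
        z = z_apex + (z_top - z_apex) * v
        r = rfun(z)
        ang = 2 * np.pi * u
        return np.c_[cx + r * np.cos(ang), cy + r * np.sin(ang), z]

    return ParametricSurface("revolution", ev, closed_u=True)


def _trunk_outline(centers, radii, gap: float, z: float, sharpness: float = 2.5):
    """Smooth closed outline enclosing a set of circles with clearance ``gap``.

    Soft-max of the circles' polar support functions about the common
    axis; always lies outside the circles (soft-max >= max and the
    support function bounds the radial extent of the convex hull).
    """
    centers = np.asarray(centers, dtype=float)
    radii = np.asarray(radii, dtype=float)
    k = sharpness / max(radii.max(), 1e-9)

    def fn(t):
        theta = 2 * np.pi * t
        d = np.c_[np.cos(theta), np.sin(theta)]
        h = d @ centers.T + radii[None, :]          # support of each circle
        m = h.max(axis=1, keepdims=True)
        r = (m + np.log(np.exp(k * (h - m)).sum(axis=1, keepdims=True)) / k)[:, 0]
        r = r + gap
        return np.c_[r * d[:, 0], r * d[:, 1], np.full(len(t), float(z))]

    return _ParamCurve(fn, closed=True)


# ---------------------------------------------------------------------------
# furcation (pant-leg) junction
# ---------------------------------------------------------------------------

def _pant_junction(trunk_ring: np.ndarray, ring_a: np.ndarray,
                   ring_b: np.ndarray, saddle_index: int) -> trimesh.Trimesh:
    """Triangulate the flat region joining one trunk ring to two leg rings.

    All three rings share the count ``nu`` and the angular convention
    (index i at angle 2*pi*i/nu about each ring's own centre, CCW).  The
    split plane passes through ``saddle_index`` (and the opposite index):
    leg ``a`` owns the chain that runs from ``saddle+nu/2`` through index
    0 to ``saddle``; leg ``b`` owns the complementary chain.  The region
    is covered by two outer strips (trunk chain to leg outer half), a
    web strip between the legs' facing halves, and two saddle triangles.
    """
    nu = len(trunk_ring)
    if len(ring_a) != nu or len(ring_b) != nu or nu % 2:
        raise ParameterError("junction rings must share an even point count")
    s0 = saddle_index % nu
    s1 = (s0 + nu // 2) % nu
    chain_a = [(s1 + i) % nu for i in range(nu // 2 + 1)]   # ends at s0
    chain_b = [(s0 + i) % nu for i in range(nu // 2 + 1)]   # ends at s1

    verts = np.vstack([trunk_ring, ring_a, ring_b])
    T = np.arange(nu)
    A = nu + np.arange(nu)
    B = 2 * nu + np.arange(nu)

    faces = []

    def strip(lo, hi):
        for i, j in zip(range(len(lo) - 1), range(len(hi) - 1)):
            a0, a1 = lo[i], lo[i + 1]
            b0, b1 = hi[j], hi[j + 1]
            faces.append([a0, a1, b1])
            faces.append([a0, b1, b0])

    strip([T[i] for i in chain_a], [A[i] for i in chain_a])
    strip([T[i] for i in chain_b], [B[i] for i in chain_b])
    web_a = [A[i] for i in chain_b]
    web_b = [B[(2 * s0 - i) % nu] for i in chain_b]
    strip(web_a, web_b)
    faces.append([T[s0], A[s0], B[s0]])
    faces.append([T[s1], B[s1], A[s1]])
    return trimesh.Trimesh(vertices=verts, faces=np.asarray(faces),
                           process=False)


# ---------------------------------------------------------------------------
# tooth model container
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ToothModel:
    """A built parametric tooth: mesh + provenance."""

    mesh: trimesh.Trimesh
    params: MonoradicularParams | MultiradicularParams
    template_id: str
    axis_frame: str = "z=tooth axis (occlusal up), x=mesial, y=buccal, origin=CEJ centre"

    @property
    def tooth_class(self) -> str:
        return ("incisor" if isinstance(self.params, MonoradicularParams)
                else "molar")


def _finalize(parts, scale: float) -> trimesh.Trimesh:
    mesh = weld_meshes(parts, tol=1e-6 * max(scale, 1.0))
    if not mesh.is_watertight:
        raise RuntimeError("assembled tooth mesh is not closed")
    if mesh.volume < 0:
        mesh.invert()
    return mesh


# ---------------------------------------------------------------------------
# monoradicular builder
# ---------------------------------------------------------------------------

def build_monoradicular(params: MonoradicularParams,
                        template: ShapeTemplate | None = None,
                        resolution: int = 64) -> ToothModel:
    """Build a single-rooted (incisor-class) tooth mesh.

    Root: loft through closed B-spline sections (apex, mid-root at RAD,
    subcervical collar, cervical at CEJ) — the collar produces the
    anatomical cervical constriction that makes the CEJ identifiable as
    a local width minimum.  Crown: four Coons patches bounded by the
    equator section, two incisal-edge halves and four profile curves.
    A two-section connection loft joins the cervical section to the
    crown base (equator).
    """
    template = template or _INCISOR_TEMPLATE
    params.validate()
    tp = template
    nu = int(resolution)
    nu -= nu % 4                      # quadrant patches need nu % 4 == 0
    nu = max(nu, 32)

    root_len = params.T_H - params.C_H
    z_eq = tp["equator_height_fraction"] * params.C_H
    sq = tp["section_squareness"]
    bias = tp["labial_bias"]

    def root_sec(width, z):
        return closed_section(width, tp["root_depth_ratio"] * width, z,
                              squareness=sq, labial_bias=bias)

    cej_ring = root_sec(params.CEJ, 0.0)
    collar = root_sec(tp["collar_width_ratio"] * params.CEJ,
                      -tp["collar_depth_fraction"] * root_len)
    mid = root_sec(params.RAD, -0.5 * root_len)
    apex = root_sec(tp["apex_taper"] * params.RAD, -root_len)
    zs = np.array([-root_len, -0.5 * root_len,
                   -tp["collar_depth_fraction"] * root_len, 0.0])
    root_surface = loft_sections([apex, mid, collar, cej_ring],
                                 v_levels=(zs + root_len) / root_len)
    nv_root = max(12, nu // 2)
    root_mesh = tessellate(root_surface, nu, nv_root,
                           weld_tol=3 * tp["apex_taper"] * params.RAD)

    equator = closed_section(params.EQU, tp["crown_depth_ratio"] * params.EQU,
                             z_eq, squareness=sq, labial_bias=bias)
    conn_surface = loft_sections([cej_ring, equator], v_levels=[0.0, 1.0])
    conn_mesh = tessellate(conn_surface, nu, max(6, nu // 8))

    # incisal edge: flat at z = C_H, bowed labially, mesio-distally asymmetric
    wm = tp["tip_width_fraction_mesial"] * params.EQU / 2
    wd = tp["tip_width_fraction_distal"] * params.EQU / 2
    arch = tp["tip_arch_fraction"] * params.EQU / 2
    edge = BSplineCurve(np.array([
        [wm, 0.0, params.C_H],
        [(wm - wd) / 2, arch, params.C_H],
        [-wd, 0.0, params.C_H],
    ]), degree=2)

    bulge = tp["profile_bulge_fraction"] * params.EQU

    def profile(u_eq, t_edge, direction):
        a = equator.evaluate(u_eq)
        b = edge.evaluate(t_edge)
        mid_pt = (a + b) / 2 + np.asarray(direction) * bulge
        return BSplineCurve(np.array([a, mid_pt, b]), degree=2)

    p_mes = profile(0.0, 0.0, (0.18, 0, 0))
    p_buc = profile(0.25, 0.5, (0, 1.0, 0))
    p_dis = profile(0.5, 1.0, (-0.18, 0, 0))
    p_lin = profile(0.75, 0.5, (0, -0.55, 0))

    def arcE(u0, u1):
        return _segment(equator, u0, u1)

    patches = [
        coons_patch([arcE(0.0, 0.25), p_buc, _segment(edge, 0.0, 0.5), p_mes]),
        coons_patch([arcE(0.25, 0.5), p_dis, _segment(edge, 0.5, 1.0), p_buc]),
        coons_patch([arcE(0.5, 0.75), p_lin, _segment(edge, 1.0, 0.5), p_dis]),
        coons_patch([arcE(0.75, 1.0), p_mes, _segment(edge, 0.5, 0.0), p_lin]),
    ]
    nu_p = nu // 4 + 1
    nv_c = max(10, nu // 4)
    patch_meshes = [tessellate(p, nu_p, nv_c) for p in patches]

    mesh = _finalize([root_mesh, conn_mesh, *patch_meshes], params.T_H)
    return ToothModel(mesh, params, template.template_id)


# ---------------------------------------------------------------------------
# multiradicular builder
# ---------------------------------------------------------------------------

def _molar_layout(params: MultiradicularParams, tp: ShapeTemplate):
    """Axial/radial layout shared by builder and its validation."""
    z_apex_m = params.MC_H - params.MT_H
    z_apex_d = params.DC_H - params.DT_H
    z_apex_short = max(z_apex_m, z_apex_d)
    h_furc = (params.H_FURC if params.H_FURC is not None
              else tp["furcation_default_fraction"] * (-z_apex_short))
    z_furc = z_apex_short + h_furc

    rho_m = tp["root_flare"] * params.MRAD / 2
    rho_d = tp["root_flare"] * params.DRAD / 2
    half_w = tp["trunk_width_fraction"] * params.CEJ / 2
    gap = tp["web_gap_fraction"] * max(rho_m, rho_d)
    s = half_w - max(rho_m, rho_d) - gap
    return dict(z_apex_m=z_apex_m, z_apex_d=z_apex_d, z_furc=z_furc,
                h_furc=h_furc, rho_m=rho_m, rho_d=rho_d, s=s, gap=gap)


def build_multiradicular(params: MultiradicularParams,
                         template: ShapeTemplate | None = None,
                         resolution: int = 64) -> ToothModel:
    """Build a multi-rooted (molar-class) tooth mesh.

    Crown: loft through three closed B-spline sections (CEJ, equator,
    occlusal rim) closed by an occlusal cap ruled between the rim halves
    and an open cusp-ridge curve carrying the mesial/distal cusp
    heights.  Root trunk lofts from the CEJ down to the furcation level,
    where an explicit pant-leg junction hands over to one revolution
    surface per root.  With PRAD/PT_H a palatal root splits off first
    (maxillary configuration).
    """
    template = template or _MOLAR_TEMPLATE
    params.validate()
    tp = template
    nu = int(resolution)
    nu -= nu % 4
    nu = max(nu, 32)

    lay = _molar_layout(params, tp)
    z_furc, s = lay["z_furc"], lay["s"]
    rho_m, rho_d, gap = lay["rho_m"], lay["rho_d"], lay["gap"]
    if z_furc >= 0:
        raise ParameterError("H_FURC places the furcation above the CEJ")
    min_gap = tp["min_root_gap_fraction"] * params.CEJ
    if s - max(rho_m, rho_d) < min_gap:
        raise ParameterError(
            "MRAD/DRAD too large relative to CEJ: roots do not fit the trunk")
    for name, z_half in (("MRAD", lay["z_apex_m"] / 2),
                         ("DRAD", lay["z_apex_d"] / 2)):
        if z_half >= z_furc:
            raise ParameterError(
                f"{name} is measured at half root length, which lies above "
                "the furcation for these heights")

    sq = tp["section_squareness"]
    bias = tp["labial_bias"]
    c_ref = (params.MC_H + params.DC_H) / 2
    z_eq = tp["equator_height_fraction"] * c_ref

    three_roots = params.PRAD is not None
    y_b = tp["buccal_shift_fraction"] * params.CEJ if three_roots else 0.0

    # ---- crown -----------------------------------------------------------
    cej_ring = closed_section(params.CEJ, tp["trunk_depth_ratio"] * params.CEJ,
                              0.0, squareness=sq, labial_bias=bias)
    equator = closed_section(params.EQU, tp["crown_depth_ratio"] * params.EQU,
                             z_eq, squareness=sq, labial_bias=bias)
    dome = tp["cusp_dome_fraction"] * c_ref
    rim_flat = closed_section(tp["rim_width_fraction"] * params.EQU,
                              tp["rim_width_fraction"] * tp["crown_depth_ratio"]
                              * params.EQU, 0.0,
                              squareness=sq, labial_bias=bias)

    def rim_fn(t):
        p = rim_flat.evaluate(t).copy()
        theta = 2 * np.pi * t
        zm, zd = params.MC_H - dome, params.DC_H - dome
        p[:, 2] = (zm + zd) / 2 + (zm - zd) / 2 * np.cos(theta)
        return p

    rim = _ParamCurve(rim_fn, closed=True)
    z_rim_min = min(params.MC_H, params.DC_H) - dome
    if z_rim_min <= z_eq:
        raise ParameterError("MC_H/DC_H too small for the crown template")
    crown_surface = loft_sections(
        [cej_ring, equator, rim],
        v_levels=[0.0, z_eq / z_rim_min, 1.0])
    crown_mesh = tessellate(crown_surface, nu, max(12, nu // 3))

    # occlusal cap: two ruled patches between rim halves and the cusp ridge
    cx = tp["cusp_x_fraction"] * params.EQU
    fossa = tp["fossa_depth_fraction"] * c_ref
    r0 = rim.evaluate(0.0)
    r5 = rim.evaluate(0.5)
    ridge = _pchip_curve(np.array([
        r0,
        [cx, (r0[1] + r5[1]) / 2, params.MC_H],
        [0.0, (r0[1] + r5[1]) / 2, min(params.MC_H, params.DC_H) - fossa],
        [-cx, (r0[1] + r5[1]) / 2, params.DC_H],
        r5,
    ]))

    def ruled(bottom, top):
        def ev(u, v):
            return bottom.evaluate(u) * (1 - v)[:, None] + top.evaluate(u) * v[:, None]
        return ParametricSurface("loft", ev, closed_u=False)

    nu_c = nu // 2 + 1
    cap_front = tessellate(ruled(_segment(rim, 0.0, 0.5), ridge),
                           nu_c, max(8, nu // 6))
    cap_back = tessellate(ruled(_segment(rim, 0.5, 1.0),
                                _ParamCurve(lambda t: ridge.evaluate(1 - t),
                                            closed=False)),
                          nu_c, max(8, nu // 6))

    parts = [crown_mesh, cap_front, cap_back]

    # ---- trunk and roots -------------------------------------------------
    apex_taper = tp["apex_taper"]
    trunk_len = -z_furc

    if not three_roots:
        centers = np.array([[s, 0.0], [-s, 0.0]])
        radii = np.array([rho_m, rho_d])
        outline = _trunk_outline(centers, radii, gap, z_furc)
        collar = closed_section(tp["collar_width_ratio"] * params.CEJ,
                                tp["collar_width_ratio"] * tp["trunk_depth_ratio"]
                                * params.CEJ,
                                -tp["collar_depth_fraction"] * trunk_len,
                                squareness=sq, labial_bias=bias)
        trunk_surface = loft_sections(
            [outline, collar, cej_ring],
            v_levels=[0.0, 1 - tp["collar_depth_fraction"], 1.0])
        parts.append(tessellate(trunk_surface, nu, max(8, nu // 4)))

        u = np.arange(nu) / nu
        trunk_ring = outline.evaluate(u)
        ring_m = _circle_ring(centers[0], rho_m, z_furc, nu)
        ring_d = _circle_ring(centers[1], rho_d, z_furc, nu)
        parts.append(_pant_junction(trunk_ring, ring_m, ring_d, nu // 4))

        for center, rho, rad, z_apex in (
                (centers[0], rho_m, params.MRAD, lay["z_apex_m"]),
                (centers[1], rho_d, params.DRAD, lay["z_apex_d"])):
            surf = _root_surface(center, rho, z_furc, rad / 2, z_apex / 2,
                                 z_apex, apex_taper)
            parts.append(tessellate(surf, nu, max(12, nu // 2),
                                    weld_tol=3 * apex_taper * rad))
    else:
        rho_p = tp["root_flare"] * params.PRAD / 2
        y_p = tp["palatal_shift_fraction"] * params.CEJ
        z_apex_p = max(params.MC_H, params.DC_H) - params.PT_H
        z_furc_p = z_furc + tp["palatal_furcation_lift"] * params.CEJ
        if z_furc_p >= 0 or z_apex_p / 2 >= z_furc_p:
            raise ParameterError("PT_H incompatible with the furcation layout")

        centers_md = np.array([[s, y_b], [-s, y_b]])
        radii_md = np.array([rho_m, rho_d])
        # upper split: palatal root vs buccal (mesial+distal) lobe
        lobe_outline = _trunk_outline(centers_md, radii_md, gap, z_furc_p)
        lobe_ring_hi = lobe_outline.evaluate(np.arange(nu) / nu)
        pal_ring_hi = _circle_ring((0.0, -y_p), rho_p, z_furc_p, nu)
        outline_all = _trunk_outline(
            np.vstack([centers_md, [[0.0, -y_p]]]),
            np.r_[radii_md, rho_p], gap, z_furc_p)
        collar = closed_section(tp["collar_width_ratio"] * params.CEJ,
                                tp["collar_width_ratio"] * tp["trunk_depth_ratio"]
                                * params.CEJ,
                                -tp["collar_depth_fraction"] * (-z_furc_p),
                                squareness=sq, labial_bias=bias)
        trunk_surface = loft_sections(
            [outline_all, collar, cej_ring],
            v_levels=[0.0, 1 - tp["collar_depth_fraction"], 1.0])
        parts.append(tessellate(trunk_surface, nu, max(8, nu // 4)))
        trunk_ring = outline_all.evaluate(np.arange(nu) / nu)
        # split across y: saddles at the +/-x extremes (index 0)
        parts.append(_pant_junction(trunk_ring, pal_ring_hi, lobe_ring_hi, 0))

        # palatal root
        surf_p = _root_surface((0.0, -y_p), rho_p, z_furc_p, params.PRAD / 2,
                               z_apex_p / 2, z_apex_p, apex_taper)
        parts.append(tessellate(surf_p, nu, max(12, nu // 2),
                                weld_tol=3 * apex_taper * params.PRAD))

        # buccal lobe down to the mesio-distal furcation
        lobe_lo = _trunk_outline(centers_md, radii_md, gap, z_furc)
        lobe_surface = loft_sections([lobe_lo, lobe_outline],
                                     v_levels=[0.0, 1.0])
        parts.append(tessellate(lobe_surface, nu, max(6, nu // 8)))
        lobe_ring_lo = lobe_lo.evaluate(np.arange(nu) / nu)
        ring_m = _circle_ring(centers_md[0], rho_m, z_furc, nu)
        ring_d = _circle_ring(centers_md[1], rho_d, z_furc, nu)
        parts.append(_pant_junction(lobe_ring_lo, ring_m, ring_d, nu // 4))
        for center, rho, rad, z_apex in (
                (centers_md[0], rho_m, params.MRAD, lay["z_apex_m"]),
                (centers_md[1], rho_d, params.DRAD, lay["z_apex_d"])):
            surf = _root_surface(center, rho, z_furc, rad / 2, z_apex / 2,
                                 z_apex, apex_taper)
            parts.append(tessellate(surf, nu, max(12, nu // 2),
                                    weld_tol=3 * apex_taper * rad))

    mesh = _finalize(parts, params.MT_H)
    return ToothModel(mesh, params, template.template_id)


def build(tooth_class: str, params, template: ShapeTemplate | None = None,
          resolution: int = 64) -> ToothModel:
    """Dispatch on tooth class ('incisor' -> monoradicular, 'molar' -> multi)."""
    if tooth_class == "incisor":
        if isinstance(params, dict):
            params = MonoradicularParams(**params)
        return build_monoradicular(params, template, resolution)
    if tooth_class == "molar":
        if isinstance(params, dict):
            params = MultiradicularParams(**params)
        return build_multiradicular(params, template, resolution)
    raise ParameterError(f"unknown tooth class {tooth_class!r}")
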