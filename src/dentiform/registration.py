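"""Best-fit rigid superimposition and signed dimensional comparison.

The alignment is point-to-surface ICP: moving-mesh vertices are matched
to their nearest points on the fixed surface and the optimal rigid
motion of each correspondence set is solved in closed form (Kabsch /
SVD).  The dimensional comparison maps, per vertex of the parametric
model, the signed distance to the segmented surface: positive where the
parametric model lies outside the segmented one (excess, rendered warm
in colour exports), negative where it lies inside (lacking, cold).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh

from .spatial import MeshProximity, SignedMeshDistance


class RegistrationError(RuntimeError):
    """Degenerate geometry or undefined sign (open target mesh)."""


# ---------------------------------------------------------------------------
# rigid transforms
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion x -> R x + t (mm)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-8):
            raise RegistrationError("rotation matrix is not orthonormal")
        if np.linalg.det(R) < 0:
            raise RegistrationError("rotation has negative determinant")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def from_axis_angle(cls, axis, angle_rad: float,
                        translation=(0, 0, 0)) -> "RigidTransform":
        axis = np.asarray(axis, dtype=float)
        axis = axis / np.linalg.norm(axis)
        K = np.array([[0, -axis[2], axis[1]],
                      [axis[2], 0, -axis[0]],
                      [-axis[1], axis[0], 0]])
        R = (np.eye(3) + np.sin(angle_rad) * K
             + (1 - np.cos(angle_rad)) * (K @ K))
        return cls(R, np.asarray(translation, dtype=float))

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points) @ self.rotation.T + self.translation

    def apply_mesh(self, mesh: trimesh.Trimesh) -> trimesh.Trimesh:
        out = mesh.copy()
        out.vertices = self.apply(out.vertices)
        return out

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self o other: apply ``other`` first, then ``self``."""
        return RigidTransform(self.rotation @ other.rotation,
                              self.rotation @ other.translation
                              + self.translation)

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T,
                              -self.rotation.T @ self.translation)

    @property
    def angle(self) -> float:
        """Rotation angle in radians."""
        c = (np.trace(self.rotation) - 1) / 2
        return float(np.arccos(np.clip(c, -1, 1)))


def _kabsch(src: np.ndarray, dst: np.ndarray) -> RigidTransform:
    """Least-squares rigid motion mapping src onto dst (closed form)."""
    cs = src.mean(axis=0)
    cd = dst.mean(axis=0)
    H = (src - cs).T @ (dst - cd)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cd - R @ cs
    return RigidTransform(R, t)


# ---------------------------------------------------------------------------
# ICP best-fit alignment
# ---------------------------------------------------------------------------

@dataclass
class ICPConfig:
    max_iterations: int = 200
    tolerance: float = 1e-6           # |delta rms| stop, mm
    trim_fraction: float = 0.0        # drop worst correspondences
    sample_points: int = 1200         # moving vertices used per iteration
    principal_axes_init: bool = True
    seed: int = 0

    history: list = field(default_factory=list, repr=False)


def _principal_frame(points: np.ndarray):
    c = points.mean(axis=0)
    cov = np.cov((points - c).T)
    _, vecs = np.linalg.eigh(cov)
    axes = vecs[:, ::-1]              # descending variance
    if np.linalg.det(axes) < 0:
        axes[:, 2] *= -1
    return c, axes


def _init_candidates(moving_pts, fixed_pts):
    """Centroid + principal-axes pre-alignments (4 proper sign flips)."""
    cm, Am = _principal_frame(moving_pts)
    cf, Af = _principal_frame(fixed_pts)
    cands = []
    for sx, sy in ((1, 1), (1, -1), (-1, 1), (-1, -1)):
        S = np.diag([sx, sy, sx * sy])
        R = Af @ S @ Am.T
        cands.append(RigidTransform(R, cf - R @ cm))
    return cands


def best_fit_align(moving: trimesh.Trimesh, fixed: trimesh.Trimesh,
                   config: ICPConfig | None = None):
    """ICP superimposition of ``moving`` onto ``fixed``.

    Returns ``(RigidTransform, rms)`` where rms is the final
    point-to-surface root-mean-square distance of the sampled
    correspondences.  The per-iteration rms sequence is recorded in
    ``config.history`` and is non-increasing by construction of the
    closed-form update.
    """
    config = config or ICPConfig()
    if len(moving.vertices) == 0 or len(fixed.vertices) == 0:
        raise RegistrationError("cannot align empty meshes")
    if np.linalg.matrix_rank(
            np.cov(moving.vertices.T)) < 2:
        raise RegistrationError("moving mesh geometry is degenerate (collinear)")

    prox = MeshProximity(fixed, k=16)
    rng = np.random.default_rng(config.seed)
    pts = moving.vertices.view(np.ndarray)
    if len(pts) > config.sample_points:
        pts = pts[rng.choice(len(pts), config.sample_points, replace=False)]

    def rms_of(transform):
        _, d, _ = prox.closest(transform.apply(pts))
        return float(np.sqrt(np.mean(d ** 2)))

    if config.principal_axes_init:
        cands = _init_candidates(pts, fixed.vertices.view(np.ndarray))
        transform = min(cands, key=rms_of)
    else:
        transform = RigidTransform.identity()

    config.history.clear()
    prev = np.inf
    for _ in range(config.max_iterations):
        cur = transform.apply(pts)
        closest, d, _ = prox.closest(cur)
        if config.trim_fraction > 0:
            keep = d <= np.quantile(d, 1 - config.trim_fraction)
            src, dst, dk = cur[keep], closest[keep], d[keep]
        else:
            src, dst, dk = cur, closest, d
        rms = float(np.sqrt(np.mean(dk ** 2)))
        config.history.append(rms)
        if prev - rms < config.tolerance or rms < 1e-9:
            break
        prev = rms
        step = _kabsch(src, dst)
        transform = step.compose(transform)
    return transform, config.history[-1]


# ---------------------------------------------------------------------------
# signed deviation mapping
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DistanceMap:
    """Per-vertex signed deviation (mm) of a parametric model.

    Positive = parametric surface outside the segmented one (excess,
    warm colours); negative = inside (lacking, cold colours).
    """

    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(v)):
            raise RegistrationError("distance map contains non-finite values")
        object.__setattr__(self, "values", v)


def signed_distance_map(parametric: trimesh.Trimesh,
                        segmented: trimesh.Trimesh) -> DistanceMap:
    """Signed distance of every parametric vertex to the segmented surface.

    The meshes are assumed pre-aligned (run :func:`best_fit_align`
    first).  The segmented mesh must be closed: the sign comes from an
    inside/outside (winding-number) test against it.
    """
    if not segmented.is_watertight:
        raise RegistrationError(
            "segmented mesh is not closed; deviation sign undefined")
    sdf = SignedMeshDistance(segmented)
    return DistanceMap(sdf(parametric.vertices.view(np.ndarray)))


# ---------------------------------------------------------------------------
# region-wise deviation report
# ---------------------------------------------------------------------------

@dataclass
class RegionConfig:
    """Axial band layout for the report, in the canonical tooth frame.

    ``apex_fraction``: apical band height as a fraction of the axial
    extent; ``cej_halfwidth``: half-height (mm) of the band around the
    CEJ plane; ``cej_z``: CEJ plane height (mm), default 0 (canonical
    frame origin).
    """

    apex_fraction: float = 0.15
    cej_halfwidth: float = 1.0
    cej_z: float = 0.0


def deviation_report(dmap: DistanceMap, mesh: trimesh.Trimesh,
                     region_config: RegionConfig | None = None) -> dict:
    """Overall and per-region deviation statistics.

    Regions partition the vertices by axial band: apex band (apical
    ``apex_fraction`` of the extent), CEJ band (within
    ``cej_halfwidth`` of the CEJ plane), crown (above the CEJ band) and
    root body (the rest).  Empty regions report n=0.
    """
    cfg = region_config or RegionConfig()
    d = dmap.values
    z = mesh.vertices[:, 2]
    if len(d) != len(z):
        raise ValueError("distance map does not match mesh vertex count")
    z0, z1 = z.min(), z.max()
    apex_top = z0 + cfg.apex_fraction * (z1 - z0)
    region = np.full(len(z), "root_body", dtype=object)
    region[z <= apex_top] = "apex"
    in_cej = np.abs(z - cfg.cej_z) <= cfg.cej_halfwidth
    region[in_cej & (z > apex_top)] = "cej"
    region[(z > cfg.cej_z + cfg.cej_halfwidth)] = "crown"

    def stats(vals):
        if len(vals) == 0:
            return {"n": 0}
        return {"n": int(len(vals)),
                "max_abs": float(np.abs(vals).max()),
                "mean_abs": float(np.abs(vals).mean()),
                "max_signed": float(vals.max()),
                "min_signed": float(vals.min())}

    report = {"overall": stats(d), "regions": {}}
    for name in ("apex", "root_body", "cej", "crown"):
        report["regions"][name] = stats(d[region == name])
    counts = sum(r["n"] for r in report["regions"].values())
    assert counts == len(d)
    return report
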