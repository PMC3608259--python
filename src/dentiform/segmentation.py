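"""Iso-surface segmentation of scalar volumes and threshold calibration.

A CBCT-like scan is represented as an axis-aligned scalar volume; a
tooth surface is the iso-surface at a user threshold.  Because the
right threshold is operator-dependent, it is calibrated by
superimposition: for every candidate threshold the extracted surface is
rigidly best-fit aligned to a trusted reference surface (e.g. an
optical scan) and the threshold minimising the mean absolute
surface-to-reference distance wins.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh
from skimage import measure as _skmeasure

from .registration import ICPConfig, best_fit_align
from .spatial import MeshProximity, contains


class SegmentationError(RuntimeError):
    """Threshold outside the data range, or no extractable surface."""


@dataclass(frozen=True)
class ScalarVolume:
    """Axis-aligned 3-D scalar grid.

    ``values``: (nx, ny, nz) array; ``spacing``: mm per voxel along each
    axis; ``origin``: world position (mm) of voxel (0, 0, 0).
    """

    values: np.ndarray
    spacing: tuple = (1.0, 1.0, 1.0)
    origin: tuple = (0.0, 0.0, 0.0)

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 3 or min(v.shape) < 2:
            raise ValueError("volume must be a 3-D grid, >= 2 voxels per axis")
        sp = np.asarray(self.spacing, dtype=float)
        if sp.shape != (3,) or np.any(sp <= 0):
            raise ValueError("spacing must be 3 positive values")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "spacing", tuple(sp))
        object.__setattr__(self, "origin",
                           tuple(np.asarray(self.origin, dtype=float)))

    @classmethod
    def from_mesh_occupancy(cls, mesh: trimesh.Trimesh, spacing: float = 0.5,
                            padding: float = 2.0) -> "ScalarVolume":
        """Binary occupancy (1 inside / 0 outside) of a closed mesh.

        Inside/outside comes from the generalized winding number on the
        voxel-centre grid.
        """
        lo = mesh.vertices.min(axis=0) - padding
        hi = mesh.vertices.max(axis=0) + padding
        dims = np.maximum(np.ceil((hi - lo) / spacing).astype(int) + 1, 2)
        axes = [lo[i] + spacing * np.arange(dims[i]) for i in range(3)]
        occ = _occupancy_by_slicing(mesh, axes)
        return cls(occ, (spacing,) * 3, tuple(lo))

    def blurred(self, sigma_voxels: float = 1.0) -> "ScalarVolume":
        """Gaussian-smoothed copy (partial-volume / PSF emulation)."""
        from scipy.ndimage import gaussian_filter

        return ScalarVolume(gaussian_filter(self.values, sigma_voxels),
                            self.spacing, self.origin)


@dataclass(frozen=True)
class ThresholdCalibration:
    """Result of superimposition-based threshold search."""

    tau_star: float
    objective_curve: list          # [(tau, mean |distance| mm), ...]
    transforms: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        taus = [t for t, _ in self.objective_curve]
        objs = [o for _, o in self.objective_curve]
        if abs(objs[taus.index(self.tau_star)] - min(objs)) > 1e-12:
            raise ValueError("tau_star must attain the curve minimum")


def _occupancy_by_slicing(mesh: trimesh.Trimesh, axes) -> np.ndarray:
    """Inside/outside of every grid point by per-slice scanline parity.

    For each z level the mesh cross-section segments are cast against
    +x rays from the grid points of that slice; odd crossing counts are
    inside.  Equivalent to the winding-number test for closed meshes
    but linear in grid size.
    """
    from .metrology import _face_plane_segments

    xg, yg, zg = axes
    occ = np.zeros((len(xg), len(yg), len(zg)))
    vz = mesh.vertices[:, 2]
    tri_z = vz[mesh.faces]
    zmin, zmax = tri_z.min(axis=1), tri_z.max(axis=1)
    span = max(vz.max() - vz.min(), 1.0)
    for kz, z in enumerate(zg):
        if np.any(np.abs(vz - z) < 1e-12 * span):
            z = z + 1e-7 * span
        crossing = np.nonzero((zmin < z) & (zmax > z))[0]
        if len(crossing) == 0:
            continue
        segs = _face_plane_segments(mesh, crossing, z)
        if len(segs) == 0:
            continue
        x0, y0 = segs[:, 0, 0], segs[:, 0, 1]
        x1, y1 = segs[:, 1, 0], segs[:, 1, 1]
        for ky, y in enumerate(yg):
            straddle = (y0 <= y) != (y1 <= y)
            if not straddle.any():
                continue
            t = (y - y0[straddle]) / (y1[straddle] - y0[straddle])
            xi = x0[straddle] + t * (x1[straddle] - x0[straddle])
            counts = (xi[None, :] > xg[:, None]).sum(axis=1)
            occ[:, ky, kz] = counts % 2
    return occ


def extract_isosurface(volume: ScalarVolume, tau: float) -> trimesh.Trimesh:
    """Marching-cubes surface at iso-level ``tau``, vertices in mm.

    ``tau`` must lie strictly inside the volume's value range.
    Marching-cubes ambiguities follow scikit-image's resolution
    (Lewiner variant).
    """
    vmin, vmax = volume.values.min(), volume.values.max()
    if not vmin < tau < vmax:
        raise SegmentationError(
            f"threshold {tau} outside data range ({vmin:.4g}, {vmax:.4g})")
    verts, faces, _, _ = _skmeasure.marching_cubes(
        volume.values, level=tau, spacing=volume.spacing)
    verts = verts + np.asarray(volume.origin)
    mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=False)
    mesh.merge_vertices()
    if len(mesh.faces) == 0:
        raise SegmentationError(f"empty level set at threshold {tau}")
    if mesh.is_watertight and mesh.volume < 0:
        mesh.invert()
    return mesh


def calibrate_threshold(volume: ScalarVolume, reference: trimesh.Trimesh,
                        tau_grid, icp_config: ICPConfig | None = None,
                        sample_points: int = 1500) -> ThresholdCalibration:
    """Pick the threshold whose iso-surface best matches a reference scan.

    For each tau in ``tau_grid``: extract the iso-surface, best-fit
    align it to ``reference``, record the mean absolute distance of
    (subsampled) aligned surface vertices to the reference surface.
    tau_star is the arg-min of that curve.  Deterministic given inputs.
    """
    tau_grid = list(tau_grid)
    if len(tau_grid) == 0:
        raise ValueError("tau_grid is empty")
    prox = MeshProximity(reference)
    curve = []
    transforms = {}
    failures = []
    for tau in tau_grid:
        try:
            surf = extract_isosurface(volume, tau)
        except SegmentationError as exc:
            failures.append((tau, str(exc)))
            continue
        cfg = ICPConfig(**{**(icp_config.__dict__ if icp_config else {}),
                           "history": []}) if icp_config else ICPConfig()
        cfg.sample_points = min(cfg.sample_points, sample_points)
        transform, _ = best_fit_align(surf, reference, cfg)
        pts = surf.vertices.view(np.ndarray)
        if len(pts) > sample_points:
            rng = np.random.default_rng(cfg.seed)
            pts = pts[rng.choice(len(pts), sample_points, replace=False)]
        _, d, _ = prox.closest(transform.apply(pts))
        curve.append((float(tau), float(np.mean(d))))
        transforms[float(tau)] = transform
    if not curve:
        raise SegmentationError(
            "no threshold in the grid produced a surface: "
            + "; ".join(f"tau={t}: {m}" for t, m in failures))
    tau_star = min(curve, key=lambda c: c[1])[0]
    return ThresholdCalibration(tau_star=tau_star, objective_curve=curve,
                                transforms=transforms)
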