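"""Measurement and method-comparison statistics.

* :func:`measure_mesh` reads the named anatomical parameters back off a
  built or segmented tooth mesh (equator, CEJ, crown/tooth heights,
  root widths at half root length, furcation height).
* :func:`dahlberg_error` implements the classical repeatability error
  S_D = sqrt(sum d_i^2 / 2n) over replicate measurement pairs.
* :func:`estimate_scale` fits the multiplicative factor mapping one
  method's readings onto another's (least squares).
* :func:`compare_methods` runs the nonparametric comparison protocol:
  Shapiro-Wilk normality per method and per paired difference, Wilcoxon
  signed-rank per method pair (overall, per arch, per tooth group) and
  Kruskal-Wallis omnibus tests.

Widths follow the panoramic-projection convention: a "width" is the
mesio-distal (x) extent of a horizontal cross-section.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import trimesh
from scipy import stats
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components


class MeasurementError(RuntimeError):
    """Raised when a requested anatomical feature cannot be located."""


# ---------------------------------------------------------------------------
# records
# ---------------------------------------------------------------------------

METHODS = ("in_vivo", "PAN", "CBCT", "mesh")

CROWN_PARAMETERS = frozenset(
    {"EQU", "CEJ", "C_H", "MC_H", "DC_H"})


@dataclass
class ToothMeasures:
    """Named measurements (mm) for one tooth under one method."""

    tooth_id: str
    method: str
    values: dict[str, float] = field(default_factory=dict)

    def validate(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}")
        for key, val in self.values.items():
            if not val > 0:
                raise ValueError(f"measurement {key} must be positive")
        if self.method == "in_vivo":
            extra = set(self.values) - CROWN_PARAMETERS
            if extra:
                raise ValueError(
                    f"in_vivo records hold crown measures only, got {sorted(extra)}")


@dataclass(frozen=True)
class DahlbergResult:
    S_D: float
    n: int


@dataclass(frozen=True)
class ScaleCalibration:
    factor: float
    n_pairs: int
    residual_rms: float


# ---------------------------------------------------------------------------
# slicing machinery
# ---------------------------------------------------------------------------

def _cross_sections(mesh: trimesh.Trimesh, z: float):
    """Plane-crossing segments at height ``z`` grouped by contour.

    Returns a list of (P_i, 2, 3) arrays, one per connected contour
    (components of the face-adjacency graph restricted to crossing
    faces).  ``z`` is nudged off exact vertex heights.
    """
    vz = mesh.vertices[:, 2]
    span = vz.max() - vz.min()
    if np.any(np.abs(vz - z) < 1e-12 * max(span, 1.0)):
        z = z + 1e-9 * max(span, 1.0)
    tri_z = vz[mesh.faces]
    crossing = (tri_z.min(axis=1) < z) & (tri_z.max(axis=1) > z)
    cross_idx = np.nonzero(crossing)[0]
    if len(cross_idx) == 0:
        return []

    segs = _face_plane_segments(mesh, cross_idx, z)

    adj = mesh.face_adjacency
    keep = crossing[adj[:, 0]] & crossing[adj[:, 1]]
    sub = adj[keep]
    remap = -np.ones(len(mesh.faces), dtype=int)
    remap[cross_idx] = np.arange(len(cross_idx))
    rows, cols = remap[sub[:, 0]], remap[sub[:, 1]]
    graph = coo_matrix((np.ones(len(rows)), (rows, cols)),
                       shape=(len(cross_idx), len(cross_idx)))
    n_comp, labels = connected_components(graph, directed=False)
    return [segs[labels == c] for c in range(n_comp)]


def _face_plane_segments(mesh, face_idx, z):
    """(n, 2, 3) intersection segments of the listed faces with plane z."""
    tri = mesh.vertices[mesh.faces[face_idx]]  # (n, 3, 3)
    pts = np.full((len(face_idx), 2, 3), np.nan)
    count = np.zeros(len(face_idx), dtype=int)
    for a, b in ((0, 1), (1, 2), (2, 0)):
        za, zb = tri[:, a, 2], tri[:, b, 2]
        hit = (za - z) * (zb - z) < 0
        t = np.zeros(len(face_idx))
        t[hit] = (z - za[hit]) / (zb[hit] - za[hit])
        p = tri[:, a, :] + t[:, None] * (tri[:, b, :] - tri[:, a, :])
        sel = hit & (count < 2)
        pts[sel, count[sel]] = p[sel]
        count += hit
    ok = count == 2
    return pts[ok]


def slice_width(mesh: trimesh.Trimesh, z: float, axis: int = 0) -> float:
    """Mesio-distal extent of the full cross-section at height ``z``."""
    comps = _cross_sections(mesh, z)
    if not comps:
        return 0.0
    pts = np.concatenate([c.reshape(-1, 3) for c in comps])
    return float(pts[:, axis].max() - pts[:, axis].min())


def width_profile(mesh: trimesh.Trimesh, z_levels: np.ndarray,
                  axis: int = 0) -> np.ndarray:
    """Cross-section width at each z level (0 where the plane misses)."""
    vz = mesh.vertices[:, 2]
    tri_z = vz[mesh.faces]
    zmin, zmax = tri_z.min(axis=1), tri_z.max(axis=1)
    out = np.zeros(len(z_levels))
    for i, z in enumerate(z_levels):
        crossing = np.nonzero((zmin < z) & (zmax > z))[0]
        if len(crossing) == 0:
            continue
        segs = _face_plane_segments(mesh, crossing, z)
        if len(segs) == 0:
            continue
        x = segs[..., axis]
        out[i] = x.max() - x.min()
    return out


def _parabolic_refine(z, w, i, mode="max"):
    """Sub-grid extremum of w(z) from the 3-point parabola around index i."""
    if i <= 0 or i >= len(z) - 1:
        return z[i], w[i]
    y0, y1, y2 = w[i - 1], w[i], w[i + 1]
    denom = (y0 - 2 * y1 + y2)
    if abs(denom) < 1e-15:
        return z[i], w[i]
    delta = 0.5 * (y0 - y2) / denom
    delta = np.clip(delta, -1, 1)
    dz = z[1] - z[0]
    return z[i] + delta * dz, y1 - 0.25 * (y0 - y2) * delta


def _locate_equator_and_cej(z, w):
    """Equator = widest slice in the occlusal region; CEJ = first local
    width minimum scanning apically from the equator (the cervical
    constriction)."""
    z0, z1 = z[0], z[-1]
    extent = z1 - z0
    top = z > z1 - 0.45 * extent
    i_eq = np.nonzero(top)[0][np.argmax(w[top])]
    z_eq, w_eq = _parabolic_refine(z, w, i_eq, "max")

    # walk apically from the equator tracking the running width minimum;
    # stop once the width has risen a cumulative `bump` above it (the
    # subcervical flare), which marks the cervical constriction.
    bump = 5e-3 * w[i_eq]
    i_min = i_eq
    for i in range(i_eq - 1, -1, -1):
        if w[i] < w[i_min]:
            i_min = i
        elif w[i] > w[i_min] + bump:
            break
    z_cej, w_cej = _parabolic_refine(z, w, i_min, "min")
    return z_eq, w_eq, z_cej, w_cej


def _component_stats(comps):
    """(centroid_xy, x_extent) per contour component."""
    out = []
    for c in comps:
        pts = c.reshape(-1, 3)
        out.append((pts[:, :2].mean(axis=0),
                    pts[:, 0].max() - pts[:, 0].min()))
    return out


def _find_furcation(mesh, z_lo, z_hi, x_tol, n_probe=80):
    """Top of the z band where mesial and distal contours are separate.

    Returns (z_furc, band_found).  Separation = two contours whose
    centroids straddle x = +/- x_tol.
    """
    def separated(z):
        comps = _cross_sections(mesh, z)
        if len(comps) < 2:
            return False
        cents = [c for c, _ in _component_stats(comps)]
        return (any(c[0] > x_tol for c in cents)
                and any(c[0] < -x_tol for c in cents))

    zs = np.linspace(z_lo, z_hi, n_probe)
    flags = np.array([separated(z) for z in zs])
    if not flags.any():
        return None, False
    i_top = int(np.nonzero(flags)[0][-1])
    lo = zs[i_top]
    hi = zs[i_top + 1] if i_top + 1 < len(zs) else z_hi
    for _ in range(18):
        mid = (lo + hi) / 2
        if separated(mid):
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2, True


# ---------------------------------------------------------------------------
# mesh measurement
# ---------------------------------------------------------------------------

def measure_mesh(mesh: trimesh.Trimesh, tooth_class: str,
                 tooth_id: str = "", n_levels: int = 200) -> ToothMeasures:
    """Re-measure the named control parameters from a tooth mesh.

    The mesh must be closed and expressed in the canonical frame
    (z = tooth axis occlusal up, x = mesio-distal).  For the molar
    class, per-root quantities require a detectable furcation;
    measuring a single-rooted mesh as a molar raises
    :class:`MeasurementError`.
    """
    if tooth_class not in ("incisor", "molar"):
        raise ValueError(f"unknown tooth class {tooth_class!r}")
    vz = mesh.vertices[:, 2]
    z0, z1 = float(vz.min()), float(vz.max())
    extent = z1 - z0
    eps = 5e-3 * extent
    z = np.linspace(z0 + eps, z1 - eps, n_levels)
    w = width_profile(mesh, z)

    z_eq, w_eq, z_cej, w_cej = _locate_equator_and_cej(z, w)
    values = {"EQU": w_eq, "CEJ": w_cej}

    if tooth_class == "incisor":
        root_len = z_cej - z0
        z_half = z_cej - root_len / 2
        values["T_H"] = extent
        values["C_H"] = z1 - z_cej
        values["RAD"] = slice_width(mesh, np.clip(z_half, z0 + eps, z1 - eps))
        return ToothMeasures(tooth_id, "mesh", values)

    # ---- molar ----------------------------------------------------------
    x_tol = 0.04 * w_eq
    z_furc, found = _find_furcation(mesh, z0 + eps, z_cej - eps, x_tol)
    if not found:
        raise MeasurementError(
            "furcation not found: mesh has no separated mesial/distal roots")

    below = mesh.vertices[vz < z_furc]
    comps = _cross_sections(mesh, z_furc - 0.25 * (z_furc - z0))
    cents = np.array([c for c, _ in _component_stats(comps)])
    labels = np.argmin(
        np.linalg.norm(below[:, None, :2] - cents[None], axis=2), axis=1)
    i_mes = int(np.argmax(cents[:, 0]))
    i_dis = int(np.argmin(cents[:, 0]))
    apex = {i: float(below[labels == i, 2].min())
            for i in range(len(cents)) if (labels == i).any()}

    crown = mesh.vertices[vz > z_cej]
    cusp_m = float(crown[crown[:, 0] > 0, 2].max())
    cusp_d = float(crown[crown[:, 0] < 0, 2].max())
    values["MC_H"] = cusp_m - z_cej
    values["DC_H"] = cusp_d - z_cej
    values["MT_H"] = cusp_m - apex[i_mes]
    values["DT_H"] = cusp_d - apex[i_dis]
    values["H_FURC"] = z_furc - max(apex[i_mes], apex[i_dis])

    def root_width(i_comp):
        z_half = (z_cej + apex[i_comp]) / 2
        comps_h = _cross_sections(mesh, z_half)
        stats_h = _component_stats(comps_h)
        if not stats_h:
            return np.nan
        j = int(np.argmin([np.linalg.norm(c - cents[i_comp])
                           for c, _ in stats_h]))
        return stats_h[j][1]

    values["MRAD"] = root_width(i_mes)
    values["DRAD"] = root_width(i_dis)

    if len(cents) >= 3:
        i_pal = int(np.argmin(cents[:, 1]))
        if i_pal not in (i_mes, i_dis):
            values["PRAD"] = root_width(i_pal)
            values["PT_H"] = float(vz.max()) - apex[i_pal]
    return ToothMeasures(tooth_id, "mesh", values)


# ---------------------------------------------------------------------------
# Dahlberg repeatability error
# ---------------------------------------------------------------------------

def dahlberg_error(pairs: Sequence) -> DahlbergResult:
    """Repeatability error S_D = sqrt(sum(d_i^2) / (2 n)).

    ``pairs`` holds replicate measurement pairs (x1_i, x2_i); d_i is
    their difference.  S_D estimates the standard deviation of a single
    measurement's error, assuming independent replicates.
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.size == 0:
        raise ValueError("dahlberg_error needs at least one replicate pair")
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("pairs must be an (n, 2) array of replicates")
    d = arr[:, 0] - arr[:, 1]
    n = len(d)
    return DahlbergResult(S_D=float(np.sqrt(np.sum(d ** 2) / (2 * n))), n=n)


# ---------------------------------------------------------------------------
# scale calibration
# ---------------------------------------------------------------------------

def estimate_scale(reference: Sequence[float],
                   target: Sequence[float]) -> ScaleCalibration:
    """Least-squares multiplicative factor mapping target onto reference.

    Minimises sum (reference_i - factor * target_i)^2, i.e.
    factor = <r, t> / <t, t>.  Used to bring one method's units (e.g.
    CBCT voxel-derived values) onto another's millimetres.
    """
    r = np.asarray(reference, dtype=float)
    t = np.asarray(target, dtype=float)
    if r.shape != t.shape or r.ndim != 1:
        raise ValueError("reference and target must be equal-length 1-D")
    if len(r) < 2:
        raise ValueError("need at least 2 pairs to estimate a scale")
    if np.any(r <= 0) or np.any(t <= 0):
        raise ValueError("scale estimation requires positive measurements")
    factor = float(np.dot(r, t) / np.dot(t, t))
    resid = r - factor * t
    return ScaleCalibration(factor=factor, n_pairs=len(r),
                            residual_rms=float(np.sqrt(np.mean(resid ** 2))))


# ---------------------------------------------------------------------------
# method-comparison protocol
# ---------------------------------------------------------------------------

_ARCH = {"1": "upper", "2": "upper", "3": "lower", "4": "lower"}
_GROUP = {"1": "incisor", "2": "incisor", "3": "canine",
          "4": "premolar", "5": "premolar", "6": "molar", "7": "molar",
          "8": "molar"}


def tooth_arch(tooth_id: str) -> str:
    """Dental arch from FDI notation ('2.1' -> upper)."""
    return _ARCH.get(str(tooth_id).strip()[0], "unknown")


def tooth_group(tooth_id: str) -> str:
    """Tooth group (incisor/canine/premolar/molar) from FDI notation."""
    digits = [c for c in str(tooth_id) if c.isdigit()]
    return _GROUP.get(digits[1], "unknown") if len(digits) >= 2 else "unknown"


def _wilcoxon_entry(x, y):
    d = np.asarray(x, dtype=float) - np.asarray(y, dtype=float)
    n = len(d)
    if n < 2:
        return {"flag": "insufficient data", "n": n}
    if np.allclose(d, 0):
        return {"statistic": 0.0, "p_value": 1.0, "n": n, "flag": "degenerate"}
    res = stats.wilcoxon(d)
    return {"statistic": float(res.statistic), "p_value": float(res.pvalue),
            "n": n}


def _shapiro_entry(x):
    x = np.asarray(x, dtype=float)
    if len(x) < 3 or np.ptp(x) == 0:
        return {"flag": "insufficient data", "n": len(x)}
    res = stats.shapiro(x)
    return {"statistic": float(res.statistic), "p_value": float(res.pvalue),
            "n": len(x)}


def _kruskal_entry(groups):
    groups = [np.asarray(g, dtype=float) for g in groups if len(g) > 0]
    if len(groups) < 2 or sum(len(g) for g in groups) < 3:
        return {"flag": "insufficient data",
                "n": int(sum(len(g) for g in groups))}
    if all(np.ptp(np.concatenate(groups)) == 0 for _ in [0]):
        return {"statistic": 0.0, "p_value": 1.0,
                "n": int(sum(len(g) for g in groups)), "flag": "degenerate"}
    res = stats.kruskal(*groups)
    return {"statistic": float(res.statistic), "p_value": float(res.pvalue),
            "n": int(sum(len(g) for g in groups))}


def compare_methods(table: pd.DataFrame,
                    methods: Sequence[str] | None = None) -> dict:
    """Run the nonparametric method-comparison protocol on a long table.

    ``table`` columns: tooth_id, method, parameter, value_mm (replicates,
    if present, are averaged first).  Produces a nested report:
    normality per method and per paired difference; Wilcoxon signed-rank
    per method pair overall / per arch / per tooth group; Kruskal-Wallis
    across methods and across tooth groups.  Raw p-values only, no
    multiple-testing correction, mirroring the protocol's structure.
    """
    df = (table.groupby(["tooth_id", "method", "parameter"], as_index=False)
          ["value_mm"].mean())
    methods = list(methods) if methods else sorted(df["method"].unique())
    if len(methods) < 2:
        raise ValueError("compare_methods needs at least two methods")
    wide = df.pivot_table(index=["tooth_id", "parameter"], columns="method",
                          values="value_mm")

    report: dict = {"methods": methods, "normality": {}, "wilcoxon": {},
                    "kruskal_wallis": {}}
    for m in methods:
        if m in wide:
            report["normality"][m] = _shapiro_entry(wide[m].dropna())

    pairs = [(a, b) for i, a in enumerate(methods) for b in methods[i + 1:]]
    ids = wide.index.get_level_values("tooth_id")
    arches = np.array([tooth_arch(t) for t in ids])
    groups = np.array([tooth_group(t) for t in ids])

    for a, b in pairs:
        key = f"{a}_vs_{b}"
        if a not in wide or b not in wide:
            report["wilcoxon"][key] = {"flag": "insufficient data", "n": 0}
            continue
        paired = wide[[a, b]].dropna()
        mask_all = wide[[a, b]].notna().all(axis=1).to_numpy()
        report["normality"][f"diff_{key}"] = _shapiro_entry(
            paired[a] - paired[b])
        entry = {"overall": _wilcoxon_entry(paired[a], paired[b]),
                 "by_arch": {}, "by_tooth_group": {}}
        for arch in sorted(set(arches[mask_all])):
            sel = paired[(arches[mask_all] == arch)]
            entry["by_arch"][arch] = _wilcoxon_entry(sel[a], sel[b])
        for grp in sorted(set(groups[mask_all])):
            sel = paired[(groups[mask_all] == grp)]
            entry["by_tooth_group"][grp] = _wilcoxon_entry(sel[a], sel[b])
        report["wilcoxon"][key] = entry

    report["kruskal_wallis"]["across_methods"] = _kruskal_entry(
        [wide[m].dropna() for m in methods if m in wide])
    a, b = pairs[0]
    if a in wide and b in wide:
        paired = wide[[a, b]].dropna()
        mask_all = wide[[a, b]].notna().all(axis=1).to_numpy()
        diffs = (paired[a] - paired[b]).to_numpy()
        glabels = groups[mask_all]
        report["kruskal_wallis"]["across_tooth_groups"] = _kruskal_entry(
            [diffs[glabels == g] for g in sorted(set(glabels))])
    return report
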