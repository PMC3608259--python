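"""Synthetic validation scenario generator.

Emulates, at measurement level, the data a single-patient imaging study
would provide: ground-truth parametric tooth meshes, perturbed
"CBCT-segmented" counterparts, blurred occupancy volumes, and
multi-method measurement tables (in-vivo calliper, panoramic radiograph
with vertical magnification, CBCT in scanner units) with replicate
readings for repeatability analysis.

All randomness flows from a single seed through named substreams, so
regeneration is bit-identical and each component is independently
reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
import trimesh

from .metrology import CROWN_PARAMETERS
from .segmentation import ScalarVolume
from .tooth_builder import (
    MonoradicularParams,
    MultiradicularParams,
    ToothModel,
    build,
)

HEIGHT_PARAMETERS = frozenset(
    {"T_H", "C_H", "MC_H", "DC_H", "MT_H", "DT_H", "PT_H", "H_FURC"})


@dataclass(frozen=True)
class NoiseModel:
    """Method-specific error model for the simulated measurements.

    ``landmark_sd``: per-reading Gaussian noise (mm), the digitisation /
    calliper repeatability floor.  ``pan_height_magnification`` /
    ``pan_width_magnification``: multiplicative projection distortion of
    the panoramic radiograph (vertical magnification dominates, so the
    height factor is larger).  ``cbct_scale``: factor from mm to the
    raw CBCT unit in which that method's values are recorded.
    ``mesh_perturbation_amplitude`` / ``..._wavelength``: RMS amplitude
    and spatial scale (mm) of the smooth displacement field applied to
    ground-truth meshes to emulate segmentation error.
    """

    landmark_sd: float = 0.15
    pan_height_magnification: float = 1.15
    pan_width_magnification: float = 1.05
    cbct_scale: float = 1.0 / 0.313854
    mesh_perturbation_amplitude: float = 0.3
    mesh_perturbation_wavelength: float = 6.0
    voxel_spacing: float = 0.5
    blur_sigma_voxels: float = 1.0

    def validate(self) -> None:
        if self.landmark_sd < 0:
            raise ValueError("landmark_sd must be >= 0")
        for name in ("pan_height_magnification", "pan_width_magnification",
                     "cbct_scale"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if self.mesh_perturbation_amplitude < 0:
            raise ValueError("mesh_perturbation_amplitude must be >= 0")
        if not self.mesh_perturbation_wavelength > 0:
            raise ValueError("mesh_perturbation_wavelength must be positive")


#: plausible adult tooth dimensions (mm) per FDI tooth, used by the
#: default full-arch roster.  Crown-only methods read the crown subset.
_INCISOR_BASE = dict(T_H=23.0, C_H=10.5, CEJ=6.3, EQU=8.5, RAD=4.2)
_MOLAR_BASE = dict(EQU=11.0, CEJ=9.0, MC_H=7.5, DC_H=7.0, MT_H=21.0,
                   DT_H=20.0, MRAD=3.4, DRAD=3.15, H_FURC=9.5)


@dataclass(frozen=True)
class RosterEntry:
    tooth_id: str
    tooth_class: str
    params: MonoradicularParams | MultiradicularParams


def default_roster() -> list[RosterEntry]:
    """The two validated teeth: 2.1 (incisor) and 3.6 (molar), FDI."""
    return [
        RosterEntry("2.1", "incisor", MonoradicularParams(**_INCISOR_BASE)),
        RosterEntry("3.6", "molar", MultiradicularParams(**_MOLAR_BASE)),
    ]


def full_arch_roster(seed: int = 0,
                     quadrants=(1, 2, 3, 4),
                     positions=(1, 2, 3, 4, 5, 6, 7)) -> list[RosterEntry]:
    """Configurable synthetic arch for the statistics protocol.

    One tooth per (quadrant, position) with unique FDI ids and mild
    anatomical size variation.  Positions 1-5 (incisors through
    premolars) use the single-rooted builder; 6-7 the molar builder.
    Parameter draws respect the builder invariants with margin.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 11]))
    roster = []
    for q in quadrants:
        for pos in positions:
            tooth_id = f"{q}.{pos}"
            if pos <= 5:
                size = {1: 1.0, 2: 0.88, 3: 1.05, 4: 0.92, 5: 0.9}[pos]
                roster.append(RosterEntry(
                    tooth_id, "incisor",
                    random_incisor_params(rng,
                                          scale=size * rng.uniform(0.95, 1.05))))
            else:
                size = 1.0 if pos == 6 else 0.95
                roster.append(RosterEntry(
                    tooth_id, "molar",
                    random_molar_params(rng,
                                        scale=size * rng.uniform(0.95, 1.05))))
    return roster


def random_incisor_params(rng: np.random.Generator,
                          scale: float = 1.0) -> MonoradicularParams:
    """Anatomically plausible random single-rooted parameter set."""
    T_H = rng.uniform(20.0, 26.0) * scale
    C_H = T_H * rng.uniform(0.38, 0.48)
    EQU = rng.uniform(7.0, 9.5) * scale
    CEJ = EQU * rng.uniform(0.68, 0.82)
    RAD = CEJ * rng.uniform(0.55, 0.85)
    return MonoradicularParams(T_H=T_H, C_H=C_H, CEJ=CEJ, EQU=EQU, RAD=RAD)


def random_molar_params(rng: np.random.Generator,
                        scale: float = 1.0) -> MultiradicularParams:
    """Anatomically plausible random two-rooted parameter set."""
    MT_H = rng.uniform(19.0, 23.0) * scale
    MC_H = MT_H * rng.uniform(0.33, 0.40)
    DT_H = MT_H * rng.uniform(0.93, 1.0)
    DC_H = MC_H * rng.uniform(0.90, 1.0)
    EQU = rng.uniform(10.0, 12.0) * scale
    CEJ = EQU * rng.uniform(0.78, 0.86)
    MRAD = CEJ * rng.uniform(0.30, 0.38)
    DRAD = MRAD * rng.uniform(0.85, 1.0)
    shorter = min(MT_H - MC_H, DT_H - DC_H)
    H_FURC = shorter * rng.uniform(0.65, 0.8)
    return MultiradicularParams(EQU=EQU, CEJ=CEJ, MC_H=MC_H, DC_H=DC_H,
                                MT_H=MT_H, DT_H=DT_H, MRAD=MRAD, DRAD=DRAD,
                                H_FURC=H_FURC)


# ---------------------------------------------------------------------------
# mesh perturbation
# ---------------------------------------------------------------------------

def perturb_mesh(mesh: trimesh.Trimesh, amplitude: float, wavelength: float,
                 seed: int = 0, n_harmonics: int = 24) -> trimesh.Trimesh:
    """Displace vertices along a smooth pseudo-random vector field.

    The field is a fixed-count sum of spatial harmonics with seeded
    random wave vectors (magnitude ~ 2*pi/wavelength), directions and
    phases, rescaled so the RMS vertex displacement equals ``amplitude``
    exactly.  Topology is untouched, so closedness is preserved;
    at the default amplitude/wavelength (a few tenths of a mm over
    several mm) the mapping is far below the self-intersection regime.
    """
    if amplitude < 0:
        raise ValueError("amplitude must be >= 0")
    if wavelength <= 0:
        raise ValueError("wavelength must be positive")
    out = mesh.copy()
    if amplitude == 0:
        return out
    rng = np.random.default_rng(np.random.SeedSequence([seed, 101]))
    v = out.vertices.view(np.ndarray)
    disp = np.zeros_like(v)
    for _ in range(n_harmonics):
        k_dir = rng.normal(size=3)
        k_dir /= np.linalg.norm(k_dir)
        k = 2 * np.pi / (wavelength * rng.uniform(0.7, 1.4)) * k_dir
        phase = rng.uniform(0, 2 * np.pi)
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        disp += np.outer(np.sin(v @ k + phase), direction)
    rms = np.sqrt(np.mean(np.sum(disp ** 2, axis=1)))
    out.vertices = v + disp * (amplitude / rms)
    return out


# ---------------------------------------------------------------------------
# measurement tables
# ---------------------------------------------------------------------------

def _true_values(entry: RosterEntry) -> dict[str, float]:
    vals = {k: v for k, v in vars(entry.params).items()
            if isinstance(v, (int, float)) and v is not None}
    return vals


def _method_transform(values: dict, method: str, noise: NoiseModel) -> dict:
    if method == "CBCT":
        return {k: v * noise.cbct_scale for k, v in values.items()}
    if method == "PAN":
        return {k: v * (noise.pan_height_magnification
                        if k in HEIGHT_PARAMETERS
                        else noise.pan_width_magnification)
                for k, v in values.items()}
    if method == "in_vivo":
        return {k: v for k, v in values.items() if k in CROWN_PARAMETERS}
    raise ValueError(f"unknown method {method!r}")


def make_measurement_table(roster: Sequence[RosterEntry], method: str,
                           noise: NoiseModel, replicates: int = 1,
                           seed: int = 0) -> pd.DataFrame:
    """Simulated long-format measurement table for one method.

    Columns: tooth_id, method, parameter, replicate, value_mm (PAN and
    CBCT values are in their native distorted/scaled units; the column
    name keeps the table schema uniform).  Each replicate re-draws the
    landmark noise, which is what the repeatability (Dahlberg) analysis
    consumes.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    noise.validate()
    streams = {"in_vivo": 1, "PAN": 2, "CBCT": 3}
    if method not in streams:
        raise ValueError(f"unknown method {method!r}")
    rng = np.random.default_rng(np.random.SeedSequence([seed, streams[method]]))
    rows = []
    for entry in roster:
        base = _method_transform(_true_values(entry), method, noise)
        for rep in range(1, replicates + 1):
            for param, val in base.items():
                noisy = val + rng.normal(0.0, noise.landmark_sd)
                rows.append((entry.tooth_id, method, param, rep,
                             max(noisy, 1e-3)))
    return pd.DataFrame(
        rows, columns=["tooth_id", "method", "parameter", "replicate",
                       "value_mm"])


# ---------------------------------------------------------------------------
# full patient scenario
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SyntheticTooth:
    tooth_id: str
    tooth_class: str
    ground_truth: ToothModel
    segmented: trimesh.Trimesh
    volume: ScalarVolume | None


@dataclass(frozen=True)
class SyntheticPatient:
    seed: int
    noise: NoiseModel
    teeth: list[SyntheticTooth]
    tables: pd.DataFrame        # long table across methods, with replicates

    def table_for(self, method: str) -> pd.DataFrame:
        return self.tables[self.tables["method"] == method].reset_index(drop=True)


def generate_patient(seed: int = 0, noise: NoiseModel | None = None,
                     roster: Sequence[RosterEntry] | None = None,
                     replicates: int = 2, resolution: int = 64,
                     with_volumes: bool = False,
                     table_roster: Sequence[RosterEntry] | None = None
                     ) -> SyntheticPatient:
    """Generate the full synthetic study scenario.

    Per roster tooth: ground-truth mesh built from the true parameters;
    a "segmented" mesh = ground truth warped by the smooth displacement
    field plus nothing else (vertex-level jitter is part of the field's
    highest harmonic); optionally a blurred occupancy volume of the
    segmented mesh.  Measurement tables cover in_vivo (crown only), PAN
    (magnified) and CBCT (scaled), each with ``replicates`` readings.
    Fully deterministic given (seed, config).
    """
    noise = noise or NoiseModel()
    noise.validate()
    roster = list(roster) if roster is not None else default_roster()
    for entry in roster:
        try:
            entry.params.validate()
        except Exception as exc:
            raise ValueError(f"invalid roster entry {entry.tooth_id}: {exc}")

    teeth = []
    for i, entry in enumerate(roster):
        model = build(entry.tooth_class, entry.params, resolution=resolution)
        seg = perturb_mesh(model.mesh, noise.mesh_perturbation_amplitude,
                           noise.mesh_perturbation_wavelength,
                           seed=int(np.random.SeedSequence(
                               [seed, 7, i]).generate_state(1)[0] % 2**31))
        vol = None
        if with_volumes:
            vol = ScalarVolume.from_mesh_occupancy(
                seg, spacing=noise.voxel_spacing).blurred(
                    noise.blur_sigma_voxels)
        teeth.append(SyntheticTooth(entry.tooth_id, entry.tooth_class,
                                    model, seg, vol))

    t_roster = list(table_roster) if table_roster is not None else roster
    tables = pd.concat(
        [make_measurement_table(t_roster, m, noise, replicates, seed)
         for m in ("in_vivo", "PAN", "CBCT")], ignore_index=True)
    return SyntheticPatient(seed=seed, noise=noise, teeth=teeth,
                            tables=tables)
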