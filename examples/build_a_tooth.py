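"""Build parametric teeth from radiograph-style measurements.

Constructs a maxillary-incisor-class and a mandibular-molar-class tooth
from a handful of named millimetre parameters, then re-measures the
meshes to show that the geometry honours its inputs.
"""

from dentiform import build, measure_mesh

incisor = build("incisor", dict(T_H=23.0, C_H=10.5, CEJ=6.3, EQU=8.5,
                                RAD=4.2))
molar = build("molar", dict(EQU=11.0, CEJ=9.0, MC_H=7.5, DC_H=7.0,
                            MT_H=21.0, DT_H=20.0, MRAD=3.5, DRAD=3.2,
                            H_FURC=11.0))

for model in (incisor, molar):
    mesh = model.mesh
    print(f"\n{model.tooth_class}: {len(mesh.vertices)} vertices, "
          f"watertight={mesh.is_watertight}, volume={mesh.volume:.1f} mm^3")
    measured = measure_mesh(mesh, model.tooth_class)
    print("  input -> re-measured (mm):")
    for name, value in measured.values.items():
        truth = getattr(model.params, name)
        print(f"    {name:7s} {truth:7.2f} -> {value:7.2f}")

# Each re-measured value should match its input within ~0.1 mm: the
# mesh really is controlled by the radiograph parameters, with the
# remaining shape fixed by the class template.
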