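import numpy as np
import pytest
import trimesh

from dentiform.tooth_builder import (
    MonoradicularParams,
    MultiradicularParams,
    build_monoradicular,
    build_multiradicular,
)

INCISOR_PARAMS = MonoradicularParams(T_H=23.0, C_H=10.5, CEJ=6.3, EQU=8.5,
                                     RAD=4.2)
MOLAR_PARAMS = MultiradicularParams(EQU=11.0, CEJ=9.0, MC_H=7.5, DC_H=7.0,
                                    MT_H=21.0, DT_H=20.0, MRAD=3.5, DRAD=3.2,
                                    H_FURC=11.0)


@pytest.fixture(scope="session")
def incisor_model():
    return build_monoradicular(INCISOR_PARAMS)


@pytest.fixture(scope="session")
def incisor_mesh(incisor_model):
    return incisor_model.mesh


@pytest.fixture(scope="session")
def molar_model():
    return build_multiradicular(MOLAR_PARAMS)


@pytest.fixture(scope="session")
def molar_mesh(molar_model):
    return molar_model.mesh


@pytest.fixture(scope="session")
def sphere_pair():
    """Concentric tessellated spheres of radius 8.5 and 8.0 mm."""
    return (trimesh.creation.icosphere(subdivisions=4, radius=8.5),
            trimesh.creation.icosphere(subdivisions=4, radius=8.0))


def circle_section(radius: float, z: float, n: int = 8):
    """Closed cubic B-spline whose true radius equals ``radius`` exactly."""
    from dentiform.geometry import BSplineCurve

    ang = np.linspace(0, 2 * np.pi, n, endpoint=False)
    unit = BSplineCurve(np.c_[np.cos(ang), np.sin(ang), np.zeros(n)],
                        degree=3, closed=True)
    dense = unit.evaluate(np.linspace(0, 1, 1024, endpoint=False))
    r_actual = np.linalg.norm(dense[:, :2], axis=1).mean()
    scale = radius / r_actual
    return BSplineCurve(np.c_[np.cos(ang) * scale, np.sin(ang) * scale,
                              np.full(n, float(z))], degree=3, closed=True)
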