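"""Parametric tooth assembly: watertightness, parameter faithfulness,
invariant enforcement, scale equivariance."""

import numpy as np
import pytest

from dentiform.metrology import measure_mesh
from dentiform.tooth_builder import (
    MonoradicularParams,
    MultiradicularParams,
    ParameterError,
    ShapeTemplate,
    build,
    build_monoradicular,
    build_multiradicular,
    default_template,
)
from conftest import INCISOR_PARAMS, MOLAR_PARAMS


def _tolerance(value):
    return max(0.02 * value, 0.1)


class TestTemplates:
    @pytest.mark.parametrize("tooth_class", ["incisor", "molar"])
    def test_default_templates_have_valid_ratios(self, tooth_class):
        tpl = default_template(tooth_class)
        assert all(0 < v <= 2 for v in tpl.ratios.values())

    def test_molar_furcation_default_fraction_in_unit_interval(self):
        assert 0 < default_template("molar")["furcation_default_fraction"] < 1

    def test_unknown_class_rejected(self):
        with pytest.raises(ParameterError):
            default_template("premolar")

    def test_out_of_range_ratio_rejected(self):
        with pytest.raises(ParameterError):
            ShapeTemplate("bad", {"some_ratio": 2.5})


class TestMonoradicular:
    def test_mesh_is_closed(self, incisor_mesh):
        assert incisor_mesh.is_watertight
        assert incisor_mesh.volume > 0

    def test_axial_height_matches_T_H(self, incisor_mesh):
        z = incisor_mesh.vertices[:, 2]
        assert z.max() - z.min() == pytest.approx(INCISOR_PARAMS.T_H, abs=0.1)

    def test_crown_max_width_matches_EQU(self, incisor_model):
        m = measure_mesh(incisor_model.mesh, "incisor")
        assert m.values["EQU"] == pytest.approx(INCISOR_PARAMS.EQU, abs=0.1)

    def test_all_parameters_recovered(self, incisor_model):
        m = measure_mesh(incisor_model.mesh, "incisor")
        for name in ("T_H", "C_H", "CEJ", "EQU", "RAD"):
            truth = getattr(INCISOR_PARAMS, name)
            assert m.values[name] == pytest.approx(
                truth, abs=_tolerance(truth)), name

    def test_crown_height_equal_to_total_rejected(self):
        with pytest.raises(ParameterError, match="C_H"):
            build_monoradicular(MonoradicularParams(
                T_H=23.0, C_H=23.0, CEJ=6.3, EQU=8.5, RAD=4.2))

    def test_rad_above_cej_rejected(self):
        with pytest.raises(ParameterError, match="RAD"):
            MonoradicularParams(T_H=23, C_H=10, CEJ=6.0, EQU=8.5,
                                RAD=6.5).validate()

    def test_equator_monotone_in_EQU(self):
        widths = []
        for equ in (7.5, 8.5, 9.5):
            p = MonoradicularParams(T_H=23.0, C_H=10.5, CEJ=6.3, EQU=equ,
                                    RAD=4.2)
            mesh = build_monoradicular(p).mesh
            widths.append(np.ptp(mesh.vertices[:, 0]))
        assert widths[0] < widths[1] < widths[2]

    def test_extent_monotone_in_T_H(self):
        extents = []
        for th in (21.0, 23.0, 25.0):
            p = MonoradicularParams(T_H=th, C_H=10.5, CEJ=6.3, EQU=8.5,
                                    RAD=4.2)
            mesh = build_monoradicular(p).mesh
            extents.append(np.ptp(mesh.vertices[:, 2]))
        assert extents[0] < extents[1] < extents[2]

    def test_scale_equivariance(self, incisor_mesh):
        s = 1.37
        scaled = MonoradicularParams(
            **{k: s * v for k, v in vars(INCISOR_PARAMS).items()})
        mesh_s = build_monoradicular(scaled).mesh
        assert np.allclose(mesh_s.vertices, s * incisor_mesh.vertices,
                           atol=1e-8)


class TestMultiradicular:
    def test_mesh_is_closed(self, molar_mesh):
        assert molar_mesh.is_watertight
        assert molar_mesh.volume > 0

    def test_mesial_axial_extent(self, molar_model):
        m = measure_mesh(molar_model.mesh, "molar")
        assert m.values["MT_H"] == pytest.approx(MOLAR_PARAMS.MT_H, abs=0.15)

    def test_two_contours_below_furcation(self, molar_mesh):
        # built furcation: z = (DC_H - DT_H) + H_FURC = -2; probe 2 mm below
        sec = molar_mesh.section(plane_origin=[0, 0, -4],
                                 plane_normal=[0, 0, 1])
        assert len(sec.discrete) == 2

    def test_mesial_root_width_at_half_length(self, molar_model):
        m = measure_mesh(molar_model.mesh, "molar")
        assert m.values["MRAD"] == pytest.approx(MOLAR_PARAMS.MRAD, abs=0.1)

    def test_all_parameters_recovered(self, molar_model):
        m = measure_mesh(molar_model.mesh, "molar")
        for name in ("EQU", "CEJ", "MC_H", "DC_H", "MT_H", "DT_H",
                     "MRAD", "DRAD", "H_FURC"):
            truth = getattr(MOLAR_PARAMS, name)
            assert m.values[name] == pytest.approx(
                truth, abs=max(_tolerance(truth), 0.15)), name

    def test_furcation_above_cej_rejected(self):
        with pytest.raises(ParameterError, match="H_FURC"):
            MultiradicularParams(EQU=11, CEJ=9, MC_H=7.5, DC_H=7.0,
                                 MT_H=21, DT_H=20, MRAD=3.5, DRAD=3.2,
                                 H_FURC=14.0).validate()

    def test_palatal_width_without_height_rejected(self):
        with pytest.raises(ParameterError, match="PRAD"):
            MultiradicularParams(EQU=11, CEJ=9, MC_H=7.5, DC_H=7.0,
                                 MT_H=21, DT_H=20, MRAD=3.5, DRAD=3.2,
                                 PRAD=3.0).validate()

    def test_three_rooted_build(self):
        p = MultiradicularParams(EQU=10.5, CEJ=8.5, MC_H=7.0, DC_H=6.6,
                                 MT_H=20.0, DT_H=19.5, MRAD=3.0, DRAD=2.8,
                                 PRAD=3.0, PT_H=20.5)
        model = build_multiradicular(p)
        assert model.mesh.is_watertight
        sec = model.mesh.section(plane_origin=[0, 0, -9],
                                 plane_normal=[0, 0, 1])
        assert len(sec.discrete) == 3
        m = measure_mesh(model.mesh, "molar")
        assert m.values["PRAD"] == pytest.approx(3.0, abs=0.15)
        assert m.values["PT_H"] == pytest.approx(20.5, abs=0.2)

    def test_oversized_roots_rejected(self):
        with pytest.raises(ParameterError, match="roots do not fit"):
            build_multiradicular(MultiradicularParams(
                EQU=11, CEJ=8.0, MC_H=7.5, DC_H=7.0, MT_H=21, DT_H=20,
                MRAD=4.5, DRAD=4.5, H_FURC=11.0))


class TestDispatch:
    def test_build_accepts_dict_params(self):
        model = build("incisor", dict(T_H=22.0, C_H=10.0, CEJ=6.0, EQU=8.0,
                                      RAD=4.0), resolution=48)
        assert model.tooth_class == "incisor"
        assert model.mesh.is_watertight

    def test_unknown_class_rejected(self):
        with pytest.raises(ParameterError):
            build("premolar", dict())
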