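"""Measurement, Dahlberg repeatability, scale fitting and the
nonparametric comparison protocol."""

import numpy as np
import pandas as pd
import pytest
import trimesh
from hypothesis import given, settings, strategies as st

from dentiform.metrology import (
    MeasurementError,
    compare_methods,
    dahlberg_error,
    estimate_scale,
    measure_mesh,
    tooth_arch,
    tooth_group,
)


class TestMeasureMesh:
    def test_constant_cross_section_cylinder(self):
        cyl = trimesh.creation.cylinder(radius=3.0, height=20.0, sections=128)
        cyl.apply_translation([0, 0, 10.0])
        m = measure_mesh(cyl, "incisor")
        for name in ("EQU", "CEJ", "RAD"):
            assert m.values[name] == pytest.approx(6.0, abs=0.05)

    def test_molar_measurement_requires_furcation(self, incisor_mesh):
        with pytest.raises(MeasurementError, match="furcation"):
            measure_mesh(incisor_mesh, "molar")

    def test_unknown_class_rejected(self, incisor_mesh):
        with pytest.raises(ValueError):
            measure_mesh(incisor_mesh, "canine")

    def test_furcation_to_apex_distance_recovered(self, molar_model):
        m = measure_mesh(molar_model.mesh, "molar")
        assert m.values["H_FURC"] == pytest.approx(11.0, abs=0.15)


class TestDahlberg:
    def test_identical_replicates_give_zero(self):
        assert dahlberg_error([(5, 5), (7, 7), (9, 9)]).S_D == 0.0

    def test_hand_computed_case(self):
        res = dahlberg_error([(1, 2), (3, 3)])
        assert res.S_D == pytest.approx(0.5)
        assert res.n == 2

    def test_recovers_injected_measurement_noise(self):
        rng = np.random.default_rng(7)
        truth = rng.uniform(5, 25, size=500)
        sigma = 0.4
        pairs = np.c_[truth + rng.normal(0, sigma, 500),
                      truth + rng.normal(0, sigma, 500)]
        assert dahlberg_error(pairs).S_D == pytest.approx(sigma, abs=0.05)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            dahlberg_error([])

    @settings(deadline=None, max_examples=25)
    @given(seed=st.integers(0, 1000), s=st.floats(0.1, 10))
    def test_scale_equivariance(self, seed, s):
        rng = np.random.default_rng(seed)
        pairs = rng.uniform(1, 10, size=(20, 2))
        base = dahlberg_error(pairs).S_D
        assert dahlberg_error(pairs * s).S_D == pytest.approx(s * base,
                                                              rel=1e-9)


class TestScale:
    def test_identity(self):
        ref = np.array([4.0, 8.0, 15.0])
        assert estimate_scale(ref, ref).factor == pytest.approx(1.0, abs=1e-12)

    def test_constructed_inverse_of_printed_factor(self):
        # the CBCT-unit calibration regime: target in raw units
        factor = 0.313854
        ref = np.array([5.1, 7.7, 11.2, 21.4, 9.6])
        cal = estimate_scale(ref, ref / factor)
        assert cal.factor == pytest.approx(factor, abs=1e-9)
        assert cal.residual_rms == pytest.approx(0.0, abs=1e-9)

    def test_noiseless_proportional_inverts_exactly(self):
        rng = np.random.default_rng(0)
        ref = rng.uniform(4, 25, 40)
        c = 3.17
        assert estimate_scale(ref, ref * c).factor * c == pytest.approx(
            1.0, abs=1e-9)

    def test_noisy_recovery(self):
        rng = np.random.default_rng(11)
        ref = rng.uniform(5, 25, 100)
        target = ref / 0.5 + rng.normal(0, 0.1, 100)
        assert estimate_scale(ref, target).factor == pytest.approx(0.5,
                                                                   abs=0.02)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            estimate_scale([1, 2], [1, 2, 3])
        with pytest.raises(ValueError):
            estimate_scale([1, -2], [1, 2])
        with pytest.raises(ValueError):
            estimate_scale([1.0], [1.0])


def _two_method_table(values_a, values_b, ids=None):
    ids = ids or [f"1.{i % 8 + 1}" for i in range(len(values_a))]
    rows = []
    for tid, a, b in zip(ids, values_a, values_b):
        rows.append((tid, "CBCT", "EQU", a))
        rows.append((tid, "PAN", "EQU", b))
    return pd.DataFrame(rows, columns=["tooth_id", "method", "parameter",
                                       "value_mm"])


class TestCompareMethods:
    def test_fdi_parsing(self):
        assert tooth_arch("2.1") == "upper"
        assert tooth_arch("3.6") == "lower"
        assert tooth_group("2.1") == "incisor"
        assert tooth_group("3.6") == "molar"

    def test_identical_methods_flagged_degenerate(self):
        rng = np.random.default_rng(0)
        vals = rng.uniform(5, 12, 20)
        ids = [f"{q}.{p}" for q in (1, 2, 3, 4) for p in range(1, 6)]
        report = compare_methods(_two_method_table(vals, vals, ids))
        overall = report["wilcoxon"]["CBCT_vs_PAN"]["overall"]
        assert overall["p_value"] == 1.0
        assert overall["flag"] == "degenerate"

    def test_shifted_method_detected(self):
        rng = np.random.default_rng(1)
        vals = rng.uniform(5, 12, 40)
        ids = [f"{q}.{p}" for q in (1, 2, 3, 4) for p in range(1, 11)]
        report = compare_methods(
            _two_method_table(vals, vals + 1.0 + rng.normal(0, 0.2, 40), ids))
        assert report["wilcoxon"]["CBCT_vs_PAN"]["overall"]["p_value"] < 0.01

    def test_report_structure_covers_protocol(self):
        rng = np.random.default_rng(2)
        ids = [f"{q}.{p}" for q in (1, 2, 3, 4) for p in range(1, 9)]
        vals = rng.uniform(5, 12, len(ids))
        report = compare_methods(
            _two_method_table(vals, vals + rng.normal(0, 0.3, len(ids)), ids))
        assert set(report["normality"]) >= {"CBCT", "PAN",
                                            "diff_CBCT_vs_PAN"}
        wil = report["wilcoxon"]["CBCT_vs_PAN"]
        assert {"upper", "lower"} <= set(wil["by_arch"])
        assert {"incisor", "molar"} <= set(wil["by_tooth_group"])
        assert "across_methods" in report["kruskal_wallis"]
        assert "across_tooth_groups" in report["kruskal_wallis"]
        for entry in (wil["overall"], report["kruskal_wallis"]["across_methods"]):
            assert {"statistic", "p_value", "n"} <= set(entry)

    def test_insufficient_data_flagged_not_crashed(self):
        table = _two_method_table([5.0], [5.1], ["1.1"])
        report = compare_methods(table)
        assert report["wilcoxon"]["CBCT_vs_PAN"]["overall"]["flag"] == \
            "insufficient data"

    def test_single_method_rejected(self):
        table = _two_method_table([5.0, 6.0], [5.1, 6.1])
        with pytest.raises(ValueError):
            compare_methods(table[table.method == "CBCT"])

    def test_null_simulation_rejects_at_nominal_rate_small(self):
        """Type-I error sanity at reduced rep count (full check in the
        acceptance suite)."""
        rng = np.random.default_rng(5)
        ids = [f"{q}.{p}" for q in (1, 2, 3, 4) for p in range(1, 11)]
        rejections = 0
        reps = 120
        for _ in range(reps):
            truth = rng.uniform(5, 12, len(ids))
            a = truth + rng.normal(0, 0.3, len(ids))
            b = truth + rng.normal(0, 0.3, len(ids))
            rep = compare_methods(_two_method_table(a, b, ids))
            rejections += rep["wilcoxon"]["CBCT_vs_PAN"]["overall"][
                "p_value"] < 0.05
        assert rejections / reps < 0.12
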