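"""Formula library: published-equation values, BSA handling, registry contract."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gfragree.formulas import (
    PatientRecord,
    ValidationError,
    adjust_bsa,
    compute_egfr,
    compute_egfr_matrix,
    du_bois_bsa,
    ellipsoid_tkv,
    get_formula,
    list_formulas,
    registry_to_json,
    unadjust_bsa,
)

ALL_IDS = [s.formula_id for s in list_formulas()]


class TestComputeEgfr:
    def test_cockcroft_gault_reduces_to_round_number(self):
        # (140-40)*72 / (72*1.0) = 100 exactly, already absolute ml/min
        p = PatientRecord("a", 40, "male", 72, 180, 1.0)
        assert compute_egfr("Cockcroft-Gault", p) == pytest.approx(100.0)

    def test_ckdepi_creatinine_female_low_creatinine(self):
        # piecewise power expression, hand-evaluated
        p = PatientRecord("b", 50, "female", 60, 160, 0.8)
        assert compute_egfr("CKD-EPI-cr", p, indexed=True) == pytest.approx(85.96, abs=0.05)

    def test_amdrd_male(self):
        p = PatientRecord("c", 60, "male", 70, 175, 1.5)
        assert compute_egfr("aMDRD", p, indexed=True) == pytest.approx(47.74, abs=0.05)

    def test_unknown_formula_raises(self):
        p = PatientRecord("d", 40, "male", 72, 180, 1.0)
        with pytest.raises(KeyError):
            compute_egfr("no-such-equation", p)

    def test_missing_cystatin_raises(self):
        p = PatientRecord("e", 40, "male", 72, 180, 1.0, cysc=None)
        with pytest.raises(ValidationError):
            compute_egfr("CKD-EPI-cy", p)

    def test_panel_matches_frozen_hand_derived_values(self, panel):
        """All 12 equations on 5 patients agree with the independent oracle
        file to 0.1 ml/min (absolute scale)."""
        for _, row in panel.iterrows():
            p = PatientRecord(
                row["id"], row["age"], row["sex"], row["weight"], row["height"],
                row["scr"], cysc=row["cysc"],
            )
            for fid in ALL_IDS:
                assert compute_egfr(fid, p) == pytest.approx(row[fid], abs=0.1), fid


class TestRegistry:
    def test_at_least_twelve_formulas(self):
        assert len(ALL_IDS) >= 12
        for required in (
            "aMDRD", "CKD-EPI-cr", "CKD-EPI-cy", "CKD-EPI-cr-cy", "Cockcroft-Gault",
            "FAS-cr", "FAS-cy", "FAS-cr-cy", "Lund-Malmö (Rv)", "Grubb-2014 (CAPA)",
            "Hoek", "Larsson",
        ):
            assert required in ALL_IDS

    def test_json_serialisation_round_trips_metadata(self):
        meta = registry_to_json()
        assert {m["formula_id"] for m in meta} == set(ALL_IDS)
        assert all(m["basis"] in ("creatinine", "cystatin", "both") for m in meta)

    @pytest.mark.parametrize("fid", ALL_IDS)
    def test_output_decreasing_in_marker(self, fid):
        """Each equation is strictly decreasing in its own marker over the
        physiological range with all else fixed."""
        spec = get_formula(fid)
        grid = np.linspace(0.3, 10.0, 80)
        for sex in ("male", "female"):
            vals = []
            for m in grid:
                scr = m if spec.basis in ("creatinine", "both") else 1.0
                cys = m if spec.basis in ("cystatin", "both") else 1.0
                p = PatientRecord("m", 50, sex, 75, 172, scr, cysc=cys)
                vals.append(compute_egfr(fid, p))
            assert np.all(np.diff(vals) < 0), f"{fid} not decreasing ({sex})"

    def test_positive_on_reasonable_inputs(self, panel):
        for _, row in panel.iterrows():
            for fid in ALL_IDS:
                assert row[fid] > 0


class TestBsa:
    @pytest.mark.parametrize(
        "weight,height,expected", [(70, 180, 1.886), (60, 160, 1.622)]
    )
    def test_du_bois_hand_values(self, weight, height, expected):
        assert du_bois_bsa(weight, height) == pytest.approx(expected, abs=0.001)

    def test_power_law_homogeneity(self):
        # scaling weight by 2^(1/0.425) doubles BSA exactly
        base = du_bois_bsa(70.0, 180.0)
        assert du_bois_bsa(70.0 * 2 ** (1 / 0.425), 180.0) == pytest.approx(2 * base)

    @pytest.mark.parametrize(
        "indexed,bsa,expected", [(60, 1.73, 60.0), (60, 2.076, 72.0), (100, 1.384, 80.0)]
    )
    def test_unadjust_ratios(self, indexed, bsa, expected):
        assert unadjust_bsa(indexed, bsa) == pytest.approx(expected)

    @settings(deadline=None, max_examples=50)
    @given(
        x=st.floats(1.0, 200.0),
        bsa=st.floats(1.2, 2.6),
    )
    def test_unadjust_adjust_round_trip(self, x, bsa):
        assert unadjust_bsa(adjust_bsa(x, bsa), bsa) == pytest.approx(x, rel=1e-12)

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ValidationError):
            du_bois_bsa(-1, 170)
        with pytest.raises(ValidationError):
            unadjust_bsa(60, 0)


class TestTkv:
    def test_zero_and_sphere(self):
        assert ellipsoid_tkv([(0, 0, 0)]) == 0.0
        assert ellipsoid_tkv([(2, 2, 2)]) == pytest.approx(np.pi / 6 * 8, abs=1e-9)

    def test_hand_value_and_two_kidneys(self):
        assert ellipsoid_tkv([(12, 6, 5)]) == pytest.approx(188.5, abs=0.05)
        assert ellipsoid_tkv([(12, 6, 5), (12, 6, 5)]) == pytest.approx(2 * 188.5, abs=0.1)

    def test_negative_diameter_rejected(self):
        with pytest.raises(ValidationError):
            ellipsoid_tkv([(1, -2, 3)])


class TestPatientRecord:
    def test_pediatric_age_rejected(self):
        with pytest.raises(ValidationError):
            PatientRecord("kid", 12, "male", 40, 150, 0.6)

    def test_nonpositive_marker_rejected(self):
        with pytest.raises(ValidationError):
            PatientRecord("x", 40, "male", 72, 180, -0.5)


def test_matrix_skips_cystatin_without_column(small_cohort):
    df = small_cohort.drop(columns=["cysc"])
    mat = compute_egfr_matrix(df, ["aMDRD", "CKD-EPI-cy"])
    assert np.all(np.isfinite(mat["aMDRD"]))
    assert np.all(np.isnan(mat["CKD-EPI-cy"]))


def test_matrix_agrees_with_scalar_path(small_cohort):
    mat = compute_egfr_matrix(small_cohort.head(10), ["CKD-EPI-cr-cy"])
    for i, (_, row) in enumerate(small_cohort.head(10).iterrows()):
        p = PatientRecord(
            row["id"], row["age"], row["sex"], row["weight"], row["height"],
            row["scr"], cysc=row["cysc"],
        )
        assert mat["CKD-EPI-cr-cy"].iloc[i] == pytest.approx(
            compute_egfr("CKD-EPI-cr-cy", p), rel=1e-12
        )
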