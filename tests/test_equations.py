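"""Equation-level tests: worked examples, piecewise structure, invariants."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import gfrbench as g
from gfrbench.equations import MissingAnalyteError

from _oracles import (
    oracle_amdrd,
    oracle_ckd_epi_cr,
    oracle_ckd_epi_cr_cys,
    oracle_ckd_epi_cys,
    oracle_mdrd7,
    oracle_re_amdrd,
)


# ---------------------------------------------------------------- examples

@pytest.mark.parametrize(
    "fn, args, expected",
    [
        (g.egfr_mdrd7, (1.0, 40, "male", False, 15, 4.0), 87.10),
        (g.egfr_amdrd, (1.0, 40, "male", False), 87.96),
        (g.egfr_re_amdrd, (1.0, 40, "male", False), 82.76),
        (g.egfr_ckd_epi_cr, (0.9, 50, "male", False), 99.24),
        (g.egfr_ckd_epi_cys, (0.8, 50, "female"), 101.45),
        (g.egfr_ckd_epi_cr_cys, (0.9, 0.8, 50, "male", False), 105.07),
    ],
)
def test_worked_examples(fn, args, expected):
    assert fn(*args) == pytest.approx(expected, abs=0.005)


def test_ckd_epi_cr_female_at_threshold():
    # 144 x 0.993^50 exactly on the threshold
    assert g.egfr_ckd_epi_cr(0.7, 50, "female") == pytest.approx(
        144 * 0.993**50, rel=1e-12
    )


@pytest.mark.parametrize(
    "fn, args, factor",
    [
        (g.egfr_mdrd7, (1.3, 45, None, False, 18, 3.9), 0.762),
        (g.egfr_amdrd, (1.3, 45, None, False), 0.742),
        (g.egfr_re_amdrd, (1.3, 45, None, False), 0.742),
    ],
)
def test_mdrd_female_factor_multiplicative(fn, args, factor):
    args_m = tuple("male" if a is None else a for a in args)
    args_f = tuple("female" if a is None else a for a in args)
    assert fn(*args_f) == pytest.approx(factor * fn(*args_m), rel=1e-14)


def test_cys_female_factor():
    m = g.egfr_ckd_epi_cys(1.1, 60, "male")
    f = g.egfr_ckd_epi_cys(1.1, 60, "female")
    assert f == pytest.approx(0.932 * m, rel=1e-14)


def test_black_factors():
    assert g.egfr_amdrd(1.2, 55, "male", True) == pytest.approx(
        1.212 * g.egfr_amdrd(1.2, 55, "male"), rel=1e-14
    )
    assert g.egfr_ckd_epi_cr(1.2, 55, "male", True) == pytest.approx(
        1.159 * g.egfr_ckd_epi_cr(1.2, 55, "male"), rel=1e-14
    )
    assert g.egfr_ckd_epi_cr_cys(1.2, 1.0, 55, "male", True) == pytest.approx(
        1.08 * g.egfr_ckd_epi_cr_cys(1.2, 1.0, 55, "male"), rel=1e-14
    )


def test_mdrd7_unit_factors_vanish():
    # BUN and albumin terms are exactly 1 at value 1
    assert g.egfr_mdrd7(1.4, 62, "male", False, 1.0, 1.0) == pytest.approx(
        170 * 1.4**-0.999 * 62**-0.176, rel=1e-14
    )


# --------------------------------------------------- piecewise structure

@pytest.mark.parametrize("sex, kappa", [("female", 0.7), ("male", 0.9)])
def test_ckd_epi_cr_branch_continuity(sex, kappa):
    eps = 1e-12
    at = g.egfr_ckd_epi_cr(kappa, 40, sex)
    below = g.egfr_ckd_epi_cr(kappa - eps, 40, sex)
    above = g.egfr_ckd_epi_cr(kappa + eps, 40, sex)
    assert below == pytest.approx(at, rel=1e-9)
    assert above == pytest.approx(at, rel=1e-9)


def test_ckd_epi_cys_branch_continuity():
    at = g.egfr_ckd_epi_cys(0.8, 40, "male")
    assert g.egfr_ckd_epi_cys(0.8 - 1e-12, 40, "male") == pytest.approx(at, rel=1e-9)
    assert g.egfr_ckd_epi_cys(0.8 + 1e-12, 40, "male") == pytest.approx(at, rel=1e-9)


@pytest.mark.parametrize("sex, kappa", [("female", 0.7), ("male", 0.9)])
def test_ckd_epi_cr_cys_continuity_both_markers(sex, kappa):
    at = g.egfr_ckd_epi_cr_cys(kappa, 0.8, 40, sex)
    for scr in (kappa - 1e-12, kappa + 1e-12):
        for scys in (0.8 - 1e-12, 0.8 + 1e-12):
            assert g.egfr_ckd_epi_cr_cys(scr, scys, 40, sex) == pytest.approx(
                at, rel=1e-9
            )


# ------------------------------------------------------------- invariants

@given(
    scr=st.floats(0.2, 15.0),
    age=st.floats(18.0, 95.0),
    sex=st.sampled_from(["male", "female"]),
    black=st.booleans(),
)
def test_re_amdrd_is_rescaled_amdrd(scr, age, sex, black):
    a = g.egfr_amdrd(scr, age, sex, black)
    r = g.egfr_re_amdrd(scr, age, sex, black)
    assert r == pytest.approx(a * 175.0 / 186.0, rel=1e-13)


@given(
    scr=st.floats(0.2, 15.0),
    scys=st.floats(0.2, 8.0),
    age=st.floats(18.0, 95.0),
    sex=st.sampled_from(["male", "female"]),
)
def test_strictly_decreasing_in_markers_and_age(scr, scys, age, sex):
    for fn, args, bumped in [
        (g.egfr_ckd_epi_cr, (scr, age, sex), (scr * 1.01, age, sex)),
        (g.egfr_ckd_epi_cys, (scys, age, sex), (scys * 1.01, age, sex)),
        (g.egfr_ckd_epi_cr_cys, (scr, scys, age, sex), (scr * 1.01, scys * 1.01, age, sex)),
        (g.egfr_amdrd, (scr, age, sex), (scr * 1.01, age, sex)),
    ]:
        assert fn(*bumped) < fn(*args)
    assert g.egfr_ckd_epi_cr(scr, age + 1, sex) < g.egfr_ckd_epi_cr(scr, age, sex)
    assert g.egfr_ckd_epi_cys(scys, age + 1, sex) < g.egfr_ckd_epi_cys(scys, age, sex)


def test_oracle_equivalence_random_inputs(rng):
    """All six equations agree with the arbitrary-precision re-evaluation
    of the printed expressions to relative error < 1e-12."""
    n = 200
    scr = rng.uniform(0.2, 12.0, n)
    scys = rng.uniform(0.2, 7.0, n)
    age = rng.uniform(18.0, 92.0, n)
    bun = rng.uniform(4.0, 80.0, n)
    alb = rng.uniform(1.5, 5.5, n)
    sexes = np.where(rng.random(n) < 0.5, "male", "female")
    blacks = rng.random(n) < 0.5
    for i in range(n):
        s, c, a = scr[i], scys[i], age[i]
        sx, bl = str(sexes[i]), bool(blacks[i])
        pairs = [
            (g.egfr_mdrd7(s, a, sx, bl, bun[i], alb[i]),
             oracle_mdrd7(s, a, sx, bl, bun[i], alb[i])),
            (g.egfr_amdrd(s, a, sx, bl), oracle_amdrd(s, a, sx, bl)),
            (g.egfr_re_amdrd(s, a, sx, bl), oracle_re_amdrd(s, a, sx, bl)),
            (g.egfr_ckd_epi_cr(s, a, sx, bl), oracle_ckd_epi_cr(s, a, sx, bl)),
            (g.egfr_ckd_epi_cys(c, a, sx), oracle_ckd_epi_cys(c, a, sx)),
            (g.egfr_ckd_epi_cr_cys(s, c, a, sx, bl),
             oracle_ckd_epi_cr_cys(s, c, a, sx, bl)),
        ]
        for got, want in pairs:
            assert got == pytest.approx(want, rel=1e-12)


# ------------------------------------------------- helpers and conversions

def test_bsa_dubois_examples():
    assert g.bsa_dubois(62.0, 163.9) == pytest.approx(1.67, abs=0.005)
    assert round(g.bsa_dubois(62.0, 163.9), 1) == 1.7
    assert g.bsa_dubois(1, 1) == pytest.approx(0.007184, rel=1e-14)
    assert g.bsa_dubois(124.0, 163.9) == pytest.approx(
        2**0.425 * g.bsa_dubois(62.0, 163.9), rel=1e-13
    )


def test_bmi_examples():
    assert g.bmi(100, 100) == pytest.approx(100.0)
    assert g.bmi(62.0, 163.9) == pytest.approx(23.08, abs=0.005)
    assert g.bmi(31.0, 163.9) == pytest.approx(g.bmi(62.0, 163.9) / 2, rel=1e-14)


def test_standardize_gfr_roundtrip():
    assert g.standardize_gfr(60, 1.73) == pytest.approx(60.0)
    assert g.standardize_gfr(60, 0.865) == pytest.approx(120.0)
    raw = 73.2
    assert g.destandardize_gfr(g.standardize_gfr(raw, 1.91), 1.91) == pytest.approx(
        raw, rel=1e-14
    )


def test_convert_units():
    assert g.convert_units(88.4, "creatinine_umol_l", "creatinine_mg_dl") == pytest.approx(1.0)
    assert g.convert_units(60.0, "urea_mg_dl", "urea_nitrogen_mg_dl") == pytest.approx(28.0)
    for a, b, v in [
        ("creatinine_umol_l", "creatinine_mg_dl", 123.0),
        ("urea_mmol_l", "urea_mg_dl", 7.5),
        ("urea_mg_dl", "urea_nitrogen_mg_dl", 33.0),
    ]:
        assert g.convert_units(g.convert_units(v, a, b), b, a) == pytest.approx(v, rel=1e-14)
    with pytest.raises(ValueError, match="unsupported"):
        g.convert_units(1.0, "creatinine_umol_l", "urea_mg_dl")


# ---------------------------------------------------------------- errors

def test_missing_analyte_errors_name_the_analyte():
    with pytest.raises(MissingAnalyteError, match="bun"):
        g.egfr_mdrd7(1.0, 40, "male", False, None, 4.0)
    with pytest.raises(MissingAnalyteError, match="albumin"):
        g.egfr_mdrd7(1.0, 40, "male", False, 15, None)
    with pytest.raises(MissingAnalyteError, match="scys"):
        g.egfr_ckd_epi_cys(None, 40, "male")


def test_domain_errors():
    with pytest.raises(ValueError):
        g.egfr_amdrd(-1.0, 40, "male")
    with pytest.raises(ValueError):
        g.egfr_ckd_epi_cr(1.0, 16, "male")
    with pytest.raises(ValueError):
        g.bsa_dubois(0.0, 170.0)
    with pytest.raises(ValueError):
        g.egfr_amdrd(1.0, 40, "M")


def test_patient_record_validation():
    rec = g.PatientRecord("p1", 40, "male", 70, 175, 1.0, mgfr_std=80.0)
    assert rec.to_row()["scr_mgdl"] == 1.0
    with pytest.raises(ValueError, match="age"):
        g.PatientRecord("p2", 17, "male", 70, 175, 1.0)
    with pytest.raises(ValueError, match="scr"):
        g.PatientRecord("p3", 40, "male", 70, 175, -1.0)
    with pytest.raises(ValueError, match="sex"):
        g.PatientRecord("p4", 40, "m", 70, 175, 1.0)


# ------------------------------------------------------------ table layer

def test_estimate_table_missing_markers(tmp_path):
    import pandas as pd

    df = pd.DataFrame(
        {
            "patient_id": ["a", "b", "c"],
            "age": [40.0, 55.0, 60.0],
            "sex": ["male", "female", "male"],
            "race_black": [False, False, False],
            "scr_mgdl": [1.0, 1.4, 0.8],
            "scys_mgl": [0.9, None, 1.2],
            "bun_mgdl": [15.0, 20.0, None],
            "albumin_gdl": [4.0, 3.5, 3.8],
        }
    )
    est = g.estimate_table(df)
    assert list(est.columns) == [e.value for e in g.EquationId]
    assert np.isnan(est.loc[1, "CKD_EPI_CYS"])  # no cystatin
    assert np.isnan(est.loc[1, "CKD_EPI_CR_CYS"])
    assert np.isnan(est.loc[2, "MDRD7"])  # no BUN
    present = est.drop(index=[1, 2]).to_numpy(float)
    assert np.all(np.isfinite(present)) and np.all(present > 0)
    # row a matches scalar calls
    assert est.loc[0, "CKD_EPI_CR"] == pytest.approx(g.egfr_ckd_epi_cr(1.0, 40, "male"))
    assert est.loc[0, "MDRD7"] == pytest.approx(g.egfr_mdrd7(1.0, 40, "male", False, 15, 4.0))


def test_patient_csv_roundtrip(tmp_path, default_cohort):
    path = tmp_path / "cohort.csv"
    g.write_patients(default_cohort, path)
    back = g.read_patients(path)
    assert len(back) == len(default_cohort)
    np.testing.assert_allclose(
        back["scr_mgdl"].to_numpy(), default_cohort["scr_mgdl"].to_numpy(), rtol=1e-12
    )
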