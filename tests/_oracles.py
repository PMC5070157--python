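"""Independent oracles used by the test suite.

Kept deliberately separate from the package: the equation oracle
re-evaluates the printed formulas in arbitrary precision with sympy, the
AUC oracle counts case-control pairs by brute force.
"""

from __future__ import annotations

import numpy as np
import sympy as sp

PREC = 50


def _F(x) -> sp.Float:
    return sp.Float(x, PREC)


def _powf(base, expo):
    return sp.Pow(_F(base), sp.Float(expo, PREC))


def oracle_mdrd7(scr, age, sex, black, bun, alb) -> float:
    v = (
        _F(170)
        * _powf(scr, "-0.999")
        * _powf(age, "-0.176")
        * _powf(bun, "-0.170")
        * _powf(alb, "0.318")
    )
    if sex == "female":
        v *= sp.Float("0.762", PREC)
    if black:
        v *= sp.Float("1.180", PREC)
    return float(v.evalf(PREC))


def _oracle_mdrd4(const, scr, age, sex, black) -> float:
    v = _F(const) * _powf(scr, "-1.154") * _powf(age, "-0.203")
    if sex == "female":
        v *= sp.Float("0.742", PREC)
    if black:
        v *= sp.Float("1.212", PREC)
    return float(v.evalf(PREC))


def oracle_amdrd(scr, age, sex, black) -> float:
    return _oracle_mdrd4(186, scr, age, sex, black)


def oracle_re_amdrd(scr, age, sex, black) -> float:
    return _oracle_mdrd4(175, scr, age, sex, black)


def oracle_ckd_epi_cr(scr, age, sex, black) -> float:
    if sex == "female":
        const, kappa, alpha = 144, "0.7", "-0.329"
    else:
        const, kappa, alpha = 141, "0.9", "-0.411"
    expo = alpha if _F(scr) <= sp.Float(kappa, PREC) else "-1.209"
    v = (
        _F(const)
        * sp.Pow(_F(scr) / sp.Float(kappa, PREC), sp.Float(expo, PREC))
        * sp.Pow(sp.Float("0.993", PREC), _F(age))
    )
    if black:
        v *= sp.Float("1.159", PREC)
    return float(v.evalf(PREC))


def oracle_ckd_epi_cys(scys, age, sex) -> float:
    expo = "-0.499" if _F(scys) <= sp.Float("0.8", PREC) else "-1.328"
    v = (
        _F(133)
        * sp.Pow(_F(scys) / sp.Float("0.8", PREC), sp.Float(expo, PREC))
        * sp.Pow(sp.Float("0.996", PREC), _F(age))
    )
    if sex == "female":
        v *= sp.Float("0.932", PREC)
    return float(v.evalf(PREC))


def oracle_ckd_epi_cr_cys(scr, scys, age, sex, black) -> float:
    if sex == "female":
        const, kappa, alpha = 130, "0.7", "-0.248"
    else:
        const, kappa, alpha = 135, "0.9", "-0.207"
    cr_expo = alpha if _F(scr) <= sp.Float(kappa, PREC) else "-0.601"
    cys_expo = "-0.375" if _F(scys) <= sp.Float("0.8", PREC) else "-0.711"
    v = (
        _F(const)
        * sp.Pow(_F(scr) / sp.Float(kappa, PREC), sp.Float(cr_expo, PREC))
        * sp.Pow(_F(scys) / sp.Float("0.8", PREC), sp.Float(cys_expo, PREC))
        * sp.Pow(sp.Float("0.995", PREC), _F(age))
    )
    if black:
        v *= sp.Float("1.08", PREC)
    return float(v.evalf(PREC))


def brute_force_auc(scores, positive) -> float:
    """Mann-Whitney pair counting: every case-control pair, ties count 1/2.

    Cases are the positive class; lower scores rank as more diseased, so a
    case scoring *below* a control counts as a correctly ordered pair.
    """
    scores = np.asarray(scores, dtype=float)
    positive = np.asarray(positive, dtype=bool)
    cases = scores[positive]
    controls = scores[~positive]
    total = 0.0
    for s_case in cases:
        for s_ctrl in controls:
            if s_case < s_ctrl:
                total += 1.0
            elif s_case == s_ctrl:
                total += 0.5
    return total / (len(cases) * len(controls))
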