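"""Estimated glomerular filtration rate (eGFR) equations.

Implements the four estimating equations used to label kidney-function
trajectories in the discovery cohort:

* CKD-EPI 2009 creatinine
* CKD-EPI 2012 cystatin C
* CKD-EPI 2012 creatinine–cystatin C (combined)
* EKFC cystatin C (adult form)

plus analytic inversion of the two single-analyte CKD-EPI equations, used
by the cohort simulator to back-calculate serum markers from a known true
GFR.

Units are fixed and never auto-detected: serum creatinine in mg/dL, serum
cystatin C in mg/L, age in years, eGFR in mL/min/1.73 m². Passing a value
in the wrong unit is the dominant real-world failure mode for this kind of
code, so anything non-positive raises instead of propagating NaN.

The 2021 race-free CKD-EPI refits are deliberately not implemented; the
optional Black race coefficient of the 2009/2012 equations is exposed as a
flag but off by default (European cohorts).
"""

from __future__ import annotations

from enum import Enum
from typing import Optional

import numpy as np

__all__ = [
    "EgfrMethod",
    "MissingAnalyteError",
    "AnalyteDomainError",
    "compute_egfr",
    "invert_egfr",
    "EKFC_Q_DEFAULT",
]

#: Default EKFC cystatin normalization constant Q (mg/L), sex-independent.
EKFC_Q_DEFAULT = 0.83


class EgfrMethod(str, Enum):
    """The four estimating equations applied to the discovery cohort."""

    CKD_EPI_CR = "CKD_EPI_CR"
    CKD_EPI_CYS = "CKD_EPI_CYS"
    CKD_EPI_CR_CYS = "CKD_EPI_CR_CYS"
    EKFC_CYS = "EKFC_CYS"


class MissingAnalyteError(ValueError):
    """A required serum analyte was not supplied."""


class AnalyteDomainError(ValueError):
    """An input lies outside the equation's domain (non-positive analyte/age)."""


def _check_sex(sex):
    sex = np.asarray(sex)
    ok = np.isin(sex, ("F", "M"))
    if not np.all(ok):
        bad = np.unique(sex[~ok])
        raise ValueError(f"sex must be 'F' or 'M', got {bad!r}")
    return sex


def _check_positive(name: str, value) -> np.ndarray:
    arr = np.asarray(value, dtype=float)
    if np.any(~np.isfinite(arr)) or np.any(arr <= 0):
        raise AnalyteDomainError(f"{name} must be finite and > 0")
    return arr


def _ckd_epi_cr(scr, age, female, black):
    kappa = np.where(female, 0.7, 0.9)
    alpha = np.where(female, -0.329, -0.411)
    r = scr / kappa
    out = (
        141.0
        * np.minimum(r, 1.0) ** alpha
        * np.maximum(r, 1.0) ** -1.209
        * 0.993**age
    )
    out = out * np.where(female, 1.018, 1.0)
    if black:
        out = out * 1.159
    return out

def _ckd_epi_cys(scys, age, female):
    r = scys / 0.8
    out = (
        133.0
        * np.minimum(r, 1.0) ** -0.499
        * np.maximum(r, 1.0) ** -1.328
        * 0.996**age
    )
    return out * np.where(female, 0.932, 1.0)

def _ckd_epi_cr_cys(scr, scys, age, female, black):
    kappa = np.where(female, 0.7, 0.9)
    alpha = np.where(female, -0.248, -0.207)
    rcr = scr / kappa
    rcys = scys / 0.8
    out = (
        135.0
        * np.minimum(rcr, 1.0) ** alpha
        * np.maximum(rcr, 1.0) ** -0.601
        * np.minimum(rcys, 1.0) ** -0.375
        * np.maximum(rcys, 1.0) ** -0.711
        * 0.995**age
    )
    out = out * np.where(female, 0.969, 1.0)
    if black:
        out = out * 1.08
    return out

def _ekfc_cys(scys, age, q):
    r = scys / q
    out = 107.3 * np.where(r < 1.0, r**-0.322, r**-1.132)
    # age factor applies only above 40 years
    return out * np.where(age > 40.0, 0.990 ** (np.maximum(age, 40.0) - 40.0), 1.0)


def compute_egfr(
    age,
    sex,
    method: EgfrMethod,
    scr=None,
    scys=None,
    *,
    black: bool = False,
    ekfc_q: Optional[float] = None,
):
    """Compute eGFR (mL/min/1.73 m²) by one of the four equations.

    Parameters
    ----------
    age : float or array
        Age in years at the time of the serum measurement; must be > 0.
    sex : {'F', 'M'} or array
    method : EgfrMethod
    scr : float or array, optional
        Serum creatinine in mg/dL; required for CKD_EPI_CR and CKD_EPI_CR_CYS.
    scys : float or array, optional
        Serum cystatin C in mg/L; required for the cystatin-based equations.
    black : bool
        Apply the published 2009/2012 Black race coefficient (1.159 creatinine,
        1.08 combined). Off by default; no coefficient exists for EKFC.
    ekfc_q : float, optional
        EKFC normalization constant Q in mg/L (default 0.83, sex-independent).

    Returns
    -------
    float or ndarray — finite, strictly positive.

    Raises
    ------
    MissingAnalyteError
        If the analyte the chosen equation needs was not supplied.
    AnalyteDomainError
        If age or a supplied analyte is non-positive or non-finite.
    """
    method = EgfrMethod(method)
    age = _check_positive("age", age)
    sex = _check_sex(sex)
    female = sex == "F"

    needs_cr = method in (EgfrMethod.CKD_EPI_CR, EgfrMethod.CKD_EPI_CR_CYS)
    needs_cys = method in (
        EgfrMethod.CKD_EPI_CYS,
        EgfrMethod.CKD_EPI_CR_CYS,
        EgfrMethod.EKFC_CYS,
    )
    if needs_cr and scr is None:
        raise MissingAnalyteError(f"{method.value} requires serum creatinine (scr)")
    if needs_cys and scys is None:
        raise MissingAnalyteError(f"{method.value} requires serum cystatin C (scys)")
    if needs_cr:
        scr = _check_positive("scr", scr)
    if needs_cys:
        scys = _check_positive("scys", scys)

    if method is EgfrMethod.CKD_EPI_CR:
        out = _ckd_epi_cr(scr, age, female, black)
    elif method is EgfrMethod.CKD_EPI_CYS:
        out = _ckd_epi_cys(scys, age, female)
    elif method is EgfrMethod.CKD_EPI_CR_CYS:
        out = _ckd_epi_cr_cys(scr, scys, age, female, black)
    else:
        out = _ekfc_cys(scys, age, EKFC_Q_DEFAULT if ekfc_q is None else ekfc_q)
    return out if out.ndim else float(out)


def invert_egfr(
    target_gfr,
    age,
    sex,
    method: EgfrMethod,
    *,
    black: bool = False,
):
    """Solve a single-analyte CKD-EPI equation for the serum marker.

    Given a target eGFR, returns the serum creatinine (CKD_EPI_CR, mg/dL) or
    cystatin C (CKD_EPI_CYS, mg/L) that the forward equation maps back to it.
    Both equations are strictly decreasing power laws of the analyte on each
    side of the knot, so the inversion is analytic: the branch is selected by
    comparing the target with the eGFR attained exactly at the knot.

    Raises :class:`AnalyteDomainError` for non-positive targets. Any positive
    target is reachable (the equations cover (0, ∞) as the analyte ranges over
    (0, ∞)).
    """
    method = EgfrMethod(method)
    g = _check_positive("target_gfr", target_gfr)
    age = _check_positive("age", age)
    sex = _check_sex(sex)
    female = sex == "F"

    if method is EgfrMethod.CKD_EPI_CR:
        kappa = np.where(female, 0.7, 0.9)
        alpha = np.where(female, -0.329, -0.411)
        scale = 141.0 * 0.993**age * np.where(female, 1.018, 1.0)
        if black:
            scale = scale * 1.159
        ratio = g / scale  # = min(r,1)^alpha * max(r,1)^-1.209 at r = scr/kappa
        # ratio < 1  <=>  scr > kappa (high branch, exponent -1.209)
        r = np.where(ratio < 1.0, ratio ** (-1.0 / 1.209), ratio ** (1.0 / alpha))
        out = kappa * r
    elif method is EgfrMethod.CKD_EPI_CYS:
        scale = 133.0 * 0.996**age * np.where(female, 0.932, 1.0)
        ratio = g / scale
        r = np.where(ratio < 1.0, ratio ** (-1.0 / 1.328), ratio ** (-1.0 / 0.499))
        out = 0.8 * r
    else:
        raise ValueError(f"invert_egfr supports CKD_EPI_CR and CKD_EPI_CYS, not {method.value}")
    return out if out.ndim else float(out)
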