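"""Creatinine-based estimated GFR equations.

Two published estimating equations are provided: the 2009 CKD-EPI
creatinine equation for adults and the bedside Schwartz (CKiD) equation
for children.  Both return eGFR in mL/min per 1.73 m^2 of body surface
area.  ``egfr_auto`` routes subjects under 18 years of age to the
pediatric equation, which is how pediatric status is conventionally
defined in proteinuric-glomerulopathy cohorts.
"""

from __future__ import annotations

__all__ = ["egfr_ckdepi", "egfr_ckid", "egfr_auto"]

# 2009 CKD-EPI creatinine equation constants
_KAPPA = {"female": 0.7, "male": 0.9}
_ALPHA = {"female": -0.329, "male": -0.411}
_BETA = -1.209          # exponent above the knot
_AGE_FACTOR = 0.993     # per year of age
_FEMALE_FACTOR = 1.018
_BLACK_FACTOR = 1.159
_INTERCEPT = 141.0

# bedside Schwartz constant, height in metres
_SCHWARTZ_K = 41.3


def egfr_ckdepi(serum_creatinine: float, age: float, female: bool, black: bool) -> float:
    """Adult eGFR from the 2009 CKD-EPI creatinine equation.

    Parameters
    ----------
    serum_creatinine : float
        Serum creatinine in mg/dL, must be positive.
    age : float
        Age in years.
    female, black : bool
        Sex and race adjustment flags of the published equation.

    Returns
    -------
    float
        eGFR in mL/min/1.73 m^2.

    Notes
    -----
    The equation is a piecewise power law in creatinine,
    ``141 * min(Scr/k, 1)**alpha * max(Scr/k, 1)**-1.209 * 0.993**age``
    with sex-specific knot ``k`` and exponent ``alpha``, times 1.018 for
    women and 1.159 for Black subjects.  It is continuous at the knot.
    """
    scr = float(serum_creatinine)
    if not scr > 0:
        raise ValueError(f"serum creatinine must be positive, got {serum_creatinine}")
    sex = "female" if female else "male"
    kappa = _KAPPA[sex]
    alpha = _ALPHA[sex]
    ratio = scr / kappa
    value = (
        _INTERCEPT
        * min(ratio, 1.0) ** alpha
        * max(ratio, 1.0) ** _BETA
        * _AGE_FACTOR ** age
    )
    if female:
        value *= _FEMALE_FACTOR
    if black:
        value *= _BLACK_FACTOR
    return value


def egfr_ckid(height: float, serum_creatinine: float) -> float:
    """Pediatric eGFR from the bedside Schwartz (CKiD) equation.

    ``eGFR = 41.3 * height / Scr`` with height in metres and serum
    creatinine in mg/dL.
    """
    if not height > 0:
        raise ValueError(f"height must be positive, got {height}")
    if not serum_creatinine > 0:
        raise ValueError(f"serum creatinine must be positive, got {serum_creatinine}")
    return _SCHWARTZ_K * float(height) / float(serum_creatinine)


def egfr_auto(
    serum_creatinine: float,
    age: float,
    female: bool,
    black: bool,
    height: float | None = None,
) -> float:
    """Route to CKiD below age 18, CKD-EPI otherwise.

    Children require ``height``; adults ignore it.
    """
    if age < 18:
        if height is None:
            raise ValueError("height is required for pediatric (age < 18) subjects")
        return egfr_ckid(height, serum_creatinine)
    return egfr_ckdepi(serum_creatinine, age, female, black)


def invert_ckdepi(egfr: float, age: float, female: bool, black: bool) -> float:
    """Serum creatinine (mg/dL) that yields ``egfr`` under CKD-EPI.

    The equation is strictly decreasing in creatinine, so the inverse is
    unique; used by the cohort simulator to attach a consistent
    creatinine to a sampled eGFR.
    """
    if not egfr > 0:
        raise ValueError("eGFR must be positive")
    sex = "female" if female else "male"
    kappa = _KAPPA[sex]
    alpha = _ALPHA[sex]
    base = _INTERCEPT * _AGE_FACTOR ** age
    if female:
        base *= _FEMALE_FACTOR
    if black:
        base *= _BLACK_FACTOR
    at_knot = base  # value when Scr == kappa
    if egfr >= at_knot:
        # below-knot branch: egfr = base * ratio**alpha, alpha < 0
        ratio = (egfr / base) ** (1.0 / alpha)
    else:
        ratio = (egfr / base) ** (1.0 / _BETA)
    return kappa * ratio


def invert_ckid(egfr: float, height: float) -> float:
    """Serum creatinine (mg/dL) that yields ``egfr`` under bedside Schwartz."""
    if not egfr > 0:
        raise ValueError("eGFR must be positive")
    if not height > 0:
        raise ValueError("height must be positive")
    return _SCHWARTZ_K * height / egfr
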