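"""Closed-form equations: EBM, treadmill workload, and VO2peak prediction.

Exercise body mass (EBM) is an allometric body-size metric,

    EBM = Mass^0.63 · Height^0.53 · 1.16^[male] · exp(-0.39 · (Age/100)²),

with mass in kg and height in m.  Workload (WL, in METs) on a treadmill
is estimated from speed Sp (mph), fractional grade fGr and heart-rate
reserve HRR (bpm) as

    WL = 2 + Sp·(1.06 + 5.22·fGr) + 0.019·HRR,

and the generalized prediction is VO2peak = 11 · EBM · WL (ml·min⁻¹),
where 11 ml·min⁻¹ per EBM unit is the oxygen cost of one MET.  The
conventional alternative indexes to total body mass with the constant
3.5 ml·kg⁻¹·min⁻¹ and a literature treadmill workload formula.

All low-level functions broadcast over numpy arrays; the ``compute_*``
wrappers take :class:`~ebmscale.records.Subject` /
:class:`~ebmscale.records.ExerciseTest` records.
"""

from __future__ import annotations

import warnings
from typing import Literal

import numpy as np

from .constants import DEFAULT_CONSTANTS, ScalingConstants
from .records import DomainWarning, ExerciseTest, Subject

__all__ = [
    "ebm_allometric",
    "ebm_additive",
    "compute_ebm_allometric",
    "compute_ebm_additive",
    "workload_ebm",
    "workload_kokkinos",
    "predict_vo2peak",
    "prediction_record",
    "index_vo2peak",
    "lbm_equivalent",
    "bcm_scale",
    "mph_to_m_per_min",
    "m_per_min_to_mph",
    "vo2_to_mets",
]


def _maybe_scalar(x: np.ndarray) -> np.ndarray | float:
    return float(x) if np.ndim(x) == 0 else x


def _male_indicator(male) -> np.ndarray:
    """Accept booleans, 0/1, or 'male'/'female' strings (scalar or array)."""
    arr = np.asarray(male)
    if arr.dtype.kind == "O":
        arr = arr.astype(str)
    if arr.dtype.kind in "US":
        lowered = np.char.lower(arr.astype(str))
        bad = ~np.isin(lowered, ("male", "female"))
        if np.any(bad):
            raise ValueError(f"unrecognised sex value(s): {np.unique(arr[bad])}")
        return (lowered == "male").astype(float)
    return arr.astype(float)


def ebm_allometric(
    mass,
    height,
    male,
    age,
    constants: ScalingConstants = DEFAULT_CONSTANTS,
):
    """Allometric exercise body mass.

    Evaluated in log space: exp(a·ln mass + b·ln height + [male]·ln 1.16
    + c·(age/100)²), which is numerically stable and makes the
    log-linear regression that produced the coefficients explicit.

    Parameters are broadcast; ``male`` may be boolean, 0/1 or a
    "male"/"female" string array.  Returns EBM units (dimensionally
    kg^0.63·m^0.53).
    """
    mass = np.asarray(mass, dtype=float)
    height = np.asarray(height, dtype=float)
    age = np.asarray(age, dtype=float)
    if np.any(mass <= 0):
        raise ValueError("mass must be strictly positive (kg)")
    if np.any(height <= 0):
        raise ValueError("height must be strictly positive (m)")
    if np.any(age < 0):
        raise ValueError("age must be >= 0 (years)")
    ind = _male_indicator(male)
    c = constants
    log_ebm = (
        c.mass_exp * np.log(mass)
        + c.height_exp * np.log(height)
        + ind * np.log(c.male_factor)
        + c.age_coef * (age / 100.0) ** 2
    )
    return _maybe_scalar(np.exp(log_ebm))


def ebm_additive(
    mass,
    height,
    male,
    age,
    constants: ScalingConstants = DEFAULT_CONSTANTS,
):
    """Sex-specific additive approximation to the allometric EBM.

    EBM ≈ b0 + b1·mass + b2·height + b3·age with published per-sex
    coefficients (age in years).  Intended as a clinically convenient
    approximation; can go non-positive for extreme inputs, in which
    case a :class:`DomainWarning` is emitted and the value returned.
    """
    mass = np.asarray(mass, dtype=float)
    height = np.asarray(height, dtype=float)
    age = np.asarray(age, dtype=float)
    if np.any(mass <= 0) or np.any(height <= 0):
        raise ValueError("mass and height must be strictly positive")
    ind = _male_indicator(male)
    m = constants.additive_male
    f = constants.additive_female
    male_val = m[0] + m[1] * mass + m[2] * height + m[3] * age
    female_val = f[0] + f[1] * mass + f[2] * height + f[3] * age
    out = ind * male_val + (1.0 - ind) * female_val
    if np.any(np.asarray(out) <= 0):
        warnings.warn(
            "additive EBM is non-positive for at least one record; the "
            "additive form is an approximation valid over typical adult "
            "anthropometrics",
            DomainWarning,
            stacklevel=2,
        )
    return _maybe_scalar(out)


def compute_ebm_allometric(
    subject: Subject, constants: ScalingConstants = DEFAULT_CONSTANTS
) -> float:
    """Allometric EBM of one subject."""
    return ebm_allometric(subject.mass, subject.height, subject.is_male, subject.age, constants)


def compute_ebm_additive(
    subject: Subject, constants: ScalingConstants = DEFAULT_CONSTANTS
) -> float:
    """Additive-approximation EBM of one subject."""
    return ebm_additive(subject.mass, subject.height, subject.is_male, subject.age, constants)


def workload_ebm(
    speed_mph,
    fractional_grade,
    hrr,
    constants: ScalingConstants = DEFAULT_CONSTANTS,
):
    """Treadmill workload in METs from speed, grade and heart-rate reserve.

    WL = 2 + Sp·(1.06 + 5.22·fGr) + 0.019·HRR.  The intercept of 2 METs
    (rather than 1) reflects the reduced economy of slow locomotion.
    Always >= the intercept for valid inputs.
    """
    sp = np.asarray(speed_mph, dtype=float)
    gr = np.asarray(fractional_grade, dtype=float)
    hr = np.asarray(hrr, dtype=float)
    if np.any(sp < 0):
        raise ValueError("speed must be >= 0 mph")
    if np.any((gr < 0) | (gr > 1)):
        raise ValueError("fractional_grade must lie in [0, 1] (fraction, not percent)")
    if np.any(hr < 0):
        raise ValueError("hrr must be >= 0 bpm")
    c = constants
    return _maybe_scalar(c.wl_intercept + sp * (c.wl_speed + c.wl_speed_grade * gr) + c.wl_hrr * hr)


def workload_kokkinos(
    speed_m_per_min,
    fractional_grade,
    constants: ScalingConstants = DEFAULT_CONSTANTS,
):
    """Comparator treadmill workload (METs) from the FRIEND-registry formula.

    [Sp(m/min)·(0.17 + 0.79·fGr) + 3.5] / 3.5 — the classic
    speed-and-grade estimate with a 1-MET resting term and no
    heart-rate adjustment.
    """
    sp = np.asarray(speed_m_per_min, dtype=float)
    gr = np.asarray(fractional_grade, dtype=float)
    if np.any(sp < 0):
        raise ValueError("speed must be >= 0 m/min")
    if np.any((gr < 0) | (gr > 1)):
        raise ValueError("fractional_grade must lie in [0, 1]")
    a, b, rest = constants.kokkinos
    return _maybe_scalar((sp * (a + b * gr) + rest) / rest)


def predict_vo2peak(
    subject: Subject,
    test: ExerciseTest,
    standard: Literal["ebm", "total_mass"] = "ebm",
    constants: ScalingConstants = DEFAULT_CONSTANTS,
    workload: Literal["ebm", "kokkinos"] | None = None,
) -> float:
    """Predict absolute VO2peak (ml O2 · min⁻¹).

    ``standard="ebm"`` uses the generalized equation 11 · EBM · WL with
    the HRR-aware workload; ``standard="total_mass"`` uses the
    conventional 3.5 · mass · WL.  Each standard defaults to its own
    workload formula (EBM standard → EBM workload, total-mass standard →
    comparator speed/grade workload); pass ``workload=`` to mix.
    """
    if standard not in ("ebm", "total_mass"):
        raise ValueError(f"standard must be 'ebm' or 'total_mass', got {standard!r}")
    if workload is None:
        workload = "ebm" if standard == "ebm" else "kokkinos"
    if workload == "ebm":
        wl = workload_ebm(test.speed, test.fractional_grade, test.hrr, constants)
    elif workload == "kokkinos":
        wl = workload_kokkinos(
            test.speed * constants.mph_to_m_per_min, test.fractional_grade, constants
        )
    else:
        raise ValueError(f"workload must be 'ebm' or 'kokkinos', got {workload!r}")
    if standard == "ebm":
        return constants.ebm_met_constant * compute_ebm_allometric(subject, constants) * wl
    return constants.met_ml_per_kg * subject.mass * wl


def prediction_record(
    subject: Subject,
    test: ExerciseTest,
    standard: Literal["ebm", "total_mass"] = "ebm",
    constants: ScalingConstants = DEFAULT_CONSTANTS,
) -> dict[str, float | str]:
    """Full prediction breakdown for reporting: EBM, WL, VO2 (ml/min, METs)."""
    ebm = compute_ebm_allometric(subject, constants)
    if standard == "ebm":
        wl = workload_ebm(test.speed, test.fractional_grade, test.hrr, constants)
    else:
        wl = workload_kokkinos(
            test.speed * constants.mph_to_m_per_min, test.fractional_grade, constants
        )
    vo2 = predict_vo2peak(subject, test, standard, constants)
    return {
        "standard": standard,
        "ebm": float(ebm),
        "wl_mets": float(wl),
        "vo2peak_ml_min": float(vo2),
        "vo2peak_mets": float(vo2 / (constants.met_ml_per_kg * subject.mass)),
    }


def index_vo2peak(
    vo2,
    subject: Subject | None = None,
    scaler: Literal["mass", "mass_0p7", "ebm"] = "mass",
    met_display: bool = False,
    constants: ScalingConstants = DEFAULT_CONSTANTS,
    *,
    mass=None,
    height=None,
    male=None,
    age=None,
):
    """Index absolute VO2peak (ml/min) to a body-size metric.

    ``scaler`` divides by total mass, mass^0.7, or EBM.  With
    ``met_display=True`` the result is further standardised to METs by
    the scaler's MET constant (3.5 for mass, 11 for EBM); the mass^0.7
    comparator has no published MET constant and rejects MET display.
    Either a :class:`Subject` or explicit arrays may be given.
    """
    vo2 = np.asarray(vo2, dtype=float)
    if np.any(vo2 <= 0):
        raise ValueError("vo2 must be strictly positive (ml/min)")
    if subject is not None:
        mass, height, male, age = subject.mass, subject.height, subject.is_male, subject.age
    mass = np.asarray(mass, dtype=float)
    if scaler == "mass":
        out = vo2 / mass
        if met_display:
            out = out / constants.met_ml_per_kg
    elif scaler == "mass_0p7":
        if met_display:
            raise ValueError("MET display is defined only for the mass and ebm scalers")
        out = vo2 / mass**constants.mass_allometry_comparator_exp
    elif scaler == "ebm":
        out = vo2 / ebm_allometric(mass, height, male, age, constants)
        if met_display:
            out = out / constants.ebm_met_constant
    else:
        raise ValueError(f"scaler must be 'mass', 'mass_0p7' or 'ebm', got {scaler!r}")
    return _maybe_scalar(out)


def lbm_equivalent(ebm, constants: ScalingConstants = DEFAULT_CONSTANTS):
    """Predicted LBM^0.9 (allometrically scaled lean body mass) from EBM."""
    ebm = np.asarray(ebm, dtype=float)
    if np.any(ebm <= 0):
        raise ValueError("ebm must be strictly positive")
    return _maybe_scalar(constants.lbm_slope * ebm)


def bcm_scale(ebm, constants: ScalingConstants = DEFAULT_CONSTANTS):
    """EBM^1.11 — EBM re-expressed on a non-allometric, body-cell-mass-like scale."""
    ebm = np.asarray(ebm, dtype=float)
    if np.any(ebm <= 0):
        raise ValueError("ebm must be strictly positive")
    return _maybe_scalar(ebm**constants.bcm_power)


def mph_to_m_per_min(speed_mph, constants: ScalingConstants = DEFAULT_CONSTANTS):
    """Miles per hour to metres per minute (exact factor 26.8224)."""
    sp = np.asarray(speed_mph, dtype=float)
    if np.any(sp < 0):
        raise ValueError("speed must be >= 0")
    return _maybe_scalar(sp * constants.mph_to_m_per_min)


def m_per_min_to_mph(speed_m_per_min, constants: ScalingConstants = DEFAULT_CONSTANTS):
    """Metres per minute to miles per hour."""
    sp = np.asarray(speed_m_per_min, dtype=float)
    if np.any(sp < 0):
        raise ValueError("speed must be >= 0")
    return _maybe_scalar(sp / constants.mph_to_m_per_min)


def vo2_to_mets(vo2, mass=1.0, constants: ScalingConstants = DEFAULT_CONSTANTS):
    """Convert VO2 to METs: vo2 / (3.5 · mass).

    Pass absolute VO2 (ml/min) with mass in kg, or per-kg VO2
    (ml·kg⁻¹·min⁻¹) with the default ``mass=1``.
    """
    vo2 = np.asarray(vo2, dtype=float)
    mass = np.asarray(mass, dtype=float)
    if np.any(vo2 < 0):
        raise ValueError("vo2 must be >= 0")
    if np.any(mass <= 0):
        raise ValueError("mass must be > 0")
    return _maybe_scalar(vo2 / (constants.met_ml_per_kg * mass))
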