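"""Validity framework: size independence, calibration, contrasts, HF slopes.

A scaling metric is body-size independent when the indexed value
(VO2peak/metric) shows no residual correlation with the metric itself.
Because VO2peak also depends on exercise intensity, independence is
tested within workload bins, separately per sex.

Calibration of a prediction equation is summarised by the
through-origin least-squares slope of measured on predicted VO2peak
(slope 1 = unbiased; < 1 = measured below prediction), reported per
sex × age-band × BMI-band subgroup.  The mean of per-subject ratios is
reported alongside as a secondary estimator.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import add_derived_columns, as_frame
from .constants import DEFAULT_CONSTANTS, ScalingConstants
from .equations import workload_kokkinos

__all__ = [
    "MEN_WL_EDGES",
    "WOMEN_WL_EDGES",
    "through_origin_slope",
    "cohens_d",
    "size_independence",
    "CalibrationReport",
    "calibration_slopes",
    "subgroup_contrasts",
    "hf_slope_analysis",
    "compare_workload_formulas",
]

# Workload bin edges (METs) used for per-sex independence testing; the
# first bin is open below the first edge, the last open above the last.
MEN_WL_EDGES: tuple[float, ...] = (7.0, 8.0, 9.0, 10.0, 11.0, 12.0, 13.0, 14.0, 15.0)
WOMEN_WL_EDGES: tuple[float, ...] = (6.0, 7.0, 8.0, 9.0, 10.0, 11.0, 12.0)


def through_origin_slope(x, y) -> float:
    """Least-squares slope of y on x with intercept fixed at zero: Σxy/Σx²."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    sxx = float(np.sum(x * x))
    if sxx == 0:
        raise ValueError("through-origin slope undefined: sum of x² is zero")
    return float(np.sum(x * y) / sxx)


def _slope_ci(x, y, level: float = 0.95) -> tuple[float, float, float]:
    """Through-origin slope with its SE and symmetric CI half-width."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    b = through_origin_slope(x, y)
    n = len(x)
    if n < 2:
        return b, float("nan"), float("nan")
    resid = y - b * x
    s2 = float(np.sum(resid**2) / (n - 1))
    se = float(np.sqrt(s2 / np.sum(x * x)))
    half = float(stats.t.ppf(0.5 + level / 2, n - 1) * se)
    return b, se, half


def cohens_d(a, b) -> float:
    """Cohen's D with pooled SD; NaN when the pooled variance is zero."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = len(a), len(b)
    if na < 2 or nb < 2:
        raise ValueError("each group needs at least 2 observations")
    pooled = np.sqrt(
        ((na - 1) * np.var(a, ddof=1) + (nb - 1) * np.var(b, ddof=1)) / (na + nb - 2)
    )
    if pooled == 0:
        return float("nan")
    return float((np.mean(a) - np.mean(b)) / pooled)


def _bin_labels(edges: Sequence[float]) -> list[str]:
    labels = [f"<{edges[0]:g}"]
    for lo, hi in zip(edges[:-1], edges[1:]):
        labels.append(f"{lo:g}-{hi - 0.1:g}")
    labels.append(f">={edges[-1]:g}")
    return labels


def _assign_bins(wl: np.ndarray, edges: Sequence[float]) -> np.ndarray:
    return np.searchsorted(np.asarray(edges, dtype=float), wl, side="right")


def size_independence(
    cohort,
    scaler: Literal["mass", "mass_0p7", "ebm"] = "mass",
    bins: dict[str, Sequence[float]] | None = None,
    constants: ScalingConstants = DEFAULT_CONSTANTS,
    alpha: float = 0.01,
) -> pd.DataFrame:
    """Within-bin correlation of indexed VO2peak with its size metric.

    For each sex × workload bin, the Pearson r (with its exact
    two-sided t-transform p at n−2 df) between VO2peak/scaler and the
    scaler.  Bins are left-closed MET intervals of the HRR-aware
    workload; ``bins`` may override the per-sex edges.  A metric scales
    independently when no bin is significant at ``alpha`` (0.01 by
    convention, a display threshold absorbing multiple comparisons).
    Bins with fewer than 3 records or zero variance report r as NaN.
    """
    df = add_derived_columns(as_frame(cohort), constants)
    if scaler == "mass":
        metric = df["mass_kg"].to_numpy(dtype=float)
    elif scaler == "mass_0p7":
        metric = df["mass_kg"].to_numpy(dtype=float) ** constants.mass_allometry_comparator_exp
    elif scaler == "ebm":
        metric = df["ebm"].to_numpy(dtype=float)
    else:
        raise ValueError(f"scaler must be 'mass', 'mass_0p7' or 'ebm', got {scaler!r}")
    indexed = df["vo2peak_ml_min"].to_numpy(dtype=float) / metric
    edges_by_sex = {"male": MEN_WL_EDGES, "female": WOMEN_WL_EDGES}
    if bins:
        edges_by_sex.update(bins)
    rows = []
    for sex in ("male", "female"):
        mask = (df["sex"] == sex).to_numpy()
        if not mask.any():
            continue
        edges = edges_by_sex[sex]
        labels = _bin_labels(edges)
        idx = _assign_bins(df.loc[mask, "wl_mets"].to_numpy(dtype=float), edges)
        for b, label in enumerate(labels):
            sel = mask.copy()
            sel[mask] = idx == b
            n = int(sel.sum())
            r = p = float("nan")
            if n < 3:
                warnings.warn(
                    f"bin {label!r} ({sex}) has n={n} < 3; correlation undefined",
                    stacklevel=2,
                )
            elif (
                np.std(metric[sel]) <= 1e-12 * abs(np.mean(metric[sel]))
                or np.std(indexed[sel]) <= 1e-12 * abs(np.mean(indexed[sel]))
            ):
                warnings.warn(
                    f"bin {label!r} ({sex}) has zero variance; correlation undefined",
                    stacklevel=2,
                )
            else:
                r_, p_ = stats.pearsonr(indexed[sel], metric[sel])
                r, p = float(r_), float(p_)
            rows.append(
                {
                    "sex": sex,
                    "wl_bin": label,
                    "n": n,
                    "r": r,
                    "p": p,
                    "significant": bool(p < alpha) if np.isfinite(p) else False,
                }
            )
    out = pd.DataFrame(rows)
    out.attrs["scaler"] = scaler
    out.attrs["alpha"] = alpha
    return out


@dataclasses.dataclass
class CalibrationReport:
    """Per-subgroup calibration slopes of measured on predicted VO2peak."""

    model: str
    table: pd.DataFrame  # sex, age_band, bmi_band, n, slope, slope_se, ci_low, ci_high, mean_ratio
    overall_slope: float
    overall_r: float
    n: int

    def worst_cell(self) -> pd.Series:
        i = (self.table["slope"] - 1.0).abs().idxmax()
        return self.table.loc[i]


def _band(values: np.ndarray, cuts: tuple[float, float]) -> np.ndarray:
    lo, hi = cuts
    labels = np.where(
        values < lo, f"<{lo:g}", np.where(values > hi, f">{hi:g}", f"{lo:g}-{hi:g}")
    )
    return labels


def _predicted(df: pd.DataFrame, model: str, constants: ScalingConstants) -> np.ndarray:
    if model == "ebm_generalized":
        return constants.ebm_met_constant * df["ebm"].to_numpy() * df["wl_mets"].to_numpy()
    if model == "mass_standard":
        wl = workload_kokkinos(
            df["speed_mph"].to_numpy() * constants.mph_to_m_per_min,
            df["grade_frac"].to_numpy(),
            constants,
        )
        return constants.met_ml_per_kg * df["mass_kg"].to_numpy() * wl
    raise ValueError(f"model must be 'ebm_generalized' or 'mass_standard', got {model!r}")


def calibration_slopes(
    cohort,
    model: Literal["ebm_generalized", "mass_standard"] = "ebm_generalized",
    age_bands: tuple[float, float] = (40.0, 60.0),
    bmi_bands: tuple[float, float] = (25.0, 30.0),
    constants: ScalingConstants = DEFAULT_CONSTANTS,
) -> CalibrationReport:
    """Calibration slope per sex × age-band × BMI-band subgroup.

    The headline estimator is the through-origin regression slope of
    measured on predicted VO2peak; ``mean_ratio`` (mean of per-subject
    measured/predicted) is reported alongside.  Empty subgroups are
    omitted with a warning.  The overall slope and Pearson correlation
    over the whole cohort are also returned.
    """
    df = add_derived_columns(as_frame(cohort), constants)
    predicted = _predicted(df, model, constants)
    measured = df["vo2peak_ml_min"].to_numpy(dtype=float)
    age_band = _band(df["age"].to_numpy(dtype=float), age_bands)
    bmi_band = _band(df["bmi"].to_numpy(dtype=float), bmi_bands)
    rows = []
    for sex in ("male", "female"):
        for ab in (f"<{age_bands[0]:g}", f"{age_bands[0]:g}-{age_bands[1]:g}", f">{age_bands[1]:g}"):
            for bb in (
                f"<{bmi_bands[0]:g}", f"{bmi_bands[0]:g}-{bmi_bands[1]:g}", f">{bmi_bands[1]:g}"
            ):
                sel = (df["sex"] == sex).to_numpy() & (age_band == ab) & (bmi_band == bb)
                n = int(sel.sum())
                if n == 0:
                    warnings.warn(
                        f"empty calibration subgroup {sex}/{ab}/{bb}; omitted", stacklevel=2
                    )
                    continue
                b, se, half = _slope_ci(predicted[sel], measured[sel])
                rows.append(
                    {
                        "sex": sex,
                        "age_band": ab,
                        "bmi_band": bb,
                        "n": n,
                        "slope": b,
                        "slope_se": se,
                        "ci_low": b - half,
                        "ci_high": b + half,
                        "mean_ratio": float(np.mean(measured[sel] / predicted[sel])),
                    }
                )
    overall = through_origin_slope(predicted, measured)
    r = float(stats.pearsonr(predicted, measured)[0]) if len(df) > 2 else float("nan")
    return CalibrationReport(
        model=model,
        table=pd.DataFrame(rows),
        overall_slope=overall,
        overall_r=r,
        n=len(df),
    )


_CONTRASTS = (
    ("men_vs_women_bmi_lt_25", "sex == 'male' and bmi < 25", "sex == 'female' and bmi < 25"),
    ("normal_vs_obese", "bmi < 25", "bmi > 30"),
    ("younger_vs_older", "age < 40", "age > 60"),
)


def subgroup_contrasts(
    cohort,
    standards: Sequence[Literal["mass", "ebm"]] = ("mass", "ebm"),
    constants: ScalingConstants = DEFAULT_CONSTANTS,
) -> pd.DataFrame:
    """Relative mean ratios and Cohen's D between canonical subgroups.

    Compares MET-standardised indexed VO2peak — VO2/(3.5·mass) for the
    total-mass standard, VO2/(11·EBM) for the EBM standard — between
    men and women at BMI < 25, normal-weight and obese, and younger and
    older subjects.  The ratio is group A mean over group B mean ×100%.
    """
    df = add_derived_columns(as_frame(cohort), constants)
    vo2 = df["vo2peak_ml_min"].to_numpy(dtype=float)
    values = {
        "mass": vo2 / (constants.met_ml_per_kg * df["mass_kg"].to_numpy()),
        "ebm": vo2 / (constants.ebm_met_constant * df["ebm"].to_numpy()),
    }
    rows = []
    for name, qa, qb in _CONTRASTS:
        mask_a = df.eval(qa).to_numpy()
        mask_b = df.eval(qb).to_numpy()
        if not mask_a.any() or not mask_b.any():
            raise ValueError(f"contrast {name!r}: both groups must be non-empty")
        for std in standards:
            a, b = values[std][mask_a], values[std][mask_b]
            rows.append(
                {
                    "contrast": name,
                    "standard": std,
                    "n_a": int(mask_a.sum()),
                    "n_b": int(mask_b.sum()),
                    "mean_a": float(np.mean(a)),
                    "mean_b": float(np.mean(b)),
                    "ratio_pct": float(np.mean(a) / np.mean(b) * 100.0),
                    "cohens_d": cohens_d(a, b),
                }
            )
    return pd.DataFrame(rows)


def hf_slope_analysis(
    healthy,
    hf,
    model: Literal["ebm_generalized", "mass_standard"] = "ebm_generalized",
    constants: ScalingConstants = DEFAULT_CONSTANTS,
    **kwargs,
) -> dict:
    """Compare calibration slopes of a heart-failure cohort to healthy.

    In HF, measured VO2peak typically falls below the workload-based
    prediction (anaerobic reliance, sarcopenia, fluid overload), giving
    an overall slope < 1.  Returns both reports, the HF/healthy slope
    ratio and a flag marking whether the HF slope is indeed lower.
    """
    healthy_report = calibration_slopes(healthy, model, constants=constants, **kwargs)
    hf_report = calibration_slopes(hf, model, constants=constants, **kwargs)
    ratio = hf_report.overall_slope / healthy_report.overall_slope
    return {
        "healthy": healthy_report,
        "hf": hf_report,
        "slope_ratio": float(ratio),
        "hf_slope_lower": bool(hf_report.overall_slope < healthy_report.overall_slope),
    }


def compare_workload_formulas(
    cohort,
    constants: ScalingConstants = DEFAULT_CONSTANTS,
    n_bins: int = 10,
) -> dict:
    """Relate the HRR-aware workload to the comparator speed/grade formula.

    Returns the through-origin slope of the comparator workload on the
    HRR-aware workload, a per-decile mean-difference profile, and a
    direction flag checking that the HRR-aware estimate exceeds the
    comparator at the low-workload end (slow walking is less efficient
    than the comparator's single resting term implies).  Both workloads
    are mass-free, so the slope is invariant to anthropometrics.
    """
    df = add_derived_columns(as_frame(cohort), constants)
    wl_ebm = df["wl_mets"].to_numpy(dtype=float)
    wl_kok = workload_kokkinos(
        df["speed_mph"].to_numpy() * constants.mph_to_m_per_min,
        df["grade_frac"].to_numpy(),
        constants,
    )
    slope = through_origin_slope(wl_ebm, wl_kok)
    q = np.quantile(wl_ebm, np.linspace(0, 1, n_bins + 1))
    idx = np.clip(np.searchsorted(q[1:-1], wl_ebm, side="right"), 0, n_bins - 1)
    prof = pd.DataFrame(
        {
            "decile": np.arange(1, n_bins + 1),
            "n": [int((idx == i).sum()) for i in range(n_bins)],
            "mean_wl_ebm": [float(np.mean(wl_ebm[idx == i])) for i in range(n_bins)],
            "mean_diff_ebm_minus_kokkinos": [
                float(np.mean(wl_ebm[idx == i] - wl_kok[idx == i])) for i in range(n_bins)
            ],
        }
    )
    return {
        "slope_kokkinos_on_ebm": slope,
        "difference_profile": prof,
        "ebm_higher_at_low_wl": bool(prof["mean_diff_ebm_minus_kokkinos"].iloc[0] > 0),
    }
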