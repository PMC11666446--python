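"""Model-fitting procedures that derive the scaling and workload equations.

The scaling metric comes from a multiplicative (log-normal) model:
ln VO2peak is regressed on ln(mass), ln(height), a male indicator,
fractional-age terms (fAge = age/100: fAge, fAge², fAge³) and the
exercise covariates, with sequential backward elimination of terms at
p > 0.05.  Exponentiating the retained body-size terms yields the
multiplicative expression Mass^a · Height^b · e^c(male) · exp(d · fAge²).

Exercise covariates can enter in two ways:

``exercise_terms="raw"``
    speed, grade and HRR enter linearly on the log scale — the
    published derivation procedure.  This is an approximation, since
    the workload acts multiplicatively, not log-linearly.
``exercise_terms="log_workload"``
    ln WL enters as a single regressor.  Under the simulator's
    generative model this is exactly identified, so it is the mode used
    for parameter-recovery validation.

The workload equation itself is derived on the MET scale by regressing
VO2peak/(Cst · EBM) on speed, speed·grade and HRR.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Any, Literal, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .cohort import as_frame
from .constants import DEFAULT_CONSTANTS, ScalingConstants
from .equations import ebm_allometric, workload_ebm

__all__ = [
    "FitResult",
    "AdditiveFit",
    "fit_ebm_model",
    "fit_additive_approximation",
    "fit_workload_equation",
    "recompute_met_constant",
]


@dataclasses.dataclass
class FitResult:
    """Outcome of one derivation regression.

    ``removed`` lists eliminated terms in elimination order with their
    exit p-values; ``extra`` carries model-specific products such as the
    multiplicative EBM expression.
    """

    model: str
    n: int
    params: dict[str, float]
    bse: dict[str, float]
    pvalues: dict[str, float]
    removed: list[tuple[str, float]]
    r_squared: float
    resid_mean: float
    resid_sd: float
    resid_normality_stat: float
    resid_normality_p: float
    extra: dict[str, Any] = dataclasses.field(default_factory=dict)

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["removed"] = [[t, p] for t, p in self.removed]
        return d

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(json.dumps(self.to_dict(), indent=2, default=float))
        return path

    def __str__(self) -> str:
        lines = [f"{self.model} fit  (n={self.n}, R²={self.r_squared:.4f})"]
        lines.append(f"{'term':<12}{'coef':>12}{'se':>12}{'p':>12}")
        for name, coef in self.params.items():
            lines.append(
                f"{name:<12}{coef:>12.5g}{self.bse[name]:>12.3g}{self.pvalues[name]:>12.3g}"
            )
        if self.removed:
            removed = ", ".join(f"{t} (p={p:.3g})" for t, p in self.removed)
            lines.append(f"eliminated: {removed}")
        lines.append(
            f"residuals: mean={self.resid_mean:.3g} sd={self.resid_sd:.3g} "
            f"normality p={self.resid_normality_p:.3g}"
        )
        for key, val in self.extra.items():
            lines.append(f"{key}: {val}")
        return "\n".join(lines)


def _check_rank(X: pd.DataFrame) -> None:
    arr = X.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(arr)
    if rank < arr.shape[1]:
        # name the columns loading on the null space to aid debugging
        _, s, vt = np.linalg.svd(arr, full_matrices=False)
        null = vt[np.isclose(s, 0, atol=s.max() * 1e-10)]
        names = set()
        for vec in null:
            names.update(X.columns[np.abs(vec) > 0.1])
        raise ValueError(
            f"design matrix is rank deficient (rank {rank} < {arr.shape[1]}); "
            f"collinear terms likely include: {sorted(names)}"
        )


def _backward_eliminate(
    y: np.ndarray,
    X: pd.DataFrame,
    p_remove: float,
    weights: np.ndarray | None = None,
):
    """Sequential backward elimination: drop the single worst term with
    p > p_remove each iteration (ties: larger p, then term name).

    The intercept is never a removal candidate.  Degenerate p-values
    from a perfect fit are treated as 0 (term kept)."""
    cols = list(X.columns)
    removed: list[tuple[str, float]] = []
    while True:
        exog = X[cols]
        model = sm.OLS(y, exog) if weights is None else sm.WLS(y, exog, weights=weights)
        res = model.fit()
        pv = res.pvalues.drop("const", errors="ignore").fillna(0.0)
        candidates = pv[pv > p_remove]
        if candidates.empty:
            return res, cols, removed
        worst_name, worst_p = sorted(candidates.items(), key=lambda kv: (-kv[1], kv[0]))[0]
        cols.remove(worst_name)
        removed.append((worst_name, float(worst_p)))


def _resid_summary(resid: np.ndarray) -> tuple[float, float, float, float]:
    if len(resid) >= 20 and np.std(resid) > 0:
        stat, p = stats.normaltest(resid)
    else:
        stat, p = float("nan"), float("nan")
    return float(np.mean(resid)), float(np.std(resid, ddof=1)), float(stat), float(p)


def _sex_interaction_test(y, X: pd.DataFrame, cols: Sequence[str], weights=None) -> float:
    """Nested F-test of a full male-by-covariate interaction model
    against the common (pooled) model.  Returns the p-value, or NaN if
    the interaction design is degenerate."""
    if "male" not in X.columns:
        return float("nan")
    base = X[list(cols)]
    inter = base.copy()
    for c in cols:
        if c in ("const", "male"):
            continue
        inter[f"male:{c}"] = X["male"] * X[c]
    if inter.shape[1] == base.shape[1]:
        return float("nan")
    try:
        fit = lambda exog: (  # noqa: E731
            sm.OLS(y, exog) if weights is None else sm.WLS(y, exog, weights=weights)
        ).fit()
        full, restricted = fit(inter), fit(base)
        _, p, _ = full.compare_f_test(restricted)
        return float(p)
    except Exception:
        return float("nan")


def fit_ebm_model(
    cohort,
    p_remove: float = 0.05,
    exercise_terms: Literal["raw", "log_workload"] = "raw",
    constants: ScalingConstants = DEFAULT_CONSTANTS,
    weights: np.ndarray | None = None,
) -> FitResult:
    """Derive the multiplicative body-size (EBM) model from a cohort.

    Regresses ln(VO2peak) on ln(mass), ln(height), male, fAge, fAge²,
    fAge³ and the exercise covariates, eliminating terms backwards at
    ``p_remove``.  The multiplicative expression in ``extra`` folds the
    retained ln-mass, ln-height, male and fAge² coefficients into
    Mass^a · Height^b · e^c(male) · exp(d·fAge²); any retained fAge or
    fAge³ terms are reported but not folded into the canonical form.
    A pooled-vs-sex-interaction F-test p-value is also reported.
    """
    df = as_frame(cohort)
    n = len(df)
    fage = df["age"].to_numpy() / 100.0
    X = pd.DataFrame(
        {
            "const": np.ones(n),
            "ln_mass": np.log(df["mass_kg"].to_numpy(dtype=float)),
            "ln_height": np.log(df["height_m"].to_numpy(dtype=float)),
            "male": (df["sex"] == "male").to_numpy(dtype=float),
            "fage": fage,
            "fage2": fage**2,
            "fage3": fage**3,
        }
    )
    if exercise_terms == "raw":
        X["speed"] = df["speed_mph"].to_numpy(dtype=float)
        X["grade"] = df["grade_frac"].to_numpy(dtype=float)
        X["hrr"] = df["hrr"].to_numpy(dtype=float)
    elif exercise_terms == "log_workload":
        X["ln_wl"] = np.log(
            workload_ebm(
                df["speed_mph"].to_numpy(), df["grade_frac"].to_numpy(),
                df["hrr"].to_numpy(), constants,
            )
        )
    else:
        raise ValueError(f"exercise_terms must be 'raw' or 'log_workload', got {exercise_terms!r}")
    if n <= X.shape[1]:
        raise ValueError(f"need more records ({n}) than model terms ({X.shape[1]})")
    y = np.log(df["vo2peak_ml_min"].to_numpy(dtype=float))
    _check_rank(X)
    res, cols, removed = _backward_eliminate(y, X, p_remove, weights)
    params = {c: float(res.params[c]) for c in cols}
    mult = {
        "mass_exp": params.get("ln_mass", 0.0),
        "height_exp": params.get("ln_height", 0.0),
        "male_factor": float(np.exp(params.get("male", 0.0))),
        "age_coef": params.get("fage2", 0.0),
    }
    rm, rsd, nstat, np_ = _resid_summary(np.asarray(res.resid))
    return FitResult(
        model="ebm_loglinear",
        n=n,
        params=params,
        bse={c: float(res.bse[c]) for c in cols},
        pvalues={c: float(res.pvalues[c]) for c in cols},
        removed=removed,
        r_squared=float(res.rsquared),
        resid_mean=rm,
        resid_sd=rsd,
        resid_normality_stat=nstat,
        resid_normality_p=np_,
        extra={
            "multiplicative": mult,
            "exercise_terms": exercise_terms,
            "sex_interaction_p": _sex_interaction_test(y, X, cols, weights),
        },
    )


@dataclasses.dataclass
class AdditiveFit:
    """Per-sex linear approximation EBM ≈ b0 + b1·mass + b2·height + b3·age."""

    sex: str
    coefficients: tuple[float, float, float, float]
    r_squared: float
    n: int
    valid: bool


def fit_additive_approximation(
    cohort=None,
    ebm: np.ndarray | None = None,
    constants: ScalingConstants = DEFAULT_CONSTANTS,
    weights: np.ndarray | None = None,
    r2_threshold: float = 0.99,
) -> dict[str, AdditiveFit]:
    """Fit the sex-specific additive approximations to allometric EBM.

    ``cohort`` needs mass_kg, height_m, age, sex columns (a dense
    anthropometric grid works as well as a cohort).  ``ebm`` defaults to
    the allometric EBM computed with ``constants``.  The ``valid`` flag
    marks fits whose R² reaches ``r2_threshold`` ("close to unity").
    """
    df = as_frame(cohort)
    if ebm is None:
        ebm = ebm_allometric(
            df["mass_kg"].to_numpy(), df["height_m"].to_numpy(), df["sex"].to_numpy(),
            df["age"].to_numpy(), constants,
        )
    ebm = np.asarray(ebm, dtype=float)
    out: dict[str, AdditiveFit] = {}
    for sex in ("male", "female"):
        mask = (df["sex"] == sex).to_numpy()
        if mask.sum() < 4:
            raise ValueError(
                f"need at least 4 {sex} records to fit the additive form, got {int(mask.sum())}"
            )
        X = sm.add_constant(
            df.loc[mask, ["mass_kg", "height_m", "age"]].to_numpy(dtype=float)
        )
        y = ebm[mask]
        w = None if weights is None else np.asarray(weights)[mask]
        res = (sm.OLS(y, X) if w is None else sm.WLS(y, X, weights=w)).fit()
        out[sex] = AdditiveFit(
            sex=sex,
            coefficients=tuple(float(b) for b in res.params),
            r_squared=float(res.rsquared),
            n=int(mask.sum()),
            valid=bool(res.rsquared >= r2_threshold),
        )
    return out


_WL_TERMS = ("speed", "speed_grade", "hrr")


def fit_workload_equation(
    cohort,
    met_constant: float | None = None,
    constants: ScalingConstants = DEFAULT_CONSTANTS,
    terms: Sequence[str] = _WL_TERMS,
    p_remove: float | None = None,
) -> FitResult:
    """Derive the workload equation on the MET scale.

    Regresses VO2peak/(met_constant · EBM) on the horizontal (speed) and
    vertical (speed·grade) external components and the internal HRR
    component, with intercept.  ``terms`` selects the covariates (e.g.
    drop "hrr" for a nested comparison); ``p_remove`` optionally enables
    backward elimination.
    """
    df = as_frame(cohort)
    n = len(df)
    if met_constant is None:
        met_constant = constants.ebm_met_constant
    ebm = ebm_allometric(
        df["mass_kg"].to_numpy(), df["height_m"].to_numpy(), df["sex"].to_numpy(),
        df["age"].to_numpy(), constants,
    )
    y = df["vo2peak_ml_min"].to_numpy(dtype=float) / (met_constant * ebm)
    unknown = set(terms) - set(_WL_TERMS)
    if unknown:
        raise ValueError(f"unknown workload term(s) {sorted(unknown)}; valid: {_WL_TERMS}")
    X = pd.DataFrame({"const": np.ones(n)})
    sp = df["speed_mph"].to_numpy(dtype=float)
    if "speed" in terms:
        X["speed"] = sp
    if "speed_grade" in terms:
        X["speed_grade"] = sp * df["grade_frac"].to_numpy(dtype=float)
    if "hrr" in terms:
        X["hrr"] = df["hrr"].to_numpy(dtype=float)
    if n <= X.shape[1]:
        raise ValueError(f"need more records ({n}) than model terms ({X.shape[1]})")
    _check_rank(X)
    if p_remove is None:
        res, cols, removed = sm.OLS(y, X).fit(), list(X.columns), []
    else:
        res, cols, removed = _backward_eliminate(y, X, p_remove)
    rm, rsd, nstat, np_ = _resid_summary(np.asarray(res.resid))
    return FitResult(
        model="workload_mets",
        n=n,
        params={c: float(res.params[c]) for c in cols},
        bse={c: float(res.bse[c]) for c in cols},
        pvalues={c: float(res.pvalues[c]) for c in cols},
        removed=removed,
        r_squared=float(res.rsquared),
        resid_mean=rm,
        resid_sd=rsd,
        resid_normality_stat=nstat,
        resid_normality_p=np_,
        extra={"met_constant": float(met_constant), "terms": list(terms)},
    )


def recompute_met_constant(
    constants: ScalingConstants = DEFAULT_CONSTANTS,
    mass: float = 76.6,
    height: float = 1.75,
    age: float = 20.0,
    male: bool = True,
) -> int:
    """Re-derive the integer MET constant of the generalized equation.

    For the reference man (height 1.75 m, BMI 25 → 76.6 kg, age 20) one
    MET costs 3.5 · mass ml/min; dividing by his EBM and rounding to the
    nearest integer gives the constant (11 with published coefficients).
    """
    ebm = ebm_allometric(mass, height, male, age, constants)
    return int(round(constants.met_ml_per_kg * mass / ebm))
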