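"""Published coefficients of the EBM, workload and comparator equations.

All numeric defaults are the printed coefficients of the generalized
VO2peak equation and its companions.  They are held in a single frozen
dataclass so that refit experiments can swap any of them without editing
code: ``ScalingConstants()`` gives the published set, ``.replace(...)``
or :meth:`ScalingConstants.from_file` gives an overridden set.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Any, Mapping

import yaml

__all__ = ["ScalingConstants", "DEFAULT_CONSTANTS"]


@dataclasses.dataclass(frozen=True)
class ScalingConstants:
    """Immutable bundle of every scaling coefficient used by the package.

    Attributes
    ----------
    met_ml_per_kg
        Oxygen cost of one MET per kg of total body mass
        (ml O2 · kg⁻¹ · min⁻¹).
    ebm_met_constant
        Oxygen cost of one MET per EBM unit (ml O2 · min⁻¹), the rounded
        constant of the generalized equation.
    mass_exp, height_exp
        Allometric exponents of mass (kg) and height (m) in EBM.
    male_factor
        Multiplicative sex factor applied for men.
    age_coef
        Coefficient applied to the squared fractional age (age/100)².
    additive_male, additive_female
        (intercept, mass, height, age) coefficients of the sex-specific
        additive approximations to EBM; age in years.
    wl_intercept, wl_speed, wl_speed_grade, wl_hrr
        Terms of the workload equation
        WL = intercept + Sp·(wl_speed + wl_speed_grade·fGr) + wl_hrr·HRR,
        speed in mph, grade fractional, HRR in bpm.
    kokkinos
        (speed, speed·grade, resting) coefficients of the comparator
        treadmill equation in ml·kg⁻¹·min⁻¹ with speed in m·min⁻¹.
    mph_to_m_per_min
        Exact unit conversion factor.
    lbm_slope, lbm_exp
        Through-origin relation LBM^lbm_exp = lbm_slope · EBM against
        DXA lean body mass.
    bcm_power
        Power (1/lbm_exp) used to display EBM on a body-cell-mass-like
        non-allometric scale.
    mass_allometry_comparator_exp
        Exponent of the simple mass-allometry comparator Mass^0.7.
    """

    met_ml_per_kg: float = 3.5
    ebm_met_constant: float = 11.0
    mass_exp: float = 0.63
    height_exp: float = 0.53
    male_factor: float = 1.16
    age_coef: float = -0.39
    additive_male: tuple[float, float, float, float] = (-0.58, 0.18, 7.20, -0.08)
    additive_female: tuple[float, float, float, float] = (-0.26, 0.16, 5.63, -0.06)
    wl_intercept: float = 2.0
    wl_speed: float = 1.06
    wl_speed_grade: float = 5.22
    wl_hrr: float = 0.019
    kokkinos: tuple[float, float, float] = (0.17, 0.79, 3.5)
    mph_to_m_per_min: float = 26.8224
    lbm_slope: float = 1.61
    lbm_exp: float = 0.9
    bcm_power: float = 1.11
    mass_allometry_comparator_exp: float = 0.7

    def replace(self, **overrides: Any) -> "ScalingConstants":
        """Return a copy with the given fields overridden.

        Unknown field names raise ``ValueError`` rather than being
        silently ignored.
        """
        known = {f.name for f in dataclasses.fields(self)}
        unknown = set(overrides) - known
        if unknown:
            raise ValueError(
                f"unknown scaling constant(s): {sorted(unknown)}; "
                f"valid names are {sorted(known)}"
            )
        coerced = {
            k: tuple(v) if isinstance(v, list) else v for k, v in overrides.items()
        }
        return dataclasses.replace(self, **coerced)

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, Any]) -> "ScalingConstants":
        return cls().replace(**dict(mapping))

    @classmethod
    def from_file(cls, path: str | Path) -> "ScalingConstants":
        """Load overrides from a flat YAML or JSON key-value file."""
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        if data is None:
            return cls()
        if not isinstance(data, Mapping):
            raise ValueError(f"{path}: expected a flat key-value mapping")
        return cls.from_mapping(data)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)


DEFAULT_CONSTANTS = ScalingConstants()
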