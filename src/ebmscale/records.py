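"""Per-subject record types: anthropometrics and peak treadmill test state."""

from __future__ import annotations

import dataclasses
import math

__all__ = ["Subject", "ExerciseTest", "DomainWarning"]

_SEXES = ("male", "female")


class DomainWarning(UserWarning):
    """Emitted when a formula is evaluated outside its sensible domain."""


@dataclasses.dataclass(frozen=True)
class Subject:
    """One individual's anthropometrics and demographics.

    Parameters
    ----------
    mass : float
        Total body mass in kilograms, > 0.
    height : float
        Standing height in metres, > 0.  Values above 3 m are rejected
        because they almost always mean centimetres were passed.
    sex : str
        ``"male"`` or ``"female"`` (case-insensitive).
    age : float
        Age in years, >= 0.
    """

    mass: float
    height: float
    sex: str
    age: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "sex", str(self.sex).strip().lower())
        if self.sex not in _SEXES:
            raise ValueError(f"sex must be one of {_SEXES}, got {self.sex!r}")
        if not (self.mass > 0 and math.isfinite(self.mass)):
            raise ValueError(f"mass must be a positive finite number, got {self.mass}")
        if not (self.height > 0 and math.isfinite(self.height)):
            raise ValueError(f"height must be a positive finite number, got {self.height}")
        if self.height > 3:
            raise ValueError(
                f"height {self.height} m is implausible; if the value is in "
                "centimetres divide by 100"
            )
        if not (self.age >= 0 and math.isfinite(self.age)):
            raise ValueError(f"age must be >= 0, got {self.age}")

    @property
    def is_male(self) -> bool:
        return self.sex == "male"

    @property
    def bmi(self) -> float:
        """Body mass index, kg · m⁻²."""
        return self.mass / self.height**2


@dataclasses.dataclass(frozen=True)
class ExerciseTest:
    """Peak treadmill state of one cardiopulmonary exercise test.

    Parameters
    ----------
    speed : float
        Peak treadmill speed in miles per hour, >= 0.
    fractional_grade : float
        Treadmill incline as a fraction (0.11 for 11%), in [0, 1].
    hrr : float
        Heart-rate reserve (peak minus resting heart rate), bpm, >= 0.
    vo2peak_measured : float, optional
        Measured peak oxygen uptake in ml O2 · min⁻¹, > 0 when present.
    rer : float, optional
        Peak respiratory exchange ratio.
    """

    speed: float
    fractional_grade: float
    hrr: float
    vo2peak_measured: float | None = None
    rer: float | None = None

    def __post_init__(self) -> None:
        if self.speed < 0:
            raise ValueError(f"speed must be >= 0 mph, got {self.speed}")
        if not 0 <= self.fractional_grade <= 1:
            raise ValueError(
                f"fractional_grade must lie in [0, 1] (a fraction, not a "
                f"percentage), got {self.fractional_grade}"
            )
        if self.hrr < 0:
            raise ValueError(f"hrr must be >= 0 bpm, got {self.hrr}")
        if self.vo2peak_measured is not None and not self.vo2peak_measured > 0:
            raise ValueError(
                f"vo2peak_measured must be > 0 ml/min, got {self.vo2peak_measured}"
            )

    @classmethod
    def from_heart_rates(
        cls,
        speed: float,
        fractional_grade: float,
        hr_peak: float,
        hr_rest: float,
        **kwargs: float,
    ) -> "ExerciseTest":
        """Build a test record deriving HRR from peak and resting heart rate."""
        return cls(speed, fractional_grade, hr_peak - hr_rest, **kwargs)
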