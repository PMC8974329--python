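"""Sex- and birth-cohort-specific life tables.

A life table stores the survival function S(age) on an integer age grid
per (sex, birth-cohort) stratum.  Between grid ages S is interpolated
linearly in log S (piecewise-constant hazard, the standard actuarial
convention; exact for exponential segments).  Beyond the last grid age
the cumulative hazard H = -log S is extrapolated with a Gompertz tail
fitted to the last two grid points.  Parametric Gompertz tables,
S(t) = exp(-(a/b)(e^{bt} - 1)), are provided as test/simulation fixtures.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["LifeTable", "LifeTableError", "make_gompertz_table",
           "gompertz_survival", "load_lifetable"]

S_FLOOR = 1e-12


class LifeTableError(ValueError):
    pass


def gompertz_survival(age, a: float, b: float):
    """Closed-form Gompertz survival S(t) = exp(-(a/b)(e^{bt}-1))."""
    age = np.asarray(age, dtype=float)
    return np.exp(-(a / b) * np.expm1(b * age))


@dataclass
class _Stratum:
    sex: str
    cohort_start: int
    cohort_end: int
    ages: np.ndarray      # strictly increasing integer grid, ages[0] == 0
    survival: np.ndarray  # S(age), S(0) == 1, non-increasing

    def __post_init__(self) -> None:
        self.ages = np.asarray(self.ages, dtype=float)
        self.survival = np.asarray(self.survival, dtype=float)
        if self.ages.size < 2 or np.any(np.diff(self.ages) <= 0):
            raise LifeTableError("age grid must be strictly increasing, >=2 ages")
        if self.ages[0] != 0 or self.survival[0] != 1.0:
            raise LifeTableError("life table must start at S(0) = 1")
        if np.any(self.survival > 1) or np.any(self.survival < 0):
            raise LifeTableError("survival outside [0, 1]")
        if np.any(np.diff(self.survival) > 1e-12):
            raise LifeTableError("survival must be non-increasing in age")
        self._H = -np.log(np.clip(self.survival, S_FLOOR, 1.0))
        # Gompertz tail growth rate from the last two grid points
        h1, h0 = self._H[-1], self._H[-2]
        da = self.ages[-1] - self.ages[-2]
        if h1 > 0 and h0 > 0 and h1 > h0:
            self._tail_b = float(np.log(h1 / h0) / da)
        else:  # flat or degenerate tail: fall back to exponential hazard
            self._tail_b = 0.0

    def cumhaz(self, age):
        """H(age) = -log S(age); vectorized over age."""
        age = np.asarray(age, dtype=float)
        H = np.interp(age, self.ages, self._H)
        over = age > self.ages[-1]
        if np.any(over):
            h1 = self._H[-1]
            if self._tail_b > 0:
                Ht = h1 * np.exp(self._tail_b * (age - self.ages[-1]))
            else:
                rate = h1 / max(self.ages[-1], 1.0)
                Ht = h1 + rate * (age - self.ages[-1])
            H = np.where(over, Ht, H)
        return H

    def inv_cumhaz(self, H):
        """Age at which the cumulative hazard reaches H (inverse of cumhaz)."""
        H = np.asarray(H, dtype=float)
        age = np.interp(H, self._H, self.ages)
        h1 = self._H[-1]
        over = H > h1
        if np.any(over):
            if self._tail_b > 0:
                at = self.ages[-1] + np.log(np.maximum(H, h1) / h1) / self._tail_b
            else:
                rate = h1 / max(self.ages[-1], 1.0)
                at = self.ages[-1] + (H - h1) / rate
            age = np.where(over, at, age)
        return age


@dataclass
class LifeTable:
    strata: list[_Stratum]

    def stratum(self, sex: str, birth_year: int) -> _Stratum:
        cands = [s for s in self.strata if s.sex == sex]
        if not cands:
            raise LifeTableError(f"no life-table stratum for sex={sex!r}")
        inside = [s for s in cands
                  if s.cohort_start <= birth_year <= s.cohort_end]
        if inside:
            return inside[0]
        nearest = min(cands, key=lambda s: min(abs(birth_year - s.cohort_start),
                                               abs(birth_year - s.cohort_end)))
        warnings.warn(
            f"birth year {birth_year} outside table cohorts for sex={sex}; "
            f"using nearest stratum [{nearest.cohort_start}, {nearest.cohort_end}]",
            stacklevel=2)
        return nearest

    def survival_prob(self, sex: str, birth_year: int, age) -> float | np.ndarray:
        """S(age) with log-linear interpolation and Gompertz-tail extrapolation.

        Clamped to (1e-12, 1].
        """
        if np.any(np.asarray(age) < 0):
            raise LifeTableError(f"negative age: {age}")
        st = self.stratum(sex, birth_year)
        s = np.exp(-st.cumhaz(age))
        s = np.clip(s, S_FLOOR, 1.0)
        return float(s) if np.isscalar(age) else s

    def cumulative_hazard(self, sex: str, birth_year: int, age):
        if np.any(np.asarray(age) < 0):
            raise LifeTableError(f"negative age: {age}")
        return self.stratum(sex, birth_year).cumhaz(age)

    def sample_age_at_death(self, sex: str, birth_year, rng: np.random.Generator,
                            hazard_multiplier: float = 1.0, size=None):
        """Inverse-transform lifespans: solve m*H(T) = E with E ~ Exp(1).

        ``hazard_multiplier`` < 1 models familial survival exceptionality
        (proportionally lower mortality at every age).
        """
        if hazard_multiplier <= 0:
            raise LifeTableError("hazard multiplier must be > 0")
        by = int(np.atleast_1d(birth_year)[0]) if not np.isscalar(birth_year) else int(birth_year)
        st = self.stratum(sex, by)
        e = rng.exponential(size=size)
        return st.inv_cumhaz(e / hazard_multiplier)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for st in self.strata:
            for a, s in zip(st.ages, st.survival):
                rows.append((st.sex, st.cohort_start, st.cohort_end, int(a), s))
        return pd.DataFrame(rows, columns=["sex", "cohort_start", "cohort_end",
                                           "age", "survival"])

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def load_lifetable(path) -> LifeTable:
    """Read a life-table CSV (columns sex, cohort_start, cohort_end, age, survival)."""
    df = pd.read_csv(path)
    need = {"sex", "cohort_start", "cohort_end", "age", "survival"}
    if not need.issubset(df.columns):
        raise LifeTableError(f"{path}: missing columns {need - set(df.columns)}")
    strata = []
    for (sex, c0, c1), sub in df.groupby(["sex", "cohort_start", "cohort_end"]):
        sub = sub.sort_values("age")
        strata.append(_Stratum(str(sex), int(c0), int(c1),
                               sub["age"].to_numpy(), sub["survival"].to_numpy()))
    return LifeTable(strata)


def make_gompertz_table(a: float, b: float, sex: str = "female",
                        cohort: tuple[int, int] = (1900, 1930),
                        max_age: int = 110) -> LifeTable:
    """Tabulate a Gompertz survival curve at integer ages 0..max_age."""
    if a <= 0 or b <= 0:
        raise LifeTableError("Gompertz parameters must be positive")
    if max_age < 1:
        raise LifeTableError("max_age must be >= 1")
    ages = np.arange(max_age + 1)
    surv = gompertz_survival(ages, a, b)
    return LifeTable([_Stratum(sex, cohort[0], cohort[1], ages, surv)])


def default_cohort_table(max_age: int = 115) -> LifeTable:
    """Two-sex Gompertz table with a modest female survival advantage.

    Parameters give life expectancies in the low 80s and are used as the
    default scoring/simulation table when no national table is supplied.
    """
    male = make_gompertz_table(3.0e-5, 0.105, "male", (1890, 1960), max_age)
    female = make_gompertz_table(1.6e-5, 0.108, "female", (1890, 1960), max_age)
    return LifeTable(male.strata + female.strata)
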