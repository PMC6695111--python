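"""All-cause mortality from a period life table, with a parametric generator.

The model's death transition is driven by qx, the annual probability of dying
between exact ages x and x+1.  The original analysis used the national
Singapore life table, which is not published with the model; this module
therefore also provides a Gompertz-Makeham generator,

    qx(age) = 1 - exp(-(A + B * c**age)),

whose Gompertz slope B is calibrated by root finding so that life expectancy
at birth matches a target (83 y by default, a high-longevity national
population).  Pre-retirement mortality is tiny under any such table, so the
discounted model outputs are insensitive to the exact table used; a real
``age,qx`` CSV can be supplied instead.

Life expectancy at birth is computed by the standard lx method:
e0 = 0.5 + sum over ages a >= 1 of l(a), with l(a) the probability of
surviving from birth to exact age a (the half year credits the year of death).
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq


class LifeTableFormatError(ValueError):
    pass


class CalibrationError(RuntimeError):
    pass


@dataclass
class LifeTable:
    ages: np.ndarray  # consecutive integer ages
    qx: np.ndarray    # qx[i] = P(death before age ages[i]+1 | alive at ages[i])

    def __post_init__(self):
        self.ages = np.asarray(self.ages, dtype=int)
        self.qx = np.asarray(self.qx, dtype=float)

    @property
    def max_age(self) -> int:
        return int(self.ages[-1])

    def to_csv(self) -> str:
        return pd.DataFrame({"age": self.ages, "qx": self.qx}).to_csv(index=False)


@dataclass
class GompertzMakehamParams:
    makeham_a: float
    gompertz_b: float
    gompertz_c: float
    max_age: int = 100

    def __post_init__(self):
        if self.makeham_a < 0:
            raise ValueError("makeham_a must be >= 0")
        if self.gompertz_b <= 0:
            raise ValueError("gompertz_b must be > 0")
        if self.gompertz_c <= 1:
            raise ValueError("gompertz_c must be > 1")


def read_life_table(table_text: str) -> LifeTable:
    """Parse an ``age,qx`` CSV.  qx at the last age is coerced to 1 (the table
    closes the cohort at its maximum age)."""
    try:
        df = pd.read_csv(io.StringIO(table_text))
    except (pd.errors.EmptyDataError, pd.errors.ParserError) as exc:
        raise LifeTableFormatError(f"unreadable life table: {exc}") from exc
    for col in ("age", "qx"):
        if col not in df.columns:
            raise LifeTableFormatError(f"missing column '{col}'")
    if len(df) == 0:
        raise LifeTableFormatError("life table has no rows")
    df = df.sort_values("age").reset_index(drop=True)
    ages = df["age"].to_numpy()
    qx = df["qx"].to_numpy(dtype=float)
    if np.any(np.diff(ages) != 1):
        raise LifeTableFormatError("ages must be consecutive integers")
    for i, q in enumerate(qx):
        if not (0.0 <= q <= 1.0):
            raise LifeTableFormatError(f"row {i} (age {ages[i]}): qx {q} "
                                       "outside [0, 1]")
    qx[-1] = 1.0
    return LifeTable(ages=ages, qx=qx)


def annual_death_probability(lt: LifeTable, age: int) -> float:
    """qx at ``age``; ages beyond the table's maximum return 1."""
    if age < lt.ages[0]:
        raise ValueError(f"age {age} precedes the first tabulated age "
                         f"{lt.ages[0]}")
    if age > lt.max_age:
        return 1.0
    return float(lt.qx[int(age) - int(lt.ages[0])])


def make_gompertz_makeham_table(p: GompertzMakehamParams) -> LifeTable:
    """qx(age) = 1 - exp(-(A + B c^age)) for ages 0..max_age-1; qx(max_age)=1."""
    ages = np.arange(0, p.max_age + 1)
    hazard = p.makeham_a + p.gompertz_b * p.gompertz_c ** ages.astype(float)
    qx = 1.0 - np.exp(-hazard)
    qx[-1] = 1.0
    return LifeTable(ages=ages, qx=qx)


def survivorship(lt: LifeTable) -> np.ndarray:
    """l(a): probability of surviving from the first tabulated age to exact
    age a, for a = ages[0]..max_age+1.  Non-increasing, l(ages[0]) = 1."""
    lx = np.ones(len(lt.ages) + 1)
    lx[1:] = np.cumprod(1.0 - lt.qx)
    return lx


def life_expectancy_at_birth(lt: LifeTable) -> float:
    """e0 by the lx method: half a year for the year of death plus one year
    per fully survived age."""
    if lt.ages[0] != 0:
        raise ValueError("life expectancy at birth needs a table starting at age 0")
    lx = survivorship(lt)
    return 0.5 + float(np.sum(lx[1:]))


def calibrate_to_life_expectancy(target_e0: float, a: float, c: float,
                                 max_age: int = 100) -> GompertzMakehamParams:
    """Find the Gompertz slope B giving a table with e0 = ``target_e0``.

    Root finding (Brent) on log10(B) over a wide bracket; raises
    CalibrationError when the target is outside the achievable range.
    """

    def e0_of(log_b: float) -> float:
        p = GompertzMakehamParams(a, 10.0 ** log_b, c, max_age)
        return life_expectancy_at_birth(make_gompertz_makeham_table(p))

    lo, hi = -12.0, 0.0  # B from 1e-12 (near-zero senescence) to 1
    f_lo, f_hi = e0_of(lo) - target_e0, e0_of(hi) - target_e0
    if f_lo * f_hi > 0:
        raise CalibrationError(
            f"life expectancy {target_e0} y is not attainable with a={a}, c={c}, "
            f"max_age={max_age} (achievable range ~[{e0_of(hi):.1f}, "
            f"{e0_of(lo):.1f}] y)")
    log_b = brentq(lambda x: e0_of(x) - target_e0, lo, hi, xtol=1e-12)
    return GompertzMakehamParams(a, 10.0 ** log_b, c, max_age)
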