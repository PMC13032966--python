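"""Synthetic background-mortality life table.

The cohort model needs age-specific all-cause mortality for US women.  To
keep the package self-contained we ship a two-parameter Gompertz
approximation instead of an external download: the annual hazard at age x
is ``a * exp(b * (x - 60))``, so the annual death probability is
``1 - exp(-a * exp(b * (x - 60)))``.  The default constants (a = 0.0065,
b = 0.085) approximate published US female life-table values over ages
60-90 (for example q(62) is about 0.008-0.009); background mortality is a
minor force in this model next to the 0.051/month post-progression death
probability, so the approximation has little leverage on results.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "LifeTable",
    "gompertz_lifetable",
    "monthly_background_mortality",
]

DEFAULT_GOMPERTZ_A = 0.0065
DEFAULT_GOMPERTZ_B = 0.085


@dataclass(frozen=True)
class LifeTable:
    """Annual death probabilities by integer age, female.

    Ages beyond ``terminal_age`` clamp to the terminal row.
    """

    ages: np.ndarray  # integer years, contiguous
    q_annual: np.ndarray  # P(death within the year | alive at age)

    def __post_init__(self) -> None:
        ages = np.asarray(self.ages, dtype=int)
        q = np.asarray(self.q_annual, dtype=float)
        if ages.shape != q.shape or ages.ndim != 1 or len(ages) == 0:
            raise ValueError("ages and q_annual must be equal-length 1-D arrays")
        if not np.all(np.diff(ages) == 1):
            raise ValueError("ages must be contiguous integers")
        if np.any((q <= 0) | (q >= 1)):
            raise ValueError("q_annual values must lie in (0, 1)")
        object.__setattr__(self, "ages", ages)
        object.__setattr__(self, "q_annual", q)

    @property
    def start_age(self) -> int:
        return int(self.ages[0])

    @property
    def terminal_age(self) -> int:
        return int(self.ages[-1])

    def annual_q(self, age) -> np.ndarray | float:
        """q for the integer year containing ``age``; clamped at both ends."""
        idx = np.clip(np.floor(age).astype(int) - self.start_age, 0, len(self.ages) - 1)
        out = self.q_annual[idx]
        return float(out) if np.isscalar(age) or np.ndim(age) == 0 else out

    # -- plain-text round trip --------------------------------------------
    def to_csv(self, path_or_buf) -> None:
        pd.DataFrame({"age": self.ages, "q_annual": self.q_annual}).to_csv(
            path_or_buf, index=False
        )

    @classmethod
    def from_csv(cls, path_or_buf) -> "LifeTable":
        df = pd.read_csv(path_or_buf)
        return cls(df["age"].to_numpy(), df["q_annual"].to_numpy())


def gompertz_lifetable(
    a: float = DEFAULT_GOMPERTZ_A,
    b: float = DEFAULT_GOMPERTZ_B,
    age_range: tuple[int, int] = (40, 110),
) -> LifeTable:
    """Build a life table from a Gompertz hazard anchored at age 60.

    ``q_annual(x) = 1 - exp(-a * exp(b * (x - 60)))``; ``a`` is the annual
    hazard at age 60 and ``b`` the log-slope per year of age.
    """
    if a <= 0 or b < 0:
        raise ValueError("gompertz requires a > 0 and b >= 0")
    lo, hi = age_range
    ages = np.arange(lo, hi + 1)
    hazard = a * np.exp(b * (ages - 60.0))
    q = 1.0 - np.exp(-hazard)
    return LifeTable(ages, q)


def monthly_background_mortality(lt: LifeTable, age) -> np.ndarray | float:
    """Monthly death probability at (fractional) ``age``.

    The annual probability of the integer year containing ``age`` is
    converted with ``1 - (1 - q) ** (1/12)``, so twelve monthly draws
    compound back to the annual value.
    """
    q = lt.annual_q(age)
    return 1.0 - (1.0 - q) ** (1.0 / 12.0)
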