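"""Deterministic synthetic life tables with controlled mortality structure.

The main generator builds a single-year life table from a Siler hazard

    mu(x) = a1 * exp(-b1 * x) + c + a3 * exp(b3 * x)

whose three components — a declining infant hazard, a constant background
hazard, and an exponentially rising senescent hazard — span the full human
age range.  Raising ``a1`` deepens the infant-mortality spike (and can force
the modal age at death to 0); ``a3``/``b3`` shape the old-age mortality hump.
All three terms integrate in closed form over each year of age, so the
generator involves no numerical quadrature and no randomness: identical
parameters give bit-identical tables.

Two further constructors produce the degenerate benchmarks the indices are
anchored on: a single-age-of-death table (the perfect-equality extreme) and
a two-point table (the minimal unequal population, handy as a hand-computable
oracle).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import LifeineqError
from .lifetable import DEFAULT_A0, DEFAULT_AX, LifeTable

__all__ = [
    "SilerParams",
    "siler_lifetable",
    "degenerate_lifetable",
    "two_point_lifetable",
    "PRESETS",
]

RADIX = 100_000.0
#: Cap on the mean years lived in the open interval (a_omega = 1/mu(omega)).
_OPEN_INTERVAL_CAP = 5.0


@dataclass(frozen=True)
class SilerParams:
    """Parameters of the Siler hazard, all in units of 1/year.

    a1 : infant hazard level at birth (>= 0)
    b1 : decay rate of the infant hazard (> 0)
    c  : age-independent background hazard (>= 0)
    a3 : senescent hazard level at birth (> 0)
    b3 : growth rate of the senescent hazard (> 0)
    omega : integer age opening the terminal interval (>= 2)
    """

    a1: float = 0.01
    b1: float = 1.0
    c: float = 0.0005
    a3: float = 2e-5
    b3: float = 0.10
    omega: int = 110

    def __post_init__(self) -> None:
        if not all(map(math.isfinite, (self.a1, self.b1, self.c, self.a3, self.b3))):
            raise ValueError("Siler rates must be finite")
        if self.a1 < 0 or self.c < 0 or self.a3 <= 0 or self.b1 <= 0 or self.b3 <= 0:
            raise ValueError("Siler rates out of range (a1,c >= 0; b1,a3,b3 > 0)")
        if self.omega < 2:
            raise ValueError("omega must be at least 2")

    def hazard(self, x: np.ndarray | float) -> np.ndarray | float:
        return (self.a1 * np.exp(-self.b1 * np.asarray(x, dtype=float))
                + self.c
                + self.a3 * np.exp(self.b3 * np.asarray(x, dtype=float)))

    def cumulative_hazard(self, x: np.ndarray | float) -> np.ndarray | float:
        """Closed-form integral of the hazard from 0 to x."""
        x = np.asarray(x, dtype=float)
        return (self.a1 / self.b1 * (1.0 - np.exp(-self.b1 * x))
                + self.c * x
                + self.a3 / self.b3 * (np.exp(self.b3 * x) - 1.0))


def siler_lifetable(p: SilerParams,
                    location: str = "siler",
                    year: int = 2000) -> LifeTable:
    """Build a complete life table on radix 100 000 from a Siler hazard.

    Survival uses the exact within-year integral of the hazard, q_x = 1 -
    exp(-H(x, x+1)).  Survivors reaching ``omega`` die in the open interval
    with mean time lived a_omega = 1/mu(omega), capped at 5 years so e0
    stays finite and stable even for very flat old-age hazards.
    """
    with np.errstate(over="raise"):
        try:
            h_terminal = float(p.cumulative_hazard(float(p.omega)))
        except FloatingPointError:
            h_terminal = math.inf
    if not math.isfinite(h_terminal):
        raise LifeineqError(
            f"hazard overflows at omega={p.omega}; reduce b3*omega "
            f"(currently {p.b3 * p.omega:g})"
        )

    ages = np.arange(p.omega + 1)
    h = p.cumulative_hazard(ages.astype(float))
    lx = RADIX * np.exp(-h)          # survivors to exact age x
    dx = np.empty(ages.size)
    dx[:-1] = lx[:-1] - lx[1:]
    dx[-1] = lx[-1]                  # everyone left dies in the open interval

    ax = np.full(ages.size, DEFAULT_AX)
    ax[0] = DEFAULT_A0
    mu_omega = float(p.hazard(float(p.omega)))
    ax[-1] = min(1.0 / mu_omega, _OPEN_INTERVAL_CAP) if mu_omega > 0 else _OPEN_INTERVAL_CAP

    # person-years and remaining life expectancy, standard column algebra
    big_l = np.empty(ages.size)
    big_l[:-1] = lx[1:] + ax[:-1] * dx[:-1]
    big_l[-1] = ax[-1] * dx[-1]
    tx = np.cumsum(big_l[::-1])[::-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        ex = np.where(lx > 0, tx / lx, 0.0)

    return LifeTable(location=location, year=year, ages=ages, dx=dx,
                     lx=lx, ax=ax, ex=ex)


def degenerate_lifetable(age: int,
                         omega: int = 110,
                         location: str = "degenerate",
                         year: int = 2000,
                         ax: dict[int, float] | None = None) -> LifeTable:
    """All deaths in the single interval [age, age+1): perfect equality."""
    if not 0 <= age <= omega:
        raise ValueError("age must lie in [0, omega]")
    return two_point_lifetable(age, omega, p=1.0, omega=omega,
                               location=location, year=year, ax=ax)


def two_point_lifetable(age_a: int,
                        age_b: int,
                        p: float,
                        omega: int = 110,
                        location: str = "two-point",
                        year: int = 2000,
                        ax: dict[int, float] | None = None) -> LifeTable:
    """Deaths split p : (1-p) between two ages; the minimal unequal table.

    ``ax`` optionally overrides the within-interval fraction at specific
    ages (e.g. ``{0: 0.0}`` places infant deaths exactly at birth), leaving
    the defaults elsewhere.
    """
    if not 0 <= age_a <= age_b <= omega:
        raise ValueError("need 0 <= age_a <= age_b <= omega")
    if age_a == age_b and p != 1.0:
        raise ValueError("age_a == age_b requires p = 1")
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must lie in [0, 1]")
    ages = np.arange(omega + 1)
    dx = np.zeros(ages.size)
    dx[age_a] += p * RADIX
    dx[age_b] += (1.0 - p) * RADIX
    ax_col = np.full(ages.size, DEFAULT_AX)
    if omega > 0:
        ax_col[0] = DEFAULT_A0
    if ax:
        for k, v in ax.items():
            ax_col[k] = v
    return LifeTable(location=location, year=year, ages=ages, dx=dx, ax=ax_col)


#: Named parameter presets for the CLI and for quick interactive use.
PRESETS: dict[str, SilerParams] = {
    # a contemporary low-mortality schedule: small infant spike, adult mode
    "low-mortality": SilerParams(a1=0.005, b1=1.0, c=0.0004, a3=2e-5, b3=0.105),
    # heavy infant mortality: the mode sits at age 0
    "high-infant-mortality": SilerParams(a1=0.5, b1=0.8, c=0.01, a3=5e-5, b3=0.09),
}
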