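"""Single-year ("complete") period life tables and their death distributions.

A :class:`LifeTable` holds one location-year mortality schedule on a fixed
radix: deaths ``dx`` per single-year age interval, optionally survivors
``lx``, the within-interval fraction lived by decedents ``ax``, and remaining
life expectancy ``ex``.  The last age is the open-ended interval.

A :class:`DeathDistribution` is the discrete distribution of ages at death
implied by a life table: point masses at effective ages ``x + a_x`` with
weights ``d_x / Σ d_x``.  It is the common substrate on which every
inequality index in :mod:`lifeineq.indices` operates.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateInputError, FormatError, ValidationError

__all__ = [
    "LifeTable",
    "DeathDistribution",
    "read_lifetable_csv",
    "write_lifetable_csv",
    "to_death_distribution",
    "compute_e0",
    "DIALECTS",
]

#: Default within-interval fraction lived by those dying in infancy.  High
#: early-infant mortality concentrates deaths near birth, so the standard
#: demographic convention places them at 0.3 of the first year.
DEFAULT_A0 = 0.3
#: Default fraction for every other closed single-year interval.
DEFAULT_AX = 0.5

# Column-name dialects: maps from source header (lower-cased) to canonical
# name.  "canonical" is the package's own layout; "wpp" follows the UN World
# Population Prospects complete-life-table export naming.
DIALECTS: dict[str, dict[str, str]] = {
    "canonical": {
        "location": "location",
        "year": "year",
        "age": "age",
        "dx": "dx",
        "lx": "lx",
        "ax": "ax",
        "ex": "ex",
    },
    "wpp": {
        "location": "location",
        "time": "year",
        "agegrpstart": "age",
        "dx": "dx",
        "lx": "lx",
        "ax": "ax",
        "ex": "ex",
    },
}

_MANDATORY = ("location", "year", "age", "dx")
_REL_TOL = 1e-6


def _as_float_array(values, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise ValidationError(f"{name} must be one-dimensional")
    return arr


@dataclass(frozen=True)
class LifeTable:
    """One location-year single-year mortality schedule.

    Parameters
    ----------
    location : str
        Opaque location key (country, territory, or any stratum label).
    year : int
        Calendar year of the period table.
    ages : array of int
        Contiguous integer ages ``0, 1, ..., omega``; the last age is the
        open-ended interval.
    dx : array of float
        Deaths in each age interval on a fixed radix; nonnegative.
    lx, ax, ex : array of float, optional
        Survivors to exact age x, average fraction of the interval lived by
        those dying in it, and remaining life expectancy at exact age x.
    """

    location: str
    year: int
    ages: np.ndarray
    dx: np.ndarray
    lx: np.ndarray | None = None
    ax: np.ndarray | None = None
    ex: np.ndarray | None = None

    def __post_init__(self) -> None:
        ages = np.asarray(self.ages, dtype=int)
        dx = _as_float_array(self.dx, "dx")
        object.__setattr__(self, "ages", ages)
        object.__setattr__(self, "dx", dx)
        for name in ("lx", "ax", "ex"):
            val = getattr(self, name)
            if val is not None:
                object.__setattr__(self, name, _as_float_array(val, name))
        self._validate()

    # -- validation ------------------------------------------------------
    def _validate(self) -> None:
        ctx = f"{self.location}/{self.year}"
        n = self.ages.size
        if n < 1:
            raise ValidationError(f"{ctx}: empty life table")
        if self.ages[0] != 0 or np.any(np.diff(self.ages) != 1):
            raise ValidationError(f"{ctx}: non-contiguous ages")
        if self.dx.size != n:
            raise ValidationError(f"{ctx}: dx length mismatch")
        if np.any(self.dx < 0):
            raise ValidationError(f"{ctx}: negative dx")
        for name in ("lx", "ax", "ex"):
            val = getattr(self, name)
            if val is not None and val.size != n:
                raise ValidationError(f"{ctx}: {name} length mismatch")
        if self.lx is not None:
            lx = self.lx
            if np.any(np.diff(lx) > _REL_TOL * max(lx[0], 1.0)):
                raise ValidationError(f"{ctx}: lx not nonincreasing")
            total = self.dx.sum()
            if total > 0 and not np.isclose(lx[0], total, rtol=_REL_TOL):
                raise ValidationError(
                    f"{ctx}: sum(dx)={total:g} does not match radix lx[0]={lx[0]:g}"
                )
            # closed intervals: lx[x] - lx[x+1] == dx[x]
            diffs = lx[:-1] - lx[1:]
            if not np.allclose(diffs, self.dx[:-1], rtol=_REL_TOL,
                               atol=_REL_TOL * max(lx[0], 1.0)):
                raise ValidationError(f"{ctx}: lx decrements inconsistent with dx")
        if self.ax is not None:
            # open interval may exceed one year; closed intervals must not
            if np.any(self.ax[:-1] < 0) or np.any(self.ax[:-1] > 1):
                raise ValidationError(f"{ctx}: ax outside [0, 1] in a closed interval")
            if self.ax[-1] < 0:
                raise ValidationError(f"{ctx}: negative terminal ax")

    # -- derived quantities ----------------------------------------------
    @property
    def omega(self) -> int:
        """Age at which the open-ended interval starts."""
        return int(self.ages[-1])

    @property
    def radix(self) -> float:
        """Cohort size at birth: ``lx[0]`` when survivors are present, else Σ dx."""
        if self.lx is not None:
            return float(self.lx[0])
        return float(self.dx.sum())

    def effective_ax(self) -> np.ndarray:
        """ax column with defaults filled where the table does not supply one.

        a_0 = 0.3, a_x = 0.5 for closed intervals, and for the open interval
        the table's remaining life expectancy at omega when available,
        otherwise 0.5.
        """
        if self.ax is not None:
            return self.ax.copy()
        ax = np.full(self.ages.size, DEFAULT_AX)
        ax[0] = DEFAULT_A0 if self.ages.size > 1 else DEFAULT_AX
        if self.ex is not None:
            ax[-1] = self.ex[-1]
        return ax

    def replace(self, **changes) -> "LifeTable":
        return dataclasses.replace(self, **changes)


@dataclass(frozen=True)
class DeathDistribution:
    """Discrete ages-at-death with probability weights summing to one."""

    points: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        points = _as_float_array(self.points, "points")
        weights = _as_float_array(self.weights, "weights")
        object.__setattr__(self, "points", points)
        object.__setattr__(self, "weights", weights)
        if points.size != weights.size or points.size == 0:
            raise ValidationError("points and weights must be equal-length, nonempty")
        if np.any(np.diff(points) <= 0):
            raise ValidationError("points must be strictly increasing")
        if np.any(weights < 0):
            raise ValidationError("weights must be nonnegative")
        if abs(weights.sum() - 1.0) > 1e-9:
            raise ValidationError(f"weights sum to {weights.sum()!r}, not 1")

    def mean(self) -> float:
        """Mean age at death of the synthetic cohort, Σ w_i x̃_i."""
        return float(np.dot(self.weights, self.points))


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _resolve_columns(columns: Sequence[str],
                     dialect: str,
                     column_map: Mapping[str, str] | None) -> dict[str, str]:
    """Map actual CSV headers to canonical names, case-insensitively."""
    if column_map is not None:
        alias = {k.lower(): v for k, v in column_map.items()}
    else:
        try:
            alias = DIALECTS[dialect]
        except KeyError:
            raise FormatError(
                f"unknown dialect {dialect!r}; known: {sorted(DIALECTS)}"
            ) from None
    out: dict[str, str] = {}
    for col in columns:
        canon = alias.get(col.lower())
        if canon is not None:
            out[col] = canon
    present = set(out.values())
    for required in _MANDATORY:
        if required not in present:
            raise FormatError(f"missing mandatory column: {required!r}")
    return out


def read_lifetable_csv(path: str | Path,
                       dialect: str = "canonical",
                       column_map: Mapping[str, str] | None = None,
                       ) -> list[LifeTable]:
    """Read a long-format life-table CSV into validated :class:`LifeTable` s.

    One row per (location, year, age); mandatory columns location, year,
    age, dx under the chosen ``dialect`` (or an explicit ``column_map`` from
    source headers to canonical names).  Header matching is case-insensitive.
    Returns one table per (location, year), ages sorted ascending.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    raw = pd.read_csv(path)
    rename = _resolve_columns(list(raw.columns), dialect, column_map)
    df = raw.rename(columns=rename)[list(dict.fromkeys(rename.values()))]

    tables: list[LifeTable] = []
    for (location, year), grp in df.groupby(["location", "year"], sort=True):
        grp = grp.sort_values("age")
        kwargs = {}
        for opt in ("lx", "ax", "ex"):
            if opt in grp.columns and not grp[opt].isna().all():
                kwargs[opt] = grp[opt].to_numpy(dtype=float)
        tables.append(
            LifeTable(
                location=str(location),
                year=int(year),
                ages=grp["age"].to_numpy(dtype=int),
                dx=grp["dx"].to_numpy(dtype=float),
                **kwargs,
            )
        )
    return tables


def write_lifetable_csv(tables: Iterable[LifeTable],
                        path: str | Path,
                        dialect: str = "canonical") -> None:
    """Write tables to long-format CSV in the canonical (or aliased) layout."""
    frames = []
    for lt in tables:
        data = {"location": lt.location, "year": lt.year,
                "age": lt.ages, "dx": lt.dx}
        for opt in ("lx", "ax", "ex"):
            val = getattr(lt, opt)
            if val is not None:
                data[opt] = val
        frames.append(pd.DataFrame(data))
    out = pd.concat(frames, ignore_index=True)
    if dialect != "canonical":
        inverse = {v: k for k, v in DIALECTS[dialect].items()}
        out = out.rename(columns=inverse)
    out.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Conversion
# ---------------------------------------------------------------------------

def to_death_distribution(lt: LifeTable) -> DeathDistribution:
    """Convert a life table to its distribution of ages at death.

    Point masses sit at effective ages x̃ = x + a_x; weights are d_x
    normalized to unit total.
    """
    total = lt.dx.sum()
    if total <= 0:
        raise DegenerateInputError(
            f"{lt.location}/{lt.year}: no deaths in table (sum dx = 0)"
        )
    points = lt.ages + lt.effective_ax()
    weights = lt.dx / total
    return DeathDistribution(points=points, weights=weights)


def compute_e0(dd: DeathDistribution) -> float:
    """Life expectancy at birth of the synthetic cohort: Σ w_i x̃_i."""
    return dd.mean()
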