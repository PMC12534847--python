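"""Lifespan-inequality indices computed from a death distribution.

Three unidimensional indices, all functions of the distribution of ages at
death of a life table's synthetic cohort:

* the modal-age-anchored normalized inequality index — mean squared
  deviation of ages at death from the modal age at death, divided by the
  largest squared deviation the support allows, reported on a percent-like
  scale (0 = everyone dies at the modal age; ``scale`` = everyone dies at
  the support endpoint farthest from it);
* the lifespan Gini coefficient — twice the area between the Lorenz curve
  of cumulative person-years lived (population ranked from shortest to
  longest life) and the diagonal of perfect equality;
* the Jamison index — one minus the share of deaths occurring before life
  expectancy at birth (1 = perfect equality).

Anchoring perfect equality at the *modal* age, not at life expectancy, is
deliberate: the mode is taken from the country's own mortality distribution,
so no ideal lifespan is imposed a priori.  A consequence is that when the
mode moves off age 0 (infancy stops being the most common age at death) the
normalized index drops discontinuously.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal

import numpy as np
import pandas as pd

from .errors import DegenerateInputError
from .lifetable import DeathDistribution, LifeTable, compute_e0, to_death_distribution

__all__ = [
    "HiniConfig",
    "InequalityRecord",
    "modal_age_at_death",
    "modal_point",
    "hini",
    "health_gini",
    "jamison_index",
    "compute_all_indices",
    "compute_indices_table",
    "records_to_frame",
]


@dataclass(frozen=True)
class HiniConfig:
    """Normalization choices for the modal-anchored index.

    scale
        Multiplicative reporting scale; 100 gives a percent-like index.
    omega_tilde
        Upper support bound ω̃ used in the maximal-deviation denominator.
        ``None`` (default) uses the effective age x̃ of the table's last
        (open) interval, keeping the index self-contained per table; a fixed
        value (e.g. 110.5) makes the denominator comparable across tables.
    degenerate
        Policy when the support collapses to a single point (maximal
        deviation zero): ``"equality"`` returns 0 with a warning — the limit
        of the defined quantity — while ``"error"`` raises.
    """

    scale: float = 100.0
    omega_tilde: float | None = None
    degenerate: Literal["equality", "error"] = "equality"

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ValueError("scale must be positive")


def modal_age_at_death(lt: LifeTable) -> int:
    """Age interval with the largest number of deaths in the life table.

    No smoothing is applied; ties break to the smallest age, which is
    conservative in that it favors detecting an infant mode.
    """
    if lt.dx.sum() <= 0:
        raise DegenerateInputError(
            f"{lt.location}/{lt.year}: all-zero deaths column"
        )
    return int(lt.ages[int(np.argmax(lt.dx))])


def modal_point(lt: LifeTable) -> float:
    """The modal age on the effective-age axis: M̃ = M + a_M."""
    m = modal_age_at_death(lt)
    idx = int(np.searchsorted(lt.ages, m))
    return float(m + lt.effective_ax()[idx])


def hini(dd: DeathDistribution,
         modal_pt: float,
         cfg: HiniConfig | None = None) -> float:
    """Normalized inequality index anchored at the modal age at death.

    Computes ``scale × Σ_i w_i (x̃_i − M̃)² / D²`` where M̃ is the modal
    point on the effective-age axis and ``D = max(M̃, ω̃ − M̃)`` is the
    largest deviation from M̃ the support [0, ω̃] allows.  The result is 0
    iff all mass sits at M̃ and equals ``scale`` iff all mass sits at the
    support endpoint farthest from M̃.

    Parameters
    ----------
    dd : DeathDistribution
    modal_pt : float
        M̃ = M + a_M for the source table's modal age M (see
        :func:`modal_point`).
    cfg : HiniConfig, optional
    """
    cfg = cfg or HiniConfig()
    omega_tilde = cfg.omega_tilde
    if omega_tilde is None:
        omega_tilde = float(dd.points[-1])
    if omega_tilde < dd.points[-1] - 1e-12:
        raise ValueError(
            f"omega_tilde={omega_tilde} below the largest age at death "
            f"{dd.points[-1]}"
        )
    d_max = max(modal_pt, omega_tilde - modal_pt)
    if d_max <= 0:
        if cfg.degenerate == "equality":
            warnings.warn(
                "single-point support: index is 0 by the equality convention",
                stacklevel=2,
            )
            return 0.0
        raise DegenerateInputError("single-age support: maximal deviation is zero")
    msd = float(np.dot(dd.weights, (dd.points - modal_pt) ** 2))
    return cfg.scale * msd / d_max**2


def health_gini(dd: DeathDistribution) -> float:
    """Lifespan Gini coefficient over years lived.

    Pairwise form ``G = Σ_i Σ_j w_i w_j |x̃_i − x̃_j| / (2 μ)`` with
    μ the mean age at death; identical to twice the area between the
    Lorenz curve of person-years lived and the diagonal.
    """
    mu = dd.mean()
    if mu <= 0:
        raise DegenerateInputError("mean age at death is zero")
    gaps = np.abs(dd.points[:, None] - dd.points[None, :])
    g = float(dd.weights @ gaps @ dd.weights) / (2.0 * mu)
    return g


def jamison_index(dd: DeathDistribution, e0: float) -> float:
    """One minus the share of deaths occurring before life expectancy.

    The cumulative share F(e0) counts the full weight of every death point
    strictly below e0.  For a point sharing e0's calendar year, its weight
    enters through a linear ramp from the point's own location x̃ to the end
    of that year, so F is continuous and nondecreasing in e0 and a
    population dying entirely at exactly e0 scores a clean 1.
    """
    lo, hi = float(dd.points[0]), float(dd.points[-1])
    if e0 < lo or e0 > hi:
        warnings.warn(
            f"e0={e0:g} outside the support [{lo:g}, {hi:g}]; clamped",
            stacklevel=2,
        )
        return 1.0 if e0 <= lo else 0.0
    year = np.floor(e0)
    pts, w = dd.points, dd.weights
    below = pts < e0
    same_year = np.floor(pts) == year
    frac = np.zeros_like(w)
    full = below & ~same_year
    frac[full] = 1.0
    ramp = below & same_year
    if np.any(ramp):
        frac[ramp] = (e0 - pts[ramp]) / (year + 1.0 - pts[ramp])
    f_before = float(np.dot(w, frac))
    return 1.0 - f_before


@dataclass(frozen=True)
class InequalityRecord:
    """Per location-year values of the three indices and their anchors."""

    location: str
    year: int
    hini: float
    gini: float
    jamison: float
    modal_age: int
    e0: float

    _FIELDS = ("location", "year", "hini", "gini", "jamison", "modal_age", "e0")


def compute_all_indices(lt: LifeTable,
                        cfg: HiniConfig | None = None,
                        e0_source: Literal["cohort", "table"] = "cohort",
                        ) -> InequalityRecord:
    """Compute every index for one life table from a single death distribution.

    ``e0_source="cohort"`` (default) uses the cohort mean age at death, which
    is internally consistent with the distribution the indices see;
    ``"table"`` prefers the table's own ``ex[0]`` when present, matching the
    producer's within-interval conventions instead.
    """
    cfg = cfg or HiniConfig()
    try:
        dd = to_death_distribution(lt)
        m = modal_age_at_death(lt)
        m_pt = modal_point(lt)
        if e0_source == "table" and lt.ex is not None:
            e0 = float(lt.ex[0])
        else:
            e0 = compute_e0(dd)
        return InequalityRecord(
            location=lt.location,
            year=lt.year,
            hini=hini(dd, m_pt, cfg),
            gini=health_gini(dd),
            jamison=jamison_index(dd, e0),
            modal_age=m,
            e0=e0,
        )
    except DegenerateInputError as exc:
        raise DegenerateInputError(f"{lt.location}/{lt.year}: {exc}") from exc


def compute_indices_table(tables: Iterable[LifeTable],
                          cfg: HiniConfig | None = None,
                          e0_source: Literal["cohort", "table"] = "cohort",
                          ) -> pd.DataFrame:
    """Batch :func:`compute_all_indices` into a tidy frame.

    Output is sorted by (location, year) so it is stable under input
    reordering.
    """
    records = [compute_all_indices(lt, cfg, e0_source) for lt in tables]
    return records_to_frame(records)


def records_to_frame(records: Iterable[InequalityRecord]) -> pd.DataFrame:
    cols = InequalityRecord._FIELDS
    df = pd.DataFrame([{c: getattr(r, c) for c in cols} for r in records],
                      columns=list(cols))
    return df.sort_values(["location", "year"], ignore_index=True)
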