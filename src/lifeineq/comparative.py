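"""Cross-country comparison: filtering, ranking, trends, income groups.

Operates on tidy index frames (one row per location-year, as produced by
:func:`lifeineq.indices.compute_indices_table`) plus a country metadata
table carrying population and a fixed four-level income-group label.  Ranks
run from 1 (most equal, i.e. lowest index value); percentiles are
100 × (N − rank) / N so higher means more equal.  Income-group membership is
held fixed at a single classification year rather than tracked
contemporaneously, so group trends reflect changing mortality, not countries
migrating between groups.
"""

from __future__ import annotations

import logging
from typing import Iterable

import pandas as pd

from .errors import ValidationError

__all__ = [
    "INCOME_GROUPS",
    "validate_country_meta",
    "filter_small_countries",
    "rank_countries",
    "normalize_trend",
    "income_group_trend",
]

logger = logging.getLogger(__name__)

#: Fixed four-level World Bank style classification.
INCOME_GROUPS = ("low", "lower-middle", "upper-middle", "high")

#: Exclude microstates below this population from cross-country analysis.
DEFAULT_POPULATION_THRESHOLD = 200_000


def validate_country_meta(meta: pd.DataFrame) -> pd.DataFrame:
    """Check a metadata frame (location, population, income_group)."""
    for col in ("location", "population"):
        if col not in meta.columns:
            raise ValidationError(f"country metadata missing column {col!r}")
    if meta["location"].duplicated().any():
        dupes = meta.loc[meta["location"].duplicated(), "location"].tolist()
        raise ValidationError(f"duplicate locations in metadata: {dupes}")
    if (meta["population"] < 0).any():
        raise ValidationError("negative population in metadata")
    if "income_group" in meta.columns:
        bad = set(meta["income_group"].dropna()) - set(INCOME_GROUPS)
        if bad:
            raise ValidationError(
                f"unknown income groups {sorted(bad)}; expected {INCOME_GROUPS}"
            )
    return meta


def filter_small_countries(records: pd.DataFrame,
                           meta: pd.DataFrame,
                           threshold: int = DEFAULT_POPULATION_THRESHOLD,
                           ) -> pd.DataFrame:
    """Drop locations whose population falls below ``threshold``.

    Every location in ``records`` must appear in ``meta``; unmatched
    locations raise rather than being silently retained or dropped.
    Idempotent: re-filtering the output changes nothing.
    """
    validate_country_meta(meta)
    known = set(meta["location"])
    missing = sorted(set(records["location"]) - known)
    if missing:
        raise ValidationError(f"locations missing from metadata: {missing}")
    keep = set(meta.loc[meta["population"] >= threshold, "location"])
    mask = records["location"].isin(keep)
    n_dropped = records.loc[~mask, "location"].nunique()
    if n_dropped:
        logger.info("excluded %d locations below population %d",
                    n_dropped, threshold)
    return records.loc[mask].reset_index(drop=True)


def rank_countries(records: pd.DataFrame,
                   value_col: str = "hini") -> pd.DataFrame:
    """Rank one year's cross-section from most equal (rank 1) upward.

    Ties share the minimum (competition) rank; output rows are ordered by
    rank, then alphabetically by location.  Percentile = 100 (N − rank)/N,
    unrounded — callers choose a reporting precision.
    """
    years = records["year"].unique()
    if len(years) != 1:
        raise ValidationError(f"rank_countries expects one year, got {sorted(years)}")
    if records["location"].duplicated().any():
        dupes = records.loc[records["location"].duplicated(), "location"].tolist()
        raise ValidationError(f"duplicate locations in cross-section: {dupes}")
    out = records[["year", "location", value_col]].copy()
    out["rank"] = out[value_col].rank(method="min").astype(int)
    n = len(out)
    out["percentile"] = 100.0 * (n - out["rank"]) / n
    return out.sort_values(["rank", "location"], ignore_index=True)


def normalize_trend(series: pd.Series, base_year: int = 1960) -> pd.Series:
    """Index a year-keyed series to 100 at ``base_year``."""
    if base_year not in series.index:
        raise ValidationError(f"base year {base_year} absent from series")
    base = series.loc[base_year]
    if base == 0 or pd.isna(base):
        raise ValidationError(f"base year {base_year} value is zero or missing")
    return series * 100.0 / base


def income_group_trend(records: pd.DataFrame,
                       meta: pd.DataFrame,
                       value_col: str = "hini") -> pd.DataFrame:
    """Unweighted mean index value and mean rank per income group and year.

    Group membership is the metadata's fixed classification.  Group-years
    with no members are omitted with a warning.  Returns a frame with
    columns (income_group, year, mean_value, mean_rank, n).
    """
    validate_country_meta(meta)
    if "income_group" not in meta.columns:
        raise ValidationError("metadata has no income_group column")
    missing = sorted(set(records["location"]) - set(meta["location"]))
    if missing:
        raise ValidationError(f"locations missing from metadata: {missing}")

    ranked = pd.concat(
        [rank_countries(grp, value_col) for _, grp in records.groupby("year")],
        ignore_index=True,
    )
    merged = ranked.merge(meta[["location", "income_group"]], on="location")
    grouped = (
        merged.groupby(["income_group", "year"], observed=True)
        .agg(mean_value=(value_col, "mean"),
             mean_rank=("rank", "mean"),
             n=("location", "size"))
        .reset_index()
    )
    expected = {(g, y) for g in merged["income_group"].unique()
                for y in merged["year"].unique()}
    present = set(zip(grouped["income_group"], grouped["year"]))
    for g, y in sorted(expected - present):
        logger.warning("no members for income group %r in year %s", g, y)
    return grouped.sort_values(["income_group", "year"], ignore_index=True)


def trend_frame(records: pd.DataFrame,
                locations: Iterable[str] | None = None,
                value_col: str = "hini",
                base_year: int | None = None) -> pd.DataFrame:
    """Per-location year series, optionally base-year normalized (tidy)."""
    df = records if locations is None else records[
        records["location"].isin(set(locations))
    ]
    parts = []
    for loc, grp in df.groupby("location"):
        s = grp.set_index("year")[value_col].sort_index()
        if base_year is not None:
            s = normalize_trend(s, base_year)
        parts.append(pd.DataFrame({"location": loc, "year": s.index,
                                   value_col: s.to_numpy()}))
    return pd.concat(parts, ignore_index=True)
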