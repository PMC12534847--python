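"""Indicator screening and random-forest factor importance.

The screening stage tames a wide socioeconomic indicator matrix (locations ×
indicators, with missingness) before any modelling: indicators must exceed a
completeness floor, and within each highly correlated pair only the member
with less missing data survives — with a caller-supplied priority list
breaking exact ties, standing in for a manual "keep the more general
indicator" judgement.  The procedure is deterministic: pairs are visited in
descending absolute correlation.

The importance stage asks which surviving indicators best distinguish
*levels* of lifespan inequality.  The continuous index is discretized into
quantile classes, a random-forest classifier is fit on 70% of countries, and
permutation importance (mean decrease in accuracy) is measured on the 30%
holdout.  Importances are summarized as shares of the total (negatives
floored at zero), alongside the holdout misclassification rate and the
forest's classic per-tree out-of-bag error.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.inspection import permutation_importance
from sklearn.model_selection import train_test_split

from .errors import DegenerateInputError, ValidationError

__all__ = [
    "completeness",
    "screen_indicators",
    "average_window",
    "ImportanceReport",
    "rf_importance",
    "rerun_without",
    "wdi_long_to_matrix",
]


def completeness(matrix: pd.DataFrame) -> pd.Series:
    """Fraction of non-missing rows per indicator column."""
    return matrix.notna().mean(axis=0)


def screen_indicators(matrix: pd.DataFrame,
                      completeness_min: float = 0.90,
                      corr_max: float = 0.85,
                      priority: Sequence[str] | None = None,
                      ) -> list[str]:
    """Select indicators passing the completeness and collinearity screens.

    Step 1 keeps columns whose completeness strictly exceeds
    ``completeness_min``.  Step 2 computes pairwise Pearson correlation on
    pairwise-complete observations and walks pairs with |r| > ``corr_max``
    in descending |r|; from each pair still intact it drops the member with
    more missing values.  An exact missingness tie consults ``priority``
    (earlier = keep); a tie with no priority ruling is an error rather than
    an arbitrary choice.

    Returns surviving column names in the matrix's column order.
    Deterministic and idempotent.
    """
    comp = completeness(matrix)
    kept = [c for c in matrix.columns if comp[c] > completeness_min]
    if len(kept) < 2:
        return kept

    corr = matrix[kept].corr(method="pearson")
    pairs: list[tuple[float, str, str]] = []
    for i, a in enumerate(kept):
        for b in kept[i + 1:]:
            r = corr.loc[a, b]
            if pd.notna(r) and abs(r) > corr_max:
                pairs.append((abs(r), a, b))
    # descending |r|; name pair as a deterministic secondary key
    pairs.sort(key=lambda t: (-t[0], t[1], t[2]))

    alive = set(kept)
    missing_n = matrix[kept].isna().sum()
    prio_rank: Mapping[str, int] = (
        {name: i for i, name in enumerate(priority)} if priority else {}
    )
    for _, a, b in pairs:
        if a not in alive or b not in alive:
            continue
        if missing_n[a] != missing_n[b]:
            drop = a if missing_n[a] > missing_n[b] else b
        else:
            if a not in prio_rank or b not in prio_rank:
                raise ValidationError(
                    f"equal missingness for correlated pair ({a!r}, {b!r}) "
                    "and no priority ruling"
                )
            drop = a if prio_rank[a] > prio_rank[b] else b
        alive.discard(drop)
    return [c for c in kept if c in alive]


def average_window(series: pd.Series, start: int = 2010, end: int = 2020) -> float:
    """Mean of non-missing values over years [start, end] inclusive.

    Returns NaN (a missing value, not an error) when the window is empty.
    """
    window = series.loc[[y for y in series.index if start <= y <= end]]
    window = window.dropna()
    if window.empty:
        return float("nan")
    return float(window.mean())


def wdi_long_to_matrix(long_df: pd.DataFrame, year: int) -> pd.DataFrame:
    """Reduce a long (location, indicator, year, value) table to a wide
    locations × indicators matrix for one year."""
    sub = long_df[long_df["year"] == year]
    return sub.pivot(index="location", columns="indicator", values="value")


@dataclass(frozen=True)
class ImportanceReport:
    """Permutation-importance summary for one forest run.

    table
        One row per indicator: mean decrease in accuracy (``importance``),
        its spread over permutation repeats (``spread``), and the share of
        total floored importance in percent (``share_pct``), sorted by
        descending importance.
    oob_error
        Misclassification rate on the 30% holdout.
    tree_oob_error
        Classic per-tree out-of-bag error of the forest on its training set.
    config
        The resolved run configuration (seed, trees, bins, ...).
    """

    table: pd.DataFrame
    oob_error: float
    tree_oob_error: float
    config: dict = field(default_factory=dict)

    def share(self, indicator: str) -> float:
        row = self.table.set_index("indicator")["share_pct"]
        return float(row[indicator])


def _quantile_classes(target: pd.Series, n_bins: int) -> pd.Series:
    if target.nunique() < 2:
        raise DegenerateInputError("constant target cannot be discretized")
    classes = pd.qcut(target, q=n_bins, labels=False, duplicates="drop")
    if classes.nunique() < 2:
        raise DegenerateInputError(
            f"quantile binning into {n_bins} classes collapsed to one class"
        )
    return classes.astype(int)


def rf_importance(matrix: pd.DataFrame,
                  target: pd.Series,
                  n_trees: int = 500,
                  seed: int = 0,
                  holdout_fraction: float = 0.30,
                  n_bins: int = 4,
                  n_repeats: int = 10,
                  ) -> ImportanceReport:
    """Random-forest permutation importance of indicators for inequality level.

    The target is discretized into ``n_bins`` quantile classes; the forest
    trains on the complement of a ``holdout_fraction`` stratified split and
    importance is the mean decrease in holdout accuracy over ``n_repeats``
    permutations of each column.  Missing indicator values are imputed with
    the training-agnostic column median.  Fully reproducible for a given
    seed, and invariant to row order (rows are canonically sorted first).
    """
    if matrix.shape[1] == 0:
        raise ValidationError("indicator matrix has no columns")
    if not matrix.index.equals(target.index):
        target = target.reindex(matrix.index)
        if target.isna().any():
            raise ValidationError("target does not cover every matrix row")
    order = matrix.index.argsort()
    matrix = matrix.iloc[order]
    target = target.iloc[order]

    classes = _quantile_classes(target, n_bins)
    counts = classes.value_counts()
    if (counts < 2).any():
        raise DegenerateInputError(
            f"fewer than 2 rows in a target class: {counts.to_dict()}"
        )

    filled = matrix.fillna(matrix.median(axis=0))
    if filled.isna().any().any():
        all_nan = [c for c in filled.columns if filled[c].isna().any()]
        raise ValidationError(f"indicator columns entirely missing: {all_nan}")

    x_train, x_test, y_train, y_test = train_test_split(
        filled, classes, test_size=holdout_fraction,
        random_state=seed, stratify=classes,
    )
    forest = RandomForestClassifier(
        n_estimators=n_trees, random_state=seed, oob_score=True,
    )
    forest.fit(x_train, y_train)

    perm = permutation_importance(
        forest, x_test, y_test, scoring="accuracy",
        n_repeats=n_repeats, random_state=seed,
    )
    importances = perm.importances_mean
    spreads = perm.importances_std
    floored = np.clip(importances, 0.0, None)
    total = floored.sum()
    shares = 100.0 * floored / total if total > 0 else np.zeros_like(floored)

    table = (
        pd.DataFrame({
            "indicator": filled.columns,
            "importance": importances,
            "spread": spreads,
            "share_pct": shares,
        })
        .sort_values(["importance", "indicator"],
                     ascending=[False, True], ignore_index=True)
    )
    oob_error = 1.0 - float(forest.score(x_test, y_test))
    tree_oob_error = 1.0 - float(forest.oob_score_)
    config = {
        "n_trees": n_trees, "seed": seed,
        "holdout_fraction": holdout_fraction,
        "n_bins": n_bins, "n_repeats": n_repeats,
        "n_rows": int(len(filled)), "n_indicators": int(filled.shape[1]),
    }
    return ImportanceReport(table=table, oob_error=oob_error,
                            tree_oob_error=tree_oob_error, config=config)


def rerun_without(matrix: pd.DataFrame,
                  target: pd.Series,
                  excluded: Sequence[str] = (),
                  **cfg) -> ImportanceReport:
    """Re-estimate importance with some indicators removed.

    With an empty exclusion list this is exactly :func:`rf_importance`;
    excluding every column is an error.
    """
    unknown = [c for c in excluded if c not in matrix.columns]
    if unknown:
        raise ValidationError(f"cannot exclude unknown indicators: {unknown}")
    reduced = matrix.drop(columns=list(excluded))
    return rf_importance(reduced, target, **cfg)
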