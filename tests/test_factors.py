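import itertools

import numpy as np
import pandas as pd
import pytest

import lifeineq as li
from lifeineq.errors import DegenerateInputError, ValidationError


# ---------------------------------------------------------------------------
# screening
# ---------------------------------------------------------------------------

def brute_force_survivor_sets(matrix, completeness_min, corr_max, priority):
    """Enumerate every survivor set reachable by applying the pairwise drop
    rule in any order; the iterative screen must land in this set."""
    comp = matrix.notna().mean(axis=0)
    kept = tuple(c for c in matrix.columns if comp[c] > completeness_min)
    corr = matrix[list(kept)].corr()
    missing = matrix[list(kept)].isna().sum()
    prio = {name: i for i, name in enumerate(priority)}

    def loser(a, b):
        if missing[a] != missing[b]:
            return a if missing[a] > missing[b] else b
        return a if prio[a] > prio[b] else b

    results = set()

    def recurse(alive):
        violating = [
            (a, b) for a, b in itertools.combinations(sorted(alive), 2)
            if pd.notna(corr.loc[a, b]) and abs(corr.loc[a, b]) > corr_max
        ]
        if not violating:
            results.add(frozenset(alive))
            return
        for a, b in violating:
            recurse(alive - {loser(a, b)})

    recurse(frozenset(kept))
    return results


def random_indicator_matrix(rng, n_rows=60):
    """Random 10-15 column matrix with a correlated cluster and varied
    missingness."""
    n_cols = int(rng.integers(10, 16))
    data = {}
    base = rng.normal(size=n_rows)
    cluster = int(rng.integers(2, 4))
    for j in range(n_cols):
        if j < cluster:
            col = base + rng.normal(scale=0.15, size=n_rows)
        else:
            col = rng.normal(size=n_rows)
        n_missing = int(rng.integers(0, 4))
        idx = rng.choice(n_rows, size=n_missing, replace=False)
        col = col.astype(float)
        col[idx] = np.nan
        data[f"ind{j:02d}"] = col
    return pd.DataFrame(data)


class TestScreenIndicators:
    def test_low_completeness_dropped_first(self):
        n = 100
        rng = np.random.default_rng(0)
        df = pd.DataFrame({
            "a": rng.normal(size=n),
            "b": rng.normal(size=n),
            "c": rng.normal(size=n),
        })
        df.loc[:4, "a"] = np.nan      # 95% complete -> kept
        df.loc[:8, "b"] = np.nan      # 91% complete -> kept
        df.loc[:19, "c"] = np.nan     # 80% complete -> dropped
        assert li.screen_indicators(df) == ["a", "b"]

    def test_exactly_at_threshold_dropped(self):
        """'More than 90% complete' is strict: 90.0% does not survive."""
        rng = np.random.default_rng(1)
        df = pd.DataFrame({"a": rng.normal(size=100)})
        df.loc[:9, "a"] = np.nan
        assert li.screen_indicators(df) == []

    def test_correlated_pair_keeps_less_missing(self):
        rng = np.random.default_rng(2)
        base = rng.normal(size=100)
        df = pd.DataFrame({"x": base + rng.normal(scale=0.05, size=100),
                           "y": base.copy()})
        df.loc[:1, "x"] = np.nan   # 2 missing
        df.loc[:4, "y"] = np.nan   # 5 missing
        assert li.screen_indicators(df) == ["x"]

    def test_tie_resolved_by_priority_or_error(self):
        rng = np.random.default_rng(3)
        base = rng.normal(size=50)
        df = pd.DataFrame({"general": base,
                           "specific": base + rng.normal(scale=0.01, size=50)})
        assert li.screen_indicators(df, priority=["general", "specific"]) \
            == ["general"]
        with pytest.raises(ValidationError, match="general"):
            li.screen_indicators(df)

    def test_idempotent(self):
        rng = np.random.default_rng(4)
        df = random_indicator_matrix(rng)
        priority = list(df.columns)
        kept = li.screen_indicators(df, priority=priority)
        again = li.screen_indicators(df[kept], priority=priority)
        assert again == kept

    def test_iterative_screen_lands_in_brute_force_set(self):
        rng = np.random.default_rng(5)
        for _ in range(25):
            df = random_indicator_matrix(rng)
            priority = list(df.columns)
            kept = frozenset(li.screen_indicators(df, priority=priority))
            valid = brute_force_survivor_sets(df, 0.90, 0.85, priority)
            assert kept in valid


class TestAverageWindow:
    def test_inclusive_window_mean(self):
        s = pd.Series({2010: 40.0, 2020: 44.0})
        assert li.average_window(s) == 42.0

    def test_all_missing_window_is_missing_not_error(self):
        s = pd.Series({2012: np.nan, 2015: np.nan})
        assert np.isnan(li.average_window(s))

    def test_out_of_window_values_ignored(self):
        s = pd.Series({2009: 99.0, 2010: 40.0, 2021: 99.0})
        assert li.average_window(s) == 40.0


# ---------------------------------------------------------------------------
# random-forest importance
# ---------------------------------------------------------------------------

def signal_fixture(rng, n_rows=181, n_cols=10, noise=0.05, twin=False):
    """Target is a noisily observed binned function of column ind00 alone;
    with ``twin`` a near-copy ind01 = ind00 + noise is added."""
    cols = {f"ind{j:02d}": rng.uniform(size=n_rows) for j in range(n_cols)}
    if twin:
        cols["ind01"] = cols["ind00"] + rng.normal(scale=0.05, size=n_rows)
    matrix = pd.DataFrame(cols, index=[f"C{i:03d}" for i in range(n_rows)])
    binned = pd.qcut(pd.Series(cols["ind00"], index=matrix.index),
                     4, labels=False).astype(float)
    target = binned + rng.normal(scale=noise, size=n_rows)
    target.name = "hini"
    return matrix, target


class TestRfImportance:
    def test_signal_carrier_dominates(self):
        rng = np.random.default_rng(0)
        matrix, target = signal_fixture(rng)
        report = li.rf_importance(matrix, target, n_trees=200, seed=0)
        assert report.share("ind00") > 90.0
        assert report.table.iloc[0]["indicator"] == "ind00"

    def test_shares_sum_to_100_and_are_nonnegative(self):
        rng = np.random.default_rng(1)
        matrix, target = signal_fixture(rng)
        report = li.rf_importance(matrix, target, n_trees=100, seed=1)
        assert report.table["share_pct"].sum() == pytest.approx(100.0, abs=1e-6)
        assert (report.table["share_pct"] >= 0).all()
        assert 0.0 <= report.oob_error <= 1.0

    def test_null_target_uninformative(self):
        """With a target independent of every indicator, averaged shares
        stay near uniform and holdout error sits near the chance rate
        (n_bins - 1) / n_bins."""
        rng = np.random.default_rng(2)
        n_cols = 8
        shares = []
        errors = []
        for seed in range(20):
            cols = {f"ind{j}": rng.uniform(size=160) for j in range(n_cols)}
            matrix = pd.DataFrame(cols, index=[f"C{i}" for i in range(160)])
            target = pd.Series(rng.uniform(size=160), index=matrix.index)
            rep = li.rf_importance(matrix, target, n_trees=100, seed=seed,
                                   n_repeats=5)
            shares.append(rep.table.set_index("indicator")["share_pct"])
            errors.append(rep.oob_error)
        mean_shares = pd.concat(shares, axis=1).mean(axis=1)
        uniform = 100.0 / n_cols
        assert mean_shares.max() < 3 * uniform
        chance = 3.0 / 4.0
        assert abs(np.mean(errors) - chance) < 0.15

    def test_deterministic_and_row_order_invariant(self):
        rng = np.random.default_rng(3)
        matrix, target = signal_fixture(rng, n_rows=120)
        a = li.rf_importance(matrix, target, n_trees=100, seed=7)
        perm = np.random.default_rng(9).permutation(len(matrix))
        b = li.rf_importance(matrix.iloc[perm], target.iloc[perm],
                             n_trees=100, seed=7)
        pd.testing.assert_frame_equal(a.table, b.table)
        assert a.oob_error == b.oob_error

    def test_constant_target_rejected(self):
        rng = np.random.default_rng(4)
        matrix, _ = signal_fixture(rng, n_rows=40)
        flat = pd.Series(1.0, index=matrix.index)
        with pytest.raises(DegenerateInputError):
            li.rf_importance(matrix, flat)


class TestRerunWithout:
    def test_excluding_dominant_column_redistributes_to_twin(self):
        rng = np.random.default_rng(5)
        matrix, target = signal_fixture(rng, twin=True)
        full = li.rf_importance(matrix, target, n_trees=200, seed=0)
        assert full.table.iloc[0]["indicator"] in {"ind00", "ind01"}
        reduced = li.rerun_without(matrix, target, ["ind00"],
                                   n_trees=200, seed=0)
        assert reduced.table.iloc[0]["indicator"] == "ind01"
        assert reduced.share("ind01") > 50.0

    def test_excluding_nothing_is_identity(self):
        rng = np.random.default_rng(6)
        matrix, target = signal_fixture(rng, n_rows=100)
        a = li.rf_importance(matrix, target, n_trees=100, seed=3)
        b = li.rerun_without(matrix, target, (), n_trees=100, seed=3)
        pd.testing.assert_frame_equal(a.table, b.table)

    def test_excluding_everything_errors(self):
        rng = np.random.default_rng(7)
        matrix, target = signal_fixture(rng, n_rows=40)
        with pytest.raises(ValidationError):
            li.rerun_without(matrix, target, list(matrix.columns))
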