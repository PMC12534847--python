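import numpy as np
import pandas as pd
import pytest

import lifeineq as li


@pytest.fixture(scope="session")
def low_mortality_table() -> li.LifeTable:
    return li.siler_lifetable(li.PRESETS["low-mortality"], location="LOW", year=2019)


@pytest.fixture(scope="session")
def high_infant_table() -> li.LifeTable:
    return li.siler_lifetable(li.PRESETS["high-infant-mortality"],
                              location="HI-INF", year=2019)


@pytest.fixture
def tiny_csv(tmp_path):
    """Minimal well-formed canonical life-table CSV: one location-year."""
    path = tmp_path / "tiny.csv"
    path.write_text(
        "location,year,age,dx\n"
        "AAA,2000,0,500\n"
        "AAA,2000,1,300\n"
        "AAA,2000,2,200\n"
    )
    return path


def random_distribution(rng: np.random.Generator,
                        max_points: int = 120) -> li.DeathDistribution:
    """A random valid death distribution for property/oracle tests."""
    n = int(rng.integers(2, max_points + 1))
    points = np.sort(rng.uniform(0.01, 110.0, size=n))
    while np.any(np.diff(points) <= 0):  # enforce strict increase
        points = np.sort(rng.uniform(0.01, 110.0, size=n))
    weights = rng.dirichlet(np.ones(n))
    weights = weights / weights.sum()
    return li.DeathDistribution(points=points, weights=weights)


def lorenz_gini(dd: li.DeathDistribution) -> float:
    """Independent Gini oracle: trapezoidal area under the Lorenz curve.

    Population ranked from fewest to most years lived; vertices are the
    cumulative population share against the cumulative person-years share.
    """
    order = np.argsort(dd.points)
    w = dd.weights[order]
    x = dd.points[order]
    pop = np.concatenate([[0.0], np.cumsum(w)])
    years = np.concatenate([[0.0], np.cumsum(w * x)])
    years = years / years[-1]
    area = np.sum((pop[1:] - pop[:-1]) * (years[1:] + years[:-1]) / 2.0)
    return 1.0 - 2.0 * area


@pytest.fixture(scope="session")
def synthetic_world():
    """A 236-location synthetic world with metadata, 55 below-threshold.

    Siler parameters vary smoothly across locations so index values span a
    wide range; income groups follow the mortality gradient so that group
    trends are meaningful.
    """
    rng = np.random.default_rng(20210)
    groups = ("low", "lower-middle", "upper-middle", "high")
    tables, meta_rows = [], []
    for i in range(236):
        code = f"C{i:03d}"
        frac = i / 235.0
        # gradient from heavy infant mortality to low mortality
        a1 = 0.45 * (1.0 - frac) ** 2 + 0.002
        c = 0.008 * (1.0 - frac) + 0.0004
        params_by_year = {
            1960: li.SilerParams(a1=min(a1 * 1.6, 0.9), b1=0.9, c=c * 1.5,
                                 a3=3e-5, b3=0.095),
            2021: li.SilerParams(a1=a1, b1=0.9, c=c, a3=2e-5, b3=0.10),
        }
        for year, p in params_by_year.items():
            tables.append(li.siler_lifetable(p, location=code, year=year))
        population = 50_000 if i % 4 == 0 and i < 220 else int(1e6 + i * 1e4)
        meta_rows.append({
            "location": code,
            "population": population,
            "income_group": groups[min(3, int(frac * 4))],
        })
    meta = pd.DataFrame(meta_rows)
    assert (meta["population"] < 200_000).sum() == 55
    return tables, meta
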