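"""National burden projection: stratum rates × population pyramids.

Under the stable-rates assumption, the expected annual number of
fractures in a calendar year is rate_per_1e5 / 1e5 × population, summed
over strata; projecting across years simply swaps the pyramid slice.
Projection scope defaults to ages 50+ even though incidence is estimated
from 40, because burden reporting conventionally starts at 50.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import pandas as pd

from .incidence import AGGREGATE_LABEL, round_half_up
from .registry import AgeBand, SEXES

__all__ = ["read_pyramid", "expected_counts", "project"]


def read_pyramid(path: str | Path) -> pd.DataFrame:
    """Read a population pyramid: columns ``year, sex, age_band, population``.

    UN World Population Prospects CSV exports fit after renaming columns
    to this schema (Time→year, Sex→sex lower-cased, AgeGrp→age_band,
    PopTotal→population with counts multiplied by 1000).
    """
    df = pd.read_csv(path, sep=None, engine="python", comment="#")
    df.columns = [c.strip().lower() for c in df.columns]
    for col in ("year", "sex", "age_band", "population"):
        if col not in df.columns:
            raise ValueError(f"{path} lacks required column {col!r}")
    df["sex"] = df["sex"].astype(str).str.strip().str.lower()
    df["age_band"] = df["age_band"].astype(str).str.strip()
    df["year"] = df["year"].astype(int)
    df["population"] = df["population"].astype(float)
    if (df["population"] < 0).any():
        raise ValueError("population counts must be >= 0")
    return df.set_index(["year", "sex", "age_band"])["population"].sort_index()


def _select_bands(rates: pd.DataFrame, min_age: int) -> list[str]:
    labels = sorted(
        {b for _, b in rates.index if b != AGGREGATE_LABEL},
        key=lambda s: AgeBand.from_label(s).lower,
    )
    return [b for b in labels if AgeBand.from_label(b).lower >= min_age]


def expected_counts(
    rates: pd.DataFrame,
    pyramid: pd.Series,
    year: int,
    min_age: int = 50,
) -> pd.DataFrame:
    """Expected annual fracture counts by (sex, age band) for one year.

    ``rates`` is an assembled incidence table (annual rates per 100,000);
    ``pyramid`` a Series indexed by ``(year, sex, age_band)``. A stratum
    with a rate but no population row for the year is fatal. Totals per
    sex and overall are appended as ``total`` rows.
    """
    if year not in pyramid.index.get_level_values("year"):
        raise KeyError(f"pyramid has no rows for year {year}")
    slice_ = pyramid.xs(year, level="year")
    bands = _select_bands(rates, min_age)
    rows = []
    for sex in SEXES:
        for band in bands:
            if (sex, band) not in slice_.index:
                raise KeyError(f"pyramid year {year} missing stratum ({sex}, {band})")
            rate = float(rates.loc[(sex, band), "rate_per_1e5"])
            pop = float(slice_.loc[(sex, band)])
            rows.append((sex, band, pop, rate, rate / 1e5 * pop))
    out = pd.DataFrame(
        rows, columns=["sex", "age_band", "population", "rate_per_1e5", "expected"]
    ).set_index(["sex", "age_band"])
    totals = out.groupby("sex")["expected"].sum()
    for sex in SEXES:
        out.loc[(sex, "total"), ["population", "rate_per_1e5", "expected"]] = [
            float(out.xs(sex, level="sex")["population"].drop("total", errors="ignore").sum()),
            float("nan"),
            float(totals[sex]),
        ]
    return out


def project(
    rates: pd.DataFrame,
    pyramid: pd.Series,
    years: Sequence[int],
    min_age: int = 50,
) -> pd.DataFrame:
    """Annual expected counts per calendar year with percent change vs baseline.

    Returns a frame indexed by year with columns ``men, women, total,
    increase_pct`` (full precision; report rounding is a display choice).
    The first listed year is the baseline for the percent increase.
    """
    years = list(years)
    if not years:
        raise ValueError("years must be non-empty")
    rows = []
    for year in years:
        ec = expected_counts(rates, pyramid, year, min_age=min_age)
        men = float(ec.loc[("male", "total"), "expected"])
        women = float(ec.loc[("female", "total"), "expected"])
        rows.append((year, men, women, men + women))
    out = pd.DataFrame(rows, columns=["year", "men", "women", "total"]).set_index("year")
    base = out["total"].iloc[0]
    out["increase_pct"] = (out["total"] / base - 1.0) * 100.0
    return out


def render_projection(table: pd.DataFrame) -> pd.DataFrame:
    """Report view: integer counts, integer percent increase (half-up)."""
    out = pd.DataFrame(index=table.index)
    for col in ("men", "women", "total"):
        out[col] = [round_half_up(v) for v in table[col]]
    out["increase_pct"] = [round_half_up(v) for v in table["increase_pct"]]
    return out
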