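"""Incidence rates per 100,000 person-years with exact Poisson confidence intervals.

Stratum event counts are modelled as Poisson with mean λ·PY. The interval
is the Garwood exact chi-square interval,

    low  = χ²(α/2; 2k) / 2 / PY,      (0 when k = 0)
    high = χ²(1 − α/2; 2k + 2) / 2 / PY,

which is conservative (coverage ≥ nominal) and remains valid at the small
counts that occur in the youngest strata. Rounding is a display concern
only: all computation and serialisation keep full precision, and the
report layer rounds half-up to integers (rates, CI bounds) or one decimal
(ratios).
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .registry import AgeBand, SEXES

__all__ = [
    "point_rate",
    "exact_poisson_ci",
    "assemble_table",
    "aggregate_bands",
    "female_male_ratio",
    "round_half_up",
    "AGGREGATE_LABEL",
]

#: label of the per-sex all-band aggregate row in an assembled table
AGGREGATE_LABEL = "40+"


def round_half_up(x, decimals: int = 0):
    """Round half away from zero (the convention used in report tables)."""
    factor = 10.0 ** decimals
    x = np.asarray(x, dtype=float)
    out = np.floor(np.abs(x) * factor + 0.5) / factor * np.sign(x)
    if out.ndim == 0:
        val = float(out)
        return int(val) if decimals <= 0 else val
    return out if decimals > 0 else out.astype(int)


def point_rate(events, person_years):
    """Incidence per 100,000 person-years: events / PY × 1e5 (full precision)."""
    events = np.asarray(events, dtype=float)
    py = np.asarray(person_years, dtype=float)
    if np.any(py <= 0):
        raise ValueError("person_years must be > 0")
    if np.any(events < 0):
        raise ValueError("events must be >= 0")
    out = events / py * 1e5
    return float(out) if out.ndim == 0 else out


def exact_poisson_ci(events, person_years, level: float = 0.95):
    """Garwood exact 95% (by default) CI for the rate, per 100,000 person-years.

    The lower bound is exactly 0 when no events were observed.
    """
    if not 0 < level < 1:
        raise ValueError(f"level must be in (0, 1), got {level}")
    events = np.asarray(events, dtype=float)
    py = np.asarray(person_years, dtype=float)
    if np.any(py <= 0):
        raise ValueError("person_years must be > 0")
    if np.any(events < 0):
        raise ValueError("events must be >= 0")
    alpha = 1.0 - level
    with np.errstate(invalid="ignore"):
        low = np.where(events == 0, 0.0, stats.chi2.ppf(alpha / 2, 2 * events) / 2)
    high = stats.chi2.ppf(1 - alpha / 2, 2 * events + 2) / 2
    low = low / py * 1e5
    high = high / py * 1e5
    if low.ndim == 0:
        return float(low), float(high)
    return low, high


def assemble_table(
    counts: pd.Series,
    exposure: pd.DataFrame,
    level: float = 0.95,
    aggregate_label: str = AGGREGATE_LABEL,
) -> pd.DataFrame:
    """Combine stratum counts and person-years into a full incidence table.

    Parameters
    ----------
    counts
        Events indexed by ``(sex, age_band)``.
    exposure
        Frame with a ``person_years`` column on the same index.

    Returns
    -------
    pandas.DataFrame
        Indexed by ``(sex, age_band)`` with columns ``events, person_years,
        rate_per_1e5, ci_low_per_1e5, ci_high_per_1e5``; one aggregate row
        per sex (labelled ``40+`` by default) pooling all bands.

    A stratum present in counts but absent from exposure (or vice versa)
    is fatal, naming the stratum.
    """
    missing = counts.index.difference(exposure.index)
    if len(missing):
        raise KeyError(f"exposure missing for strata {list(missing)}")
    extra = exposure.index.difference(counts.index)
    if len(extra):
        raise KeyError(f"counts missing for strata {list(extra)}")

    py = exposure["person_years"].reindex(counts.index)
    rows = []
    for sex in SEXES:
        ev_s = counts.xs(sex, level="sex")
        py_s = py.xs(sex, level="sex")
        for band in ev_s.index:
            rows.append((sex, band, float(ev_s[band]), float(py_s[band])))
        rows.append((sex, aggregate_label, float(ev_s.sum()), float(py_s.sum())))
    table = pd.DataFrame(rows, columns=["sex", "age_band", "events", "person_years"])
    table = table.set_index(["sex", "age_band"])
    table["rate_per_1e5"] = point_rate(table["events"], table["person_years"])
    low, high = exact_poisson_ci(table["events"], table["person_years"], level=level)
    table["ci_low_per_1e5"] = low
    table["ci_high_per_1e5"] = high
    return table


def aggregate_bands(
    table: pd.DataFrame,
    bands: Sequence[str],
    label: str,
    level: float = 0.95,
) -> pd.DataFrame:
    """Pool a union of bands (e.g. everything below 65) into one row per sex."""
    rows = []
    for sex in SEXES:
        sub = table.loc[[(sex, b) for b in bands]]
        ev, py = float(sub["events"].sum()), float(sub["person_years"].sum())
        lo, hi = exact_poisson_ci(ev, py, level=level)
        rows.append((sex, label, ev, py, point_rate(ev, py), lo, hi))
    out = pd.DataFrame(
        rows,
        columns=["sex", "age_band", "events", "person_years", "rate_per_1e5",
                 "ci_low_per_1e5", "ci_high_per_1e5"],
    )
    return out.set_index(["sex", "age_band"])


def female_male_ratio(
    table: pd.DataFrame, bands: Sequence[str] | None = None
) -> dict[str, float]:
    """Female/male ratio over a band union, in two labelled variants.

    ``count_ratio`` divides total female by total male events;
    ``rate_ratio`` divides the pooled (PY-weighted) female rate by the
    pooled male rate. They differ whenever the sexes' person-years differ.
    A zero male denominator makes the corresponding variant NaN.
    """
    if bands is None:
        bands = sorted({b for _, b in table.index if b != AGGREGATE_LABEL})
    f = table.loc[[("female", b) for b in bands]]
    m = table.loc[[("male", b) for b in bands]]
    f_ev, m_ev = float(f["events"].sum()), float(m["events"].sum())
    f_py, m_py = float(f["person_years"].sum()), float(m["person_years"].sum())
    count_ratio = f_ev / m_ev if m_ev > 0 else math.nan
    rate_ratio = (f_ev / f_py) / (m_ev / m_py) if m_ev > 0 else math.nan
    return {"count_ratio": count_ratio, "rate_ratio": rate_ratio}
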