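"""Packaged reference data.

The Stara Zagora catchment surveillance (Southern Bulgaria, calendar
years 2015–2017): hip-fracture admissions after 90-day same-site
deduplication, and insurance-corrected person-years of the catchment
population, by sex and 5-year age band from 40. The "person_years"
column is the insured population summed over the three observation
years (persons × years), not a headcount — the published rates only
reproduce under that reading.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["load_catchment_incidence"]

# (sex, band, fractures over 3 years, person-years)
_CATCHMENT = [
    ("male", "40-44", 9, 28257),
    ("male", "45-49", 14, 27267),
    ("male", "50-54", 18, 26372),
    ("male", "55-59", 26, 27646),
    ("male", "60-64", 35, 27889),
    ("male", "65-69", 37, 27903),
    ("male", "70-74", 44, 20886),
    ("male", "75-79", 54, 15632),
    ("male", "80-84", 54, 11131),
    ("male", "85-89", 53, 4832),
    ("male", "90+", 23, 1292),
    ("female", "40-44", 3, 28069),
    ("female", "45-49", 7, 26998),
    ("female", "50-54", 12, 27768),
    ("female", "55-59", 24, 30383),
    ("female", "60-64", 36, 34907),
    ("female", "65-69", 60, 38011),
    ("female", "70-74", 95, 30842),
    ("female", "75-79", 189, 24652),
    ("female", "80-84", 261, 19278),
    ("female", "85-89", 247, 9247),
    ("female", "90+", 83, 2862),
]

#: published rounded rates (per 100,000 PY) and 95% CI bounds, for cross-checks
PUBLISHED_ROUNDED = {
    ("male", "40+"): (167, 151, 186),
    ("female", "40+"): (373, 350, 396),
    ("female", "90+"): (2900, 2310, 3595),
}


def load_catchment_incidence() -> pd.DataFrame:
    """Events and person-years of the 2015–2017 catchment surveillance.

    Returns a DataFrame indexed by ``(sex, age_band)`` with integer
    ``events`` and ``person_years`` columns — the inputs from which the
    incidence table (rates + exact Poisson CIs) is recomputed, never the
    published rates themselves.
    """
    df = pd.DataFrame(_CATCHMENT, columns=["sex", "age_band", "events", "person_years"])
    return df.set_index(["sex", "age_band"])
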