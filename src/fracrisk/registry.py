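"""Registry ingest: parse, validate, deduplicate and stratify hip-fracture admissions.

The operational case definition is an inpatient admission coded ICD-10
S72.0 (femoral neck), S72.1 (pertrochanteric) or S72.2 (subtrochanteric).
Repeat admissions for the same fracture site — identified by an identical
ICD-10 code for the same patient — within a configurable window (default
90 days) are treated as care episodes for one fracture and collapsed.

Denominators are person-years of the insured catchment population:
``raw_population × coverage_fraction × years_observed`` per sex and
5-year age band, because only insured individuals can appear in the
insurance-fund registry.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "HIP_CODES",
    "SEXES",
    "AgeBand",
    "FractureRecord",
    "default_bands",
    "band_label_for_age",
    "parse_registry",
    "deduplicate",
    "stratify",
    "build_exposure",
    "read_stratum_column",
]

#: ICD-10 codes that define a hip fracture.
HIP_CODES = ("S72.0", "S72.1", "S72.2")

SEXES = ("male", "female")

_SEX_ALIASES = {
    "m": "male", "male": "male", "man": "male",
    "f": "female", "female": "female", "woman": "female",
}


@dataclass(frozen=True, order=True)
class AgeBand:
    """A 5-year (or terminal open) age band, e.g. 40–44 or 90+.

    ``upper`` is inclusive; ``None`` marks the open-ended terminal band.
    """

    lower: int
    upper: int | None = None

    def __post_init__(self) -> None:
        if self.lower < 0:
            raise ValueError(f"age band lower bound must be >= 0, got {self.lower}")
        if self.upper is not None and self.upper < self.lower:
            raise ValueError(f"age band upper {self.upper} < lower {self.lower}")

    @property
    def label(self) -> str:
        return f"{self.lower}+" if self.upper is None else f"{self.lower}-{self.upper}"

    @property
    def width(self) -> float:
        return float("inf") if self.upper is None else self.upper - self.lower + 1

    def contains(self, age: int) -> bool:
        return age >= self.lower and (self.upper is None or age <= self.upper)

    @classmethod
    def from_label(cls, label: str) -> "AgeBand":
        label = label.strip()
        if label.endswith("+"):
            return cls(int(label[:-1]), None)
        lo, _, hi = label.partition("-")
        if not hi:
            raise ValueError(f"unparseable age-band label {label!r}")
        return cls(int(lo), int(hi))


def default_bands(start: int = 40, stop: int = 90) -> list[AgeBand]:
    """Contiguous 5-year bands from ``start`` with an open terminal band at ``stop``."""
    bands = [AgeBand(lo, lo + 4) for lo in range(start, stop, 5)]
    bands.append(AgeBand(stop, None))
    return bands


def band_label_for_age(age: float, bands: Sequence[AgeBand]) -> str:
    for b in bands:
        if b.contains(int(age)):
            return b.label
    raise KeyError(f"age {age} not covered by the band scheme")


@dataclass(frozen=True)
class FractureRecord:
    """One line-listed registry admission."""

    patient_id: str
    sex: str
    age_years: int
    admission_date: dt.date
    icd_code: str
    facility_id: str | None = None

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise ValueError(f"sex must be one of {SEXES}, got {self.sex!r}")
        if self.icd_code not in HIP_CODES:
            raise ValueError(f"icd_code must be one of {HIP_CODES}, got {self.icd_code!r}")
        if self.age_years < 0:
            raise ValueError("age_years must be >= 0")


_REQUIRED_COLUMNS = ("patient_id", "sex", "age", "admission_date", "icd_code")


def parse_registry(
    path: str | Path,
    window: tuple[dt.date, dt.date],
) -> tuple[list[FractureRecord], pd.DataFrame]:
    """Parse a delimited registry extract into validated :class:`FractureRecord` rows.

    Parameters
    ----------
    path
        Comma- or tab-delimited text with header columns ``patient_id, sex,
        age, admission_date, icd_code`` (``facility_id`` optional); the
        delimiter is sniffed.
    window
        Inclusive observation window ``(start, end)``; admissions outside it
        are rejected.

    Returns
    -------
    records, rejected
        Accepted records, and a DataFrame of rejected input rows with a
        ``reason`` code column (``non_hip_code``, ``out_of_window``,
        ``bad_date``, ``bad_sex``, ``bad_age``, ``missing_field``).

    An unreadable file or missing required column raises; malformed *rows*
    are logged, not fatal.
    """
    path = Path(path)
    try:
        raw = pd.read_csv(path, sep=None, engine="python", dtype=str)
    except OSError as exc:
        raise OSError(f"cannot read registry file {path}: {exc}") from exc
    raw.columns = [c.strip().lower() for c in raw.columns]
    missing = [c for c in _REQUIRED_COLUMNS if c not in raw.columns]
    if missing:
        raise ValueError(f"registry file {path} lacks required columns {missing}")

    start, end = window
    if end < start:
        raise ValueError(f"observation window end {end} precedes start {start}")

    records: list[FractureRecord] = []
    rejected: list[dict] = []

    def reject(row: pd.Series, reason: str) -> None:
        d = row.to_dict()
        d["reason"] = reason
        rejected.append(d)

    for _, row in raw.iterrows():
        if any(pd.isna(row.get(c)) or str(row.get(c)).strip() == "" for c in _REQUIRED_COLUMNS):
            reject(row, "missing_field")
            continue
        code = str(row["icd_code"]).strip().upper()
        if code not in HIP_CODES:
            reject(row, "non_hip_code")
            continue
        sex = _SEX_ALIASES.get(str(row["sex"]).strip().lower())
        if sex is None:
            reject(row, "bad_sex")
            continue
        try:
            date = dt.date.fromisoformat(str(row["admission_date"]).strip())
        except ValueError:
            reject(row, "bad_date")
            continue
        try:
            age = int(str(row["age"]).strip())
            if age < 0:
                raise ValueError
        except ValueError:
            reject(row, "bad_age")
            continue
        if not (start <= date <= end):
            reject(row, "out_of_window")
            continue
        fac = row.get("facility_id")
        records.append(
            FractureRecord(
                patient_id=str(row["patient_id"]).strip(),
                sex=sex,
                age_years=age,
                admission_date=date,
                icd_code=code,
                facility_id=None if pd.isna(fac) else str(fac).strip(),
            )
        )
    reject_df = pd.DataFrame(rejected, columns=list(raw.columns) + ["reason"])
    return records, reject_df


def deduplicate(
    records: Iterable[FractureRecord], window_days: int = 90
) -> list[FractureRecord]:
    """Collapse readmissions for the same fracture site within ``window_days``.

    Within each ``(patient_id, icd_code)`` group, admissions are scanned in
    date order; an admission is dropped when it falls within ``window_days``
    (inclusive) of the most recently *retained* admission of that group, so
    the window rolls forward along a chain of readmissions rather than
    collapsing the whole chain onto the first date. The earliest admission
    of every group is always retained. Output order is deterministic:
    ``(patient_id, admission_date, icd_code)``.
    """
    if window_days < 0:
        raise ValueError(f"window_days must be >= 0, got {window_days}")
    groups: dict[tuple[str, str], list[FractureRecord]] = {}
    for r in records:
        groups.setdefault((r.patient_id, r.icd_code), []).append(r)
    kept: list[FractureRecord] = []
    for recs in groups.values():
        recs.sort(key=lambda r: r.admission_date)
        last_retained: dt.date | None = None
        for r in recs:
            if last_retained is None or (r.admission_date - last_retained).days > window_days:
                kept.append(r)
                last_retained = r.admission_date
    kept.sort(key=lambda r: (r.patient_id, r.admission_date, r.icd_code))
    return kept


def stratify(
    records: Iterable[FractureRecord],
    bands: Sequence[AgeBand] | None = None,
) -> tuple[pd.Series, int]:
    """Count records per (sex, age band).

    Records younger than the lowest band are excluded; the count of
    exclusions is returned alongside the table so callers can audit
    conservation (counts sum + exclusions = input size).

    Returns
    -------
    counts : pandas.Series
        Integer counts indexed by ``(sex, age_band)`` with every stratum
        present (zeros included).
    n_underage : int
    """
    from collections import Counter

    bands = list(bands) if bands is not None else default_bands()
    floor_age = min(b.lower for b in bands)
    index = pd.MultiIndex.from_product(
        [list(SEXES), [b.label for b in bands]], names=["sex", "age_band"]
    )
    tally: Counter = Counter()
    n_underage = 0
    for r in records:
        if r.age_years < floor_age:
            n_underage += 1
            continue
        tally[(r.sex, band_label_for_age(r.age_years, bands))] += 1
    counts = pd.Series([tally.get(k, 0) for k in index], index=index, name="events")
    return counts, n_underage


def build_exposure(
    raw_population: pd.Series,
    coverage: pd.Series,
    years_observed: float,
) -> pd.DataFrame:
    """Insurance-corrected person-year denominators per stratum.

    ``person_years = raw_population × coverage_fraction × years_observed``.
    Both inputs are Series indexed by ``(sex, age_band)``; coverage varies
    freely by stratum. A stratum present in one input but not the other is
    a fatal error naming the stratum.
    """
    if years_observed <= 0:
        raise ValueError(f"years_observed must be > 0, got {years_observed}")
    missing_cov = raw_population.index.difference(coverage.index)
    if len(missing_cov):
        raise KeyError(f"coverage missing for strata {list(missing_cov)}")
    missing_pop = coverage.index.difference(raw_population.index)
    if len(missing_pop):
        raise KeyError(f"population missing for strata {list(missing_pop)}")
    pop = raw_population.astype(float)
    cov = coverage.astype(float).reindex(pop.index)
    if (pop <= 0).any():
        bad = list(pop.index[pop <= 0])
        raise ValueError(f"non-positive population in strata {bad}")
    if ((cov <= 0) | (cov > 1)).any():
        bad = list(cov.index[(cov <= 0) | (cov > 1)])
        raise ValueError(f"coverage outside (0, 1] in strata {bad}")
    out = pd.DataFrame(
        {
            "raw_population": pop,
            "coverage_fraction": cov,
            "years_observed": years_observed,
            "person_years": pop * cov * years_observed,
        }
    )
    out.index.names = ["sex", "age_band"]
    return out


def read_stratum_column(path: str | Path, value_col: str) -> pd.Series:
    """Read a delimited file keyed by ``sex, age_band`` into a Series.

    Age-band labels follow the ``"40-44" … "90+"`` convention; sex labels
    are normalised to ``male``/``female``.
    """
    df = pd.read_csv(path, sep=None, engine="python", comment="#")
    df.columns = [c.strip().lower() for c in df.columns]
    for col in ("sex", "age_band", value_col):
        if col not in df.columns:
            raise ValueError(f"{path} lacks required column {col!r}")
    sex = df["sex"].astype(str).str.strip().str.lower().map(_SEX_ALIASES)
    if sex.isna().any():
        raise ValueError(f"{path} has unrecognised sex labels")
    idx = pd.MultiIndex.from_arrays(
        [sex, df["age_band"].astype(str).str.strip()], names=["sex", "age_band"]
    )
    return pd.Series(df[value_col].astype(float).to_numpy(), index=idx, name=value_col)
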