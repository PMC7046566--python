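"""Synthetic inputs with known ground truth for every pipeline stage.

The generator emulates a 3-year insurance-fund catchment registry:
stratum event counts are Poisson with mean true_rate × insured
person-years, each event becomes an admission line with a uniform date
in the observation window, and a configurable fraction of records gains
an injected same-site readmission 10–80 days later — inside the 90-day
deduplication window by construction, so deduplication must remove
every injected duplicate exactly. Uninsured individuals generate no
records, which is why the true denominators are coverage-corrected.

Mortality is Gompertz–Makeham, h(x) = a + b·cˣ: a is background
(age-independent) mortality, b the senescent level and c the slope.
Defaults are calibrated to mid-2010s South-East-European life
expectancy at birth (≈78 y women, ≈71 y men). Fracture-rate defaults
are calibrated to the packaged catchment surveillance so synthetic
output is magnitude-realistic; they are a calibration, not a national
estimate. Population pyramids drift geometrically per band to emulate
an aging medium-variant projection.

All generators are pure functions of (TruthBundle, seed): regeneration
with the same truth file is byte-identical.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .datasets import load_catchment_incidence
from .registry import AgeBand, SEXES, default_bands

__all__ = [
    "TruthBundle",
    "RegistryDraw",
    "default_truth",
    "gen_registry",
    "gen_life_table",
    "gen_pyramid",
    "gen_all",
]

_SUBSTREAM = {"registry": 11, "duplicates": 23, "pyramid": 37}

#: Gompertz–Makeham (a, b, c) calibrated to e0 ≈ 78.0 (women) / 71.1 (men)
DEFAULT_GOMPERTZ = {
    "female": (3.0e-4, 1.55e-5, 1.11),
    "male": (9.0e-4, 4.85e-5, 1.10),
}


def _rng(seed: int, name: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((int(seed), _SUBSTREAM[name])))


@dataclass(frozen=True)
class TruthBundle:
    """Ground truth behind one synthetic dataset.

    ``true_rates`` are annual fracture rates per 100,000 person-years and
    ``coverage`` insurance fractions in (0, 1], both indexed by
    ``(sex, age_band)``; ``gompertz`` maps sex to (a, b, c).
    """

    true_rates: pd.Series
    coverage: pd.Series
    gompertz: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_GOMPERTZ)
    )
    duplicate_injection_rate: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.duplicate_injection_rate <= 1:
            raise ValueError("duplicate_injection_rate must be in [0, 1]")
        if (self.true_rates < 0).any():
            raise ValueError("true rates must be >= 0")
        if ((self.coverage <= 0) | (self.coverage > 1)).any():
            raise ValueError("coverage must lie in (0, 1]")
        for sex, (a, b, c) in self.gompertz.items():
            if a < 0 or b <= 0 or c <= 1:
                raise ValueError(
                    f"Gompertz-Makeham for {sex} needs a >= 0, b > 0, c > 1; got {(a, b, c)}"
                )

    def to_yaml(self, path: str | Path) -> None:
        doc = {
            "seed": int(self.seed),
            "duplicate_injection_rate": float(self.duplicate_injection_rate),
            "gompertz": {s: [float(v) for v in p] for s, p in self.gompertz.items()},
            "true_rates": {
                f"{s}|{b}": float(v) for (s, b), v in self.true_rates.items()
            },
            "coverage": {f"{s}|{b}": float(v) for (s, b), v in self.coverage.items()},
        }
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "TruthBundle":
        doc = yaml.safe_load(Path(path).read_text())

        def series(d: dict) -> pd.Series:
            idx = pd.MultiIndex.from_tuples(
                [tuple(k.split("|")) for k in d], names=["sex", "age_band"]
            )
            return pd.Series(list(d.values()), index=idx, dtype=float)

        return cls(
            true_rates=series(doc["true_rates"]),
            coverage=series(doc["coverage"]),
            gompertz={s: tuple(p) for s, p in doc["gompertz"].items()},
            duplicate_injection_rate=doc["duplicate_injection_rate"],
            seed=doc["seed"],
        )


def default_truth(seed: int = 0, duplicate_injection_rate: float = 0.05) -> TruthBundle:
    """Truth calibrated to the packaged catchment surveillance.

    Rates are the full-precision events/person-years of the catchment
    table; insurance coverage rises gently with age (older residents are
    more completely insured) around the overall ≈0.81 level.
    """
    cat = load_catchment_incidence()
    rates = cat["events"] / cat["person_years"] * 1e5
    rates.name = "rate_per_1e5"
    cov = {}
    for sex, band in cat.index:
        b = AgeBand.from_label(band)
        mid = b.lower + 2.5 if b.upper is not None else 95.0
        cov[(sex, band)] = min(0.70 + 0.002 * (mid - 40) + (0.02 if sex == "female" else 0.0), 0.95)
    coverage = pd.Series(cov, name="coverage_fraction")
    coverage.index.names = ["sex", "age_band"]
    return TruthBundle(
        true_rates=rates,
        coverage=coverage,
        duplicate_injection_rate=duplicate_injection_rate,
        seed=seed,
    )


def default_population(truth: TruthBundle, years: int = 3) -> pd.Series:
    """Raw catchment population consistent with the packaged person-years."""
    cat = load_catchment_incidence()
    pop = cat["person_years"] / (truth.coverage.reindex(cat.index) * years)
    pop.name = "raw_population"
    return pop


@dataclass(frozen=True)
class RegistryDraw:
    """A generated registry plus its bookkeeping."""

    frame: pd.DataFrame  # columns patient_id, sex, age, admission_date, icd_code, facility_id
    true_counts: pd.Series  # pre-duplicate event counts per (sex, age_band)
    n_duplicates: int
    window: tuple[dt.date, dt.date]
    truth: TruthBundle


def gen_registry(
    truth: TruthBundle,
    years: int = 3,
    population: pd.Series | None = None,
    start: dt.date = dt.date(2015, 1, 1),
) -> RegistryDraw:
    """Draw a line-listed registry under the truth's rates.

    Per stratum the event count is Poisson(rate/1e5 × population ×
    coverage × years); events get uniform admission dates inside the
    window, uniform ages within their band (90+ → 90–99) and uniform hip
    ICD codes. Then ``duplicate_injection_rate`` of the records gain a
    same-patient same-code readmission 10–80 days later (clamped to the
    window end, hence always within the 90-day exclusion window).
    """
    if years <= 0:
        raise ValueError("years must be > 0")
    if population is None:
        population = default_population(truth, years)
    rng = _rng(truth.seed, "registry")
    dup_rng = _rng(truth.seed, "duplicates")
    end = dt.date(start.year + years, start.month, start.day) - dt.timedelta(days=1)
    n_days = (end - start).days + 1

    rows: list[dict] = []
    counts: dict[tuple[str, str], int] = {}
    pid = 0
    for (sex, band) in truth.true_rates.index:
        rate = float(truth.true_rates[(sex, band)])
        py = float(population[(sex, band)]) * float(truth.coverage[(sex, band)]) * years
        n = int(rng.poisson(rate / 1e5 * py))
        counts[(sex, band)] = n
        b = AgeBand.from_label(band)
        hi = b.upper if b.upper is not None else b.lower + 9
        ages = rng.integers(b.lower, hi + 1, size=n)
        offsets = rng.integers(0, n_days, size=n)
        codes = rng.choice(["S72.0", "S72.1", "S72.2"], size=n)
        for age, off, code in zip(ages, offsets, codes):
            pid += 1
            rows.append(
                {
                    "patient_id": f"P{pid:07d}",
                    "sex": sex,
                    "age": int(age),
                    "admission_date": (start + dt.timedelta(days=int(off))).isoformat(),
                    "icd_code": str(code),
                    "facility_id": "H1",
                }
            )
    n_dup = 0
    if rows and truth.duplicate_injection_rate > 0:
        take = dup_rng.random(len(rows)) < truth.duplicate_injection_rate
        gaps = dup_rng.integers(10, 81, size=len(rows))
        for row, t, gap in zip(list(rows), take, gaps):
            if not t:
                continue
            base = dt.date.fromisoformat(row["admission_date"])
            # clamp to the window end: the gap can only shrink, so the
            # readmission always stays inside the 90-day exclusion window
            dup_date = min(base + dt.timedelta(days=int(gap)), end)
            dup = dict(row)
            dup["admission_date"] = dup_date.isoformat()
            rows.append(dup)
            n_dup += 1
    frame = pd.DataFrame(
        rows,
        columns=["patient_id", "sex", "age", "admission_date", "icd_code", "facility_id"],
    ).sort_values(["patient_id", "admission_date", "icd_code"], kind="stable")
    frame = frame.reset_index(drop=True)
    idx = pd.MultiIndex.from_tuples(list(counts), names=["sex", "age_band"])
    true_counts = pd.Series(list(counts.values()), index=idx, name="events")
    return RegistryDraw(
        frame=frame, true_counts=true_counts, n_duplicates=n_dup,
        window=(start, end), truth=truth,
    )


def gen_life_table(
    params: dict[str, tuple[float, float, float]] | None = None,
    bands: Sequence[AgeBand] | None = None,
    terminal_age: int = 110,
) -> pd.DataFrame:
    """Band-level Gompertz–Makeham death hazards, h = a + b·cˣ at band midpoints.

    The terminal open band uses the midpoint of [lower, terminal_age].
    Returns a frame with columns ``sex, age_band, hazard``.
    """
    params = dict(DEFAULT_GOMPERTZ) if params is None else params
    bands = list(bands) if bands is not None else default_bands()
    rows = []
    for sex in SEXES:
        a, b, c = params[sex]
        if a < 0 or b <= 0 or c <= 1:
            raise ValueError(f"invalid Gompertz-Makeham parameters for {sex}: {(a, b, c)}")
        for band in bands:
            hi = band.upper + 1 if band.upper is not None else terminal_age
            mid = (band.lower + hi) / 2.0
            rows.append((sex, band.label, a + b * c**mid))
    return pd.DataFrame(rows, columns=["sex", "age_band", "hazard"])


def gen_pyramid(
    base: pd.Series,
    years: Sequence[int],
    drift,
) -> pd.DataFrame:
    """Geometric per-band population drift across calendar years.

    ``base`` is population indexed by ``(sex, age_band)`` for the first
    listed year; ``drift`` is an annual growth rate (scalar, or a Series
    on the same index). Returns long-format ``year, sex, age_band,
    population`` rows.
    """
    years = list(years)
    if (base <= 0).any():
        raise ValueError("base populations must be > 0")
    if np.isscalar(drift):
        drift = pd.Series(float(drift), index=base.index)
    drift = drift.reindex(base.index)
    if drift.isna().any():
        raise ValueError("drift missing for some strata")
    rows = []
    for year in years:
        dt_years = year - years[0]
        pop = base * (1.0 + drift) ** dt_years
        for (sex, band), v in pop.items():
            rows.append((year, sex, band, float(v)))
    return pd.DataFrame(rows, columns=["year", "sex", "age_band", "population"])


def gen_all(
    truth: TruthBundle,
    out_dir: str | Path,
    years: int = 3,
    pyramid_years: Sequence[int] = (2015, 2020, 2030, 2040, 2050),
) -> dict[str, Path]:
    """Materialise a complete self-consistent input set plus the truth file.

    Writes registry.csv, population.csv, coverage.csv, life_table.csv,
    pyramid.csv and truth.yaml into ``out_dir`` and returns their paths.
    The pyramid scales the catchment-consistent base population to a
    national magnitude and ages it: bands 70+ grow 1%/year, bands below
    shrink 0.5%/year.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    draw = gen_registry(truth, years=years)
    paths = {"registry": out / "registry.csv", "population": out / "population.csv",
             "coverage": out / "coverage.csv", "life_table": out / "life_table.csv",
             "pyramid": out / "pyramid.csv", "truth": out / "truth.yaml"}
    draw.frame.to_csv(paths["registry"], index=False)
    pop = default_population(truth, years)
    pop.reset_index().to_csv(paths["population"], index=False)
    truth.coverage.reset_index().to_csv(paths["coverage"], index=False)
    gen_life_table(truth.gompertz).to_csv(paths["life_table"], index=False)
    drift = pd.Series(
        [0.01 if AgeBand.from_label(b).lower >= 70 else -0.005 for _, b in pop.index],
        index=pop.index,
    )
    national_base = pop * 20.0  # catchment ≈ 5% of the national population
    gen_pyramid(national_base, list(pyramid_years), drift).to_csv(
        paths["pyramid"], index=False
    )
    truth.to_yaml(paths["truth"])
    return paths
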