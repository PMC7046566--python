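"""Piecewise-constant annual hazard curves by sex and age band.

An incidence table becomes a fracture hazard curve by unit conversion
(rate per 100,000 person-years / 1e5 = events per person-year); a life
table becomes a death hazard curve either directly (mx-style hazards) or
via h = −ln(1 − qx)/Δ for annual death probabilities qx. Hazards are
constant within each band — no smoothing — matching the 5-year
granularity of the incidence estimates, and the terminal open band is
extended as a constant to ``terminal_age`` (default 110), beyond which
survival is negligible.

Major-osteoporotic-fracture (MOF: hip, clinical spine, forearm, humerus)
hazards are imputed from hip hazards by configurable age- and sex-specific
MOF:hip ratios; the ratio values are an input, never built in.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .registry import AgeBand, SEXES, band_label_for_age, default_bands

__all__ = [
    "HazardCurve",
    "incidence_to_hazard",
    "impute_mof",
    "load_life_table",
    "qx_to_hazard",
    "DEFAULT_TERMINAL_AGE",
]

DEFAULT_TERMINAL_AGE = 110


@dataclass(frozen=True)
class HazardCurve:
    """Piecewise-constant hazard: ``hazards[i]`` applies on ``[ages[i], ages[i+1])``.

    ``ages`` has one more entry than ``hazards``, is strictly increasing,
    and ends at the curve's terminal age. Hazards are per person-year.
    """

    sex: str
    kind: str  # hip_fracture | major_osteoporotic | death
    ages: np.ndarray
    hazards: np.ndarray

    def __post_init__(self) -> None:
        ages = np.asarray(self.ages, dtype=float)
        hz = np.asarray(self.hazards, dtype=float)
        object.__setattr__(self, "ages", ages)
        object.__setattr__(self, "hazards", hz)
        if self.sex not in SEXES:
            raise ValueError(f"sex must be one of {SEXES}")
        if ages.ndim != 1 or hz.ndim != 1 or len(ages) != len(hz) + 1:
            raise ValueError("ages must have exactly one more entry than hazards")
        if not np.all(np.diff(ages) > 0):
            raise ValueError("age breakpoints must be strictly increasing")
        if not np.all(np.isfinite(hz)) or np.any(hz < 0):
            raise ValueError("hazards must be finite and non-negative")

    @property
    def start_age(self) -> float:
        return float(self.ages[0])

    @property
    def terminal_age(self) -> float:
        return float(self.ages[-1])

    def at(self, age: float) -> float:
        """Hazard at an exact age (right-continuous; terminal age maps to the last segment)."""
        if age < self.start_age or age > self.terminal_age:
            raise ValueError(
                f"age {age} outside curve span [{self.start_age}, {self.terminal_age}]"
            )
        i = min(int(np.searchsorted(self.ages, age, side="right")) - 1, len(self.hazards) - 1)
        return float(self.hazards[i])

    def segments_between(self, start: float, end: float) -> list[tuple[float, float, float]]:
        """Split ``[start, end]`` at the curve's breakpoints: (a0, a1, hazard) triples."""
        if start < self.start_age or end > self.terminal_age:
            raise ValueError(
                f"requested span [{start}, {end}] outside curve "
                f"[{self.start_age}, {self.terminal_age}]"
            )
        cuts = np.unique(np.concatenate([[start, end], self.ages]))
        cuts = cuts[(cuts >= start) & (cuts <= end)]
        return [(float(a), float(b), self.at(a)) for a, b in zip(cuts[:-1], cuts[1:])]

    def integral(self, start: float, end: float) -> float:
        """Cumulative hazard over ``[start, end]``."""
        return sum((b - a) * h for a, b, h in self.segments_between(start, end))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sex": self.sex,
                "kind": self.kind,
                "age_start": self.ages[:-1],
                "age_end": self.ages[1:],
                "hazard": self.hazards,
            }
        )


def _bands_to_breakpoints(
    bands: Sequence[AgeBand], terminal_age: int
) -> np.ndarray:
    bands = sorted(bands, key=lambda b: b.lower)
    edges = [float(b.lower) for b in bands]
    last = bands[-1]
    edges.append(float(terminal_age) if last.upper is None else last.upper + 1.0)
    edges_arr = np.asarray(edges)
    # contiguity: each band must start where the previous ends
    for i, b in enumerate(bands[:-1]):
        if b.upper is None or b.upper + 1 != bands[i + 1].lower:
            raise ValueError(f"bands not contiguous at {b.label} → {bands[i + 1].label}")
    return edges_arr


def incidence_to_hazard(
    table: pd.DataFrame,
    sex: str,
    kind: str = "hip_fracture",
    terminal_age: int = DEFAULT_TERMINAL_AGE,
    exclude_labels: Sequence[str] = ("40+",),
) -> HazardCurve:
    """Convert one sex's incidence rows (per 100,000 PY) into a hazard curve.

    Aggregate rows (``40+``) are ignored; the terminal open band's hazard
    is held constant up to ``terminal_age``.
    """
    rows = table.xs(sex, level="sex")
    rows = rows.loc[[b for b in rows.index if b not in exclude_labels]]
    bands = sorted((AgeBand.from_label(b) for b in rows.index), key=lambda b: b.lower)
    edges = _bands_to_breakpoints(bands, terminal_age)
    rates = np.array([rows.loc[b.label, "rate_per_1e5"] for b in bands], dtype=float)
    return HazardCurve(sex=sex, kind=kind, ages=edges, hazards=rates / 1e5)


def impute_mof(hip: HazardCurve, ratios: pd.Series) -> HazardCurve:
    """Segment-wise product of a hip curve with MOF:hip ratios.

    ``ratios`` is indexed by ``(sex, age_band)``; every hip segment must
    have a ratio for the band containing its start age (missing band →
    fatal, naming the band). Ratios need only be positive — at younger
    ages forearm fractures dominate and ratios far above 1 are expected,
    but no ordering is enforced.
    """
    try:
        r_sex = ratios.xs(hip.sex, level="sex")
    except KeyError:
        raise KeyError(f"ratio table has no rows for sex {hip.sex!r}")
    bands = [AgeBand.from_label(b) for b in r_sex.index]
    scaled = np.empty_like(hip.hazards)
    for i, a in enumerate(hip.ages[:-1]):
        try:
            label = band_label_for_age(a, bands)
        except KeyError:
            raise KeyError(f"no MOF:hip ratio covers the band starting at age {a}")
        ratio = float(r_sex[label])
        if ratio <= 0:
            raise ValueError(f"MOF:hip ratio must be > 0, got {ratio} for {label}")
        scaled[i] = hip.hazards[i] * ratio
    return HazardCurve(sex=hip.sex, kind="major_osteoporotic", ages=hip.ages, hazards=scaled)


def qx_to_hazard(qx: np.ndarray, widths: np.ndarray) -> np.ndarray:
    """Annual death probabilities to hazards: h = −ln(1 − qx) / Δ."""
    qx = np.asarray(qx, dtype=float)
    widths = np.asarray(widths, dtype=float)
    if np.any((qx < 0) | (qx >= 1)):
        raise ValueError("qx must lie in [0, 1)")
    return -np.log1p(-qx) / widths


def load_life_table(
    path: str | Path,
    terminal_age: int = DEFAULT_TERMINAL_AGE,
) -> dict[str, HazardCurve]:
    """Load a sex- and band-specific all-cause mortality life table.

    The file is delimited text with columns ``sex, age_band`` and either a
    ``hazard`` column (mx-style annual hazards, used as-is) or a ``qx``
    column (per-band death probabilities, converted by h = −ln(1−qx)/Δ).
    ``qx ≥ 1`` in a non-terminal band is fatal. UN-style abridged life
    tables fit after renaming columns to this schema.

    Returns one death :class:`HazardCurve` per sex.
    """
    df = pd.read_csv(path, sep=None, engine="python", comment="#")
    df.columns = [c.strip().lower() for c in df.columns]
    if "hazard" in df.columns:
        mode = "hazard"
    elif "qx" in df.columns:
        mode = "qx"
    else:
        raise ValueError(f"{path} must provide a 'hazard' or 'qx' column")
    for col in ("sex", "age_band"):
        if col not in df.columns:
            raise ValueError(f"{path} lacks required column {col!r}")

    curves: dict[str, HazardCurve] = {}
    for sex, sub in df.groupby(df["sex"].str.strip().str.lower()):
        if sex not in SEXES:
            raise ValueError(f"unrecognised sex label {sex!r} in {path}")
        bands = sorted(
            (AgeBand.from_label(b) for b in sub["age_band"].astype(str)),
            key=lambda b: b.lower,
        )
        edges = _bands_to_breakpoints(bands, terminal_age)
        widths = np.diff(edges)
        sub = sub.set_index(sub["age_band"].astype(str).str.strip())
        vals = np.array([sub.loc[b.label, mode] for b in bands], dtype=float)
        if mode == "qx":
            if np.any((vals >= 1) & (np.arange(len(vals)) < len(vals) - 1)):
                raise ValueError(f"{path}: qx >= 1 in a non-terminal band")
            vals = qx_to_hazard(np.clip(vals, 0, 1 - 1e-12), widths)
        curves[sex] = HazardCurve(sex=sex, kind="death", ages=edges, hazards=vals)
    return curves
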