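"""First-fracture probability under competing mortality.

For a person of a given age and sex, the probability of sustaining a
first fracture within a horizon is computed from two piecewise-constant
hazard curves — fracture intensity f(t) and all-cause death intensity
d(t) — by splitting the horizon at every band boundary. On an interval
of width Δ with constant hazards (f, d), entered with survival (no
fracture, no death so far) S,

    contribution = S · f/(f+d) · (1 − exp(−(f+d)·Δ)),

with contribution 0 when f + d = 0, and S is then multiplied by
exp(−(f+d)·Δ). The sum of contributions over all intervals is the
first-fracture probability; the remaining mass 1 − probability − S_end
is death before fracture. "Lifetime" means a horizon reaching the
curves' terminal age.

The module also ships an independent Monte-Carlo oracle that simulates
competing exponential event times segment by segment; it shares no code
with the closed form and is used to validate it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .hazards import HazardCurve

__all__ = [
    "ProbabilityResult",
    "first_event_probability",
    "lifetime_probability",
    "probability_grid",
    "simulate_first_event",
    "format_percent",
]


@dataclass(frozen=True)
class ProbabilityResult:
    """First-event probability over a horizon with its age decomposition.

    ``probability`` equals the sum of ``contributions``;
    ``probability + survival_at_horizon ≤ 1`` and the remainder is the
    probability of dying before fracturing.
    """

    sex: str
    start_age: float
    horizon: float | str  # years, or "lifetime"
    probability: float
    contributions: tuple[tuple[float, float, float], ...]  # (age0, age1, mass)
    survival_at_horizon: float

    @property
    def death_before_event(self) -> float:
        return 1.0 - self.probability - self.survival_at_horizon


def _merged_segments(
    fracture: HazardCurve, death: HazardCurve, start: float, end: float
) -> list[tuple[float, float, float, float]]:
    """(a0, a1, f, d) over [start, end], split at both curves' breakpoints."""
    cuts = np.unique(
        np.concatenate([[start, end], fracture.ages, death.ages])
    )
    cuts = cuts[(cuts >= start) & (cuts <= end)]
    return [
        (float(a), float(b), fracture.at(a), death.at(a))
        for a, b in zip(cuts[:-1], cuts[1:])
    ]


def _resolve_horizon(
    fracture: HazardCurve, death: HazardCurve, start_age: float, horizon
) -> tuple[float, float | str]:
    terminal = min(fracture.terminal_age, death.terminal_age)
    if isinstance(horizon, str):
        if horizon != "lifetime":
            raise ValueError(f"horizon must be a positive number or 'lifetime', got {horizon!r}")
        return terminal - start_age, "lifetime"
    horizon = float(horizon)
    if horizon <= 0:
        raise ValueError(f"horizon must be > 0, got {horizon}")
    return horizon, horizon


def first_event_probability(
    fracture: HazardCurve,
    death: HazardCurve,
    start_age: float,
    horizon,
) -> ProbabilityResult:
    """Probability of a first fracture in ``[start_age, start_age + horizon]``.

    Both curves must cover the span (``horizon="lifetime"`` integrates to
    the curves' common terminal age); a gap is fatal. Start ages off a
    band boundary are handled naturally: the first interval simply covers
    the remainder of its band.
    """
    if fracture.sex != death.sex:
        raise ValueError(
            f"fracture curve is {fracture.sex} but death curve is {death.sex}"
        )
    span, horizon_out = _resolve_horizon(fracture, death, start_age, horizon)
    end = start_age + span
    for curve, name in ((fracture, "fracture"), (death, "death")):
        if start_age < curve.start_age or end > curve.terminal_age:
            raise ValueError(
                f"{name} curve [{curve.start_age}, {curve.terminal_age}] does not "
                f"cover the requested span [{start_age}, {end}]"
            )
    survival = 1.0
    total = 0.0
    contribs: list[tuple[float, float, float]] = []
    for a0, a1, f, d in _merged_segments(fracture, death, start_age, end):
        width = a1 - a0
        lam = f + d
        if lam > 0:
            mass = survival * (f / lam) * -math.expm1(-lam * width)
            survival *= math.exp(-lam * width)
        else:
            mass = 0.0
        total += mass
        contribs.append((a0, a1, mass))
    return ProbabilityResult(
        sex=fracture.sex,
        start_age=float(start_age),
        horizon=horizon_out,
        probability=total,
        contributions=tuple(contribs),
        survival_at_horizon=survival,
    )


def lifetime_probability(
    fracture: HazardCurve, death: HazardCurve, start_age: float = 50
) -> ProbabilityResult:
    """Remaining-lifetime first-fracture probability from ``start_age``."""
    return first_event_probability(fracture, death, start_age, "lifetime")


def probability_grid(
    fracture: HazardCurve,
    death: HazardCurve,
    ages,
    horizons,
):
    """Tabulate :func:`first_event_probability` over age × horizon.

    Returns a pandas DataFrame with rows per age, columns per horizon,
    holding full-precision probabilities.
    """
    import pandas as pd

    data = {
        h: [first_event_probability(fracture, death, a, h).probability for a in ages]
        for h in horizons
    }
    return pd.DataFrame(data, index=pd.Index(ages, name="age"))


def simulate_first_event(
    fracture: HazardCurve,
    death: HazardCurve,
    start_age: float,
    horizon,
    n_paths: int = 200_000,
    rng: np.random.Generator | None = None,
) -> tuple[float, float]:
    """Monte-Carlo estimate of the first-fracture probability.

    Each trajectory walks the age intervals in order; within an interval
    with total hazard f + d an exponential waiting time decides whether an
    event occurs before the interval ends, and a Bernoulli(f/(f+d)) draw
    decides its type. Independent of the closed form by construction.

    Returns ``(p_hat, standard_error)``.
    """
    if rng is None:
        rng = np.random.default_rng()
    span, _ = _resolve_horizon(fracture, death, start_age, horizon)
    segs = _merged_segments(fracture, death, start_age, start_age + span)
    alive = np.ones(n_paths, dtype=bool)
    fractured = np.zeros(n_paths, dtype=bool)
    for a0, a1, f, d in segs:
        lam = f + d
        if lam == 0:
            continue
        idx = np.flatnonzero(alive)
        if idx.size == 0:
            break
        t = rng.exponential(1.0 / lam, size=idx.size)
        hit = t <= (a1 - a0)
        hit_idx = idx[hit]
        is_frac = rng.random(hit_idx.size) < f / lam
        fractured[hit_idx[is_frac]] = True
        alive[hit_idx] = False
    p = fractured.mean()
    se = math.sqrt(max(p * (1 - p), 1e-300) / n_paths)
    return float(p), se


def format_percent(p: float) -> str:
    """Report-style percentage: one decimal below 10%, integer above."""
    pct = p * 100.0
    one_dp = math.floor(pct * 10 + 0.5) / 10
    if one_dp < 10:
        return f"{one_dp:.1f}"
    return f"{math.floor(pct + 0.5):.0f}"
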