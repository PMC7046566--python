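"""End-to-end orchestration: one config in, one audited output directory out.

Stages: ingest (parse → deduplicate → stratify → exposure) → incidence
table → hazard curves (fracture, optional MOF, death) → probability grid
→ burden projection. Every run serialises its config and a manifest with
per-stage record counts and the config hash, writes outputs to a
temporary directory first and renames it into place only on success, so
a failed run leaves no partial outputs. The count accounting mirrors a
registry whose accuracy cannot be verified at source: every exclusion is
logged so parsed = rejected + deduplicated-away + stratified (+ underage).
"""

from __future__ import annotations

import datetime as dt
import hashlib
import json
import shutil
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from . import hazards, incidence, probability, projection, registry

__all__ = ["RunConfig", "run_pipeline", "render_incidence_table", "render_projection_table"]


@dataclass
class RunConfig:
    """Everything a run needs; serialised verbatim into the output directory."""

    registry_path: str
    population_path: str
    coverage_path: str
    life_table_path: str
    pyramid_path: str | None = None
    ratio_table_path: str | None = None
    window_start: str = "2015-01-01"
    window_end: str = "2017-12-31"
    years_observed: float = 3.0
    dedup_window_days: int = 90
    ci_level: float = 0.95
    terminal_age: int = 110
    projection_min_age: int = 50
    projection_years: list[int] = field(default_factory=lambda: [2015, 2020, 2030, 2040, 2050])
    grid_ages: list[int] = field(default_factory=lambda: list(range(50, 91, 5)))
    grid_horizon: float = 10.0
    lifetime_start_age: int = 50
    seed: int = 0

    def validate(self) -> None:
        if self.dedup_window_days < 0:
            raise ValueError("dedup_window_days must be >= 0")
        if not 0 < self.ci_level < 1:
            raise ValueError("ci_level must be in (0, 1)")
        start = dt.date.fromisoformat(self.window_start)
        end = dt.date.fromisoformat(self.window_end)
        if end < start:
            raise ValueError("window_end precedes window_start")
        for name in ("registry_path", "population_path", "coverage_path", "life_table_path"):
            p = getattr(self, name)
            if not Path(p).exists():
                raise FileNotFoundError(f"{name} = {p} does not exist")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.__dict__, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))

    def sha256(self) -> str:
        blob = yaml.safe_dump(self.__dict__, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


def _write_csv(df: pd.DataFrame, path: Path, config_hash: str, index: bool = True) -> None:
    df.to_csv(path, index=index)
    with open(path, "a") as fh:
        fh.write(f"# config_sha256={config_hash}\n")


def run_pipeline(config: RunConfig, out_dir: str | Path) -> Path:
    """Run every stage and write the audited output directory.

    Outputs: ``incidence.csv`` (full precision), ``incidence_report.csv``
    (display rounding), ``hazards.csv``, ``probability_grid.csv``,
    ``lifetime.json``, ``projection.csv`` (when a pyramid is configured),
    ``rejected_rows.csv``, ``config.yaml`` and ``manifest.json`` with
    stage counts and the config hash. Atomic: assembled in a temporary
    sibling directory, renamed into place on success.
    """
    config.validate()
    chash = config.sha256()
    out_dir = Path(out_dir)
    out_dir.parent.mkdir(parents=True, exist_ok=True)
    tmp = Path(tempfile.mkdtemp(dir=out_dir.parent, prefix=".run-"))
    try:
        window = (
            dt.date.fromisoformat(config.window_start),
            dt.date.fromisoformat(config.window_end),
        )
        records, rejected = registry.parse_registry(config.registry_path, window)
        deduped = registry.deduplicate(records, window_days=config.dedup_window_days)
        counts, n_underage = registry.stratify(deduped)
        pop = registry.read_stratum_column(config.population_path, "raw_population")
        cov = registry.read_stratum_column(config.coverage_path, "coverage_fraction")
        exposure = registry.build_exposure(pop, cov, config.years_observed)

        table = incidence.assemble_table(counts, exposure, level=config.ci_level)
        ratios = incidence.female_male_ratio(table)

        death = hazards.load_life_table(config.life_table_path, terminal_age=config.terminal_age)
        curves = {}
        for sex in registry.SEXES:
            # stratum rates are per *years_observed*-year totals only in the
            # events column; rate_per_1e5 is already annual, so conversion is direct
            curves[sex] = hazards.incidence_to_hazard(
                table, sex, terminal_age=config.terminal_age
            )
        mof_curves = {}
        if config.ratio_table_path:
            ratio_tab = registry.read_stratum_column(config.ratio_table_path, "ratio")
            for sex in registry.SEXES:
                mof_curves[sex] = hazards.impute_mof(curves[sex], ratio_tab)

        grids = {}
        lifetimes = {}
        for sex in registry.SEXES:
            grids[sex] = probability.probability_grid(
                curves[sex], death[sex], config.grid_ages, [config.grid_horizon]
            )
            lifetimes[sex] = probability.lifetime_probability(
                curves[sex], death[sex], start_age=config.lifetime_start_age
            )

        proj = None
        if config.pyramid_path:
            pyramid = projection.read_pyramid(config.pyramid_path)
            proj = projection.project(
                table, pyramid, config.projection_years, min_age=config.projection_min_age
            )

        # ---- write everything ----
        config.to_yaml(tmp / "config.yaml")
        _write_csv(table, tmp / "incidence.csv", chash)
        _write_csv(render_incidence_table(table), tmp / "incidence_report.csv", chash)
        _write_csv(rejected, tmp / "rejected_rows.csv", chash, index=False)
        hz_frames = [c.to_frame() for c in curves.values()]
        hz_frames += [c.to_frame() for c in mof_curves.values()]
        hz_frames += [c.to_frame() for c in death.values()]
        _write_csv(pd.concat(hz_frames, ignore_index=True), tmp / "hazards.csv", chash, index=False)
        grid_long = pd.concat(
            {sex: g for sex, g in grids.items()}, names=["sex", "age"]
        )
        _write_csv(grid_long, tmp / "probability_grid.csv", chash)
        (tmp / "lifetime.json").write_text(json.dumps(
            {
                sex: {
                    "start_age": r.start_age,
                    "probability": r.probability,
                    "percent_display": probability.format_percent(r.probability),
                    "survival_at_horizon": r.survival_at_horizon,
                }
                for sex, r in lifetimes.items()
            }
            | {"config_sha256": chash},
            indent=2,
        ))
        if proj is not None:
            _write_csv(proj, tmp / "projection.csv", chash)
            _write_csv(
                projection.render_projection(proj), tmp / "projection_report.csv", chash
            )
        manifest = {
            "config_sha256": chash,
            "counts": {
                "parsed": len(records) + len(rejected),
                "rejected": int(len(rejected)),
                "accepted": len(records),
                "deduplicated_away": len(records) - len(deduped),
                "underage_excluded": n_underage,
                "stratified": int(counts.sum()),
            },
            "female_male_ratio": ratios,
        }
        assert (
            manifest["counts"]["parsed"]
            == manifest["counts"]["rejected"]
            + manifest["counts"]["deduplicated_away"]
            + manifest["counts"]["underage_excluded"]
            + manifest["counts"]["stratified"]
        ), "record accounting failed to balance"
        (tmp / "manifest.json").write_text(json.dumps(manifest, indent=2))
        if out_dir.exists():
            shutil.rmtree(out_dir)
        tmp.rename(out_dir)
    except Exception:
        shutil.rmtree(tmp, ignore_errors=True)
        raise
    return out_dir


def render_incidence_table(table: pd.DataFrame) -> pd.DataFrame:
    """Report view with the published rounding conventions.

    Person-years and event counts as integers, rates and CI bounds
    rounded half-up to integers, CI shown as "low-high".
    """
    out = pd.DataFrame(index=table.index)
    out["person_years"] = [incidence.round_half_up(v) for v in table["person_years"]]
    out["fractures"] = table["events"].astype(int)
    out["incidence_per_1e5"] = [incidence.round_half_up(v) for v in table["rate_per_1e5"]]
    out["ci_95"] = [
        f"{incidence.round_half_up(lo)}-{incidence.round_half_up(hi)}"
        for lo, hi in zip(table["ci_low_per_1e5"], table["ci_high_per_1e5"])
    ]
    return out


def render_projection_table(proj: pd.DataFrame) -> pd.DataFrame:
    return projection.render_projection(proj)
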