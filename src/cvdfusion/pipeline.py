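"""End-to-end pipeline: generate -> classify -> estimate -> fuse -> fit -> project.

A run is fully described by a :class:`RunConfig` (YAML-serializable, strict
schema -- unknown keys are rejected so policy-switch typos cannot pass
silently).  Identical config + seed reproduces byte-identical outputs; the
manifest written with each run is sufficient to re-derive every table.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import fusion, leecarter, prevalence, synth
from .icd import classify_deaths
from .world import build_world

logger = logging.getLogger(__name__)

_TRUTH_COLS = ["true_education", "true_obesity"]


@dataclass
class RunConfig:
    seed: int = 0
    years: tuple[int, int] = (2003, 2019)
    horizon_end: int = 2029
    pop_size: int = 4_000_000
    marker_sensitivity: float = 1.0
    marker_false_positive: float = 0.0
    unknown_edu_rate: float = 0.03
    n_edu_per_cell: int = 5000
    n_prev_per_wave: int = 5000
    pooling: str = "wave"              # "wave" | "two-period"
    aggregation: str = "exposure"      # "exposure" | "equal"
    redistribute_unknown: bool = True
    jumpoff: str = "fit"               # "fit" | "observed"
    trend_break: int | None = 2011
    outdir: str | None = None

    def validate(self) -> None:
        y0, y1 = self.years
        if y1 - y0 + 1 < 3:
            raise ValueError("need at least 3 analysis years")
        if self.horizon_end <= y1:
            raise ValueError(
                f"projection horizon must start at {y1 + 1}; horizon_end={self.horizon_end}"
            )
        if self.pooling not in ("wave", "two-period"):
            raise ValueError(f"unknown pooling policy {self.pooling!r}")
        if self.aggregation not in ("exposure", "equal"):
            raise ValueError(f"unknown aggregation policy {self.aggregation!r}")
        if self.jumpoff not in ("fit", "observed"):
            raise ValueError(f"unknown jump-off policy {self.jumpoff!r}")
        if self.trend_break is not None and not (y0 < self.trend_break < y1):
            raise ValueError("trend_break must lie strictly inside the analysis years")

    @property
    def horizon(self) -> int:
        return self.horizon_end - self.years[1]

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        if "years" in raw:
            raw["years"] = tuple(raw["years"])
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["years"] = list(self.years)
        return d


def synthesize(config: RunConfig) -> dict:
    """Build the world and generate the four source datasets."""
    config.validate()
    world = build_world(
        seed=config.seed,
        years=config.years,
        pop_size=config.pop_size,
        marker_sensitivity=config.marker_sensitivity,
        marker_false_positive=config.marker_false_positive,
        unknown_edu_rate=config.unknown_edu_rate,
    )
    deaths = synth.generate_deaths(world)
    exposures = synth.generate_exposures(world)
    edu_survey = synth.generate_education_survey(world, config.n_edu_per_cell)
    prev_survey = synth.generate_prevalence_survey(world, n_per_wave=config.n_prev_per_wave)
    logger.info("synthesized %d deaths, %d survey records", len(deaths), len(edu_survey) + len(prev_survey))
    return {
        "world": world,
        "deaths": deaths,
        "exposures": exposures,
        "edu_survey": edu_survey,
        "prev_survey": prev_survey,
    }


def run(config: RunConfig, data: dict | None = None) -> dict:
    """Execute the full pipeline; returns all intermediate and final tables.

    ``data`` may carry pre-loaded input tables (keys as in
    :func:`synthesize`); otherwise synthesis mode generates them.
    """
    config.validate()
    if data is None:
        data = synthesize(config)
    deaths, exposures = data["deaths"], data["exposures"]

    classified = classify_deaths(deaths)
    n_cvd = int(classified["is_cvd"].sum())
    n_ob = int(classified["is_obesity_related"].sum())
    logger.info(
        "classified %d records: %d CVD deaths, %d obesity-related (%.1f%%)",
        len(classified), n_cvd, n_ob, 100.0 * n_ob / max(n_cvd, 1),
    )
    counts = fusion.tabulate_cvd_deaths(classified, config.redistribute_unknown)

    edu_dist = prevalence.education_distribution(data["edu_survey"])
    years = np.arange(config.years[0], config.years[1] + 1)
    prev_surface = prevalence.obesity_by_education(
        data["prev_survey"], years, pooling=config.pooling
    )

    surface = fusion.conditional_surface(counts, exposures, prev_surface, edu_dist)
    aggregate = fusion.aggregate_all_ages(surface, exposures, weighting=config.aggregation)

    fits = leecarter.fit_strata(surface)
    last_year = config.years[1]
    expo_last = (
        exposures[exposures["year"] == last_year]
        .groupby("age_group", observed=True)["person_years"]
        .sum()
    )
    proj_rows, agg_proj_rows, fit_rows = [], [], []
    for (sex, ob, edu), fit in fits.items():
        proj = leecarter.project(fit, config.horizon, jumpoff=config.jumpoff)
        ages = sorted(surface["age_group"].unique(), key=lambda a: int(str(a)[:2]))
        for ia, ag in enumerate(ages):
            for ih, yr in enumerate(proj.years):
                proj_rows.append(
                    (sex, ob, edu, ag, int(yr), proj.central[ia, ih],
                     proj.lower[ia, ih], proj.upper[ia, ih])
                )
        w = expo_last.reindex(ages).to_numpy(dtype=float)
        agg = leecarter.aggregate_projection(proj, w)
        for r in agg.itertuples():
            agg_proj_rows.append((sex, ob, edu, int(r.year), r.prob, r.lower, r.upper))
        fit_rows.append(
            (sex, ob, edu, fit.drift, fit.sigma, fit.explained_ratio, fit.degenerate)
        )

    projections = pd.DataFrame(
        proj_rows,
        columns=["sex", "obesity", "education", "age_group", "year", "prob", "lower", "upper"],
    )
    for col in ("prob", "lower", "upper"):
        projections[col + "_per_100k"] = projections[col] * 1e5
    projections_aggregate = pd.DataFrame(
        agg_proj_rows, columns=["sex", "obesity", "education", "year", "prob", "lower", "upper"]
    )
    for col in ("prob", "lower", "upper"):
        projections_aggregate[col + "_per_100k"] = projections_aggregate[col] * 1e5
    fit_table = pd.DataFrame(
        fit_rows,
        columns=["sex", "obesity", "education", "drift", "sigma", "explained_ratio", "degenerate"],
    )

    trends = _trend_table(classified, exposures, config)

    artifacts = {
        "config": config,
        "counts": counts,
        "edu_dist": edu_dist,
        "prev_surface": prev_surface,
        "surface": surface,
        "aggregate": aggregate,
        "fits": fits,
        "fit_table": fit_table,
        "projections": projections,
        "projections_aggregate": projections_aggregate,
        "trends": trends,
    }
    artifacts.update({k: data[k] for k in ("deaths", "exposures", "edu_survey", "prev_survey")})
    if "world" in data:
        artifacts["world"] = data["world"]
    if config.outdir is not None:
        write_artifacts(artifacts, config.outdir)
    return artifacts


def _trend_table(classified: pd.DataFrame, exposures: pd.DataFrame, config: RunConfig) -> pd.DataFrame:
    """Annualized % change in the overall CVD mortality rate per sex and age
    group, for the sub-periods split at ``trend_break`` and the full span."""
    y0, y1 = config.years
    periods = [(y0, y1)]
    if config.trend_break is not None:
        periods = [(y0, config.trend_break), (config.trend_break, y1)] + periods
    cvd = (
        classified[classified["is_cvd"]]
        .groupby(["age_group", "sex", "year"], observed=True)
        .size()
        .rename("deaths")
        .reset_index()
        .merge(exposures, on=["age_group", "sex", "year"])
    )
    rows = []
    for (ag, sex), grp in cvd.groupby(["age_group", "sex"], observed=True):
        grp = grp.sort_values("year")
        for p0, p1 in periods:
            sel = grp[(grp["year"] >= p0) & (grp["year"] <= p1)]
            pct, lo, hi = leecarter.annualized_change(
                sel["deaths"].to_numpy(), sel["person_years"].to_numpy(), sel["year"].to_numpy()
            )
            rows.append((sex, ag, f"{p0}-{p1}", pct, lo, hi))
    return pd.DataFrame(
        rows, columns=["sex", "age_group", "period", "annual_pct_change", "lower", "upper"]
    )


def write_artifacts(artifacts: dict, outdir) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    tables = {
        "deaths.csv": artifacts["deaths"].drop(columns=_TRUTH_COLS, errors="ignore"),
        "exposures.csv": artifacts["exposures"],
        "education_survey.csv": artifacts["edu_survey"],
        "prevalence_survey.csv": artifacts["prev_survey"],
        "cvd_death_counts.csv": artifacts["counts"],
        "education_distribution.csv": artifacts["edu_dist"],
        "obesity_prevalence.csv": artifacts["prev_surface"],
        "conditional_surface.csv": artifacts["surface"],
        "conditional_aggregate.csv": artifacts["aggregate"],
        "lee_carter_fits.csv": artifacts["fit_table"],
        "projections.csv": artifacts["projections"],
        "projections_aggregate.csv": artifacts["projections_aggregate"],
        "annualized_trends.csv": artifacts["trends"],
    }
    for name, df in tables.items():
        df.to_csv(out / name, index=False)
    manifest = {
        "config": artifacts["config"].to_dict(),
        "tables": sorted(tables),
        "n_deaths": int(len(artifacts["deaths"])),
    }
    (out / "manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=True))
    logger.info("wrote %d tables to %s", len(tables), out)
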