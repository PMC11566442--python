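"""Bayes-theorem fusion of the four data sources.

For each age group, sex and year the conditional probability of premature
CVD death given obesity status O and education E is

    Pr(CVD | O, E) = Pr(O, E | CVD) * Pr(CVD) / (Pr(O | E) * Pr(E))

with the four components estimated from different sources: Pr(O, E | CVD)
from the multiple-cause death file (obesity via the marker-code proxy),
Pr(CVD) from deaths over census person-years, Pr(O | E) from the BMI
survey and Pr(E) from the education survey.  For O = 0 the denominator
uses (1 - Pr(O=1 | E)) * Pr(E), as the probability model requires.

Because the components are ratios, the formula conserves total
probability: summing Pr(CVD|O,E) * Pr(O|E) * Pr(E) over the six (O, E)
cells returns Pr(CVD) exactly, and on a fully enumerated micro population
whose components are all computed from the same counts the fusion output
equals direct stratified counting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .education import LEVELS, harmonize_series

logger = logging.getLogger(__name__)

OBESITY_STATES = (0, 1)


@dataclass
class RateComponents:
    """The four Bayes terms for one (age group, sex, year) cell.

    ``joint_given_cvd`` and ``p_obesity_given_edu`` are indexed by
    (education, obesity) and education respectively, education ordered
    (low, middle, high).
    """

    joint_given_cvd: np.ndarray   # (3, 2): Pr(O, E | CVD)
    p_cvd: float                  # Pr(CVD) per person-year
    p_obesity_given_edu: np.ndarray  # (3,): Pr(O=1 | E)
    p_edu: np.ndarray             # (3,): Pr(E)

    def validate(self) -> None:
        if abs(self.joint_given_cvd.sum() - 1.0) > 1e-10:
            raise ValueError("Pr(O,E|CVD) must sum to 1 over the six cells")
        if abs(self.p_edu.sum() - 1.0) > 1e-10:
            raise ValueError("Pr(E) must sum to 1")
        for name, arr in [
            ("joint_given_cvd", self.joint_given_cvd),
            ("p_obesity_given_edu", self.p_obesity_given_edu),
            ("p_edu", self.p_edu),
            ("p_cvd", np.asarray([self.p_cvd])),
        ]:
            if ((np.asarray(arr) < 0) | (np.asarray(arr) > 1)).any():
                raise ValueError(f"{name} outside [0, 1]")


def conditional_probability(c: RateComponents, per_100k: bool = False) -> np.ndarray:
    """Apply the Bayes formula; returns a (3, 2) (education, obesity) array."""
    c.validate()
    denom = c.p_edu[:, None] * np.stack(
        [1.0 - c.p_obesity_given_edu, c.p_obesity_given_edu], axis=1
    )
    if (denom <= 0).any():
        bad = np.argwhere(denom <= 0)[0]
        raise ZeroDivisionError(
            f"zero Bayes denominator for education={LEVELS[bad[0]]}, obesity={bad[1]}"
        )
    out = c.joint_given_cvd * c.p_cvd / denom
    return out * 1e5 if per_100k else out


def components_from_micro(death_counts: np.ndarray, exposure_counts: np.ndarray) -> RateComponents:
    """Components of a fully enumerated micro population.

    ``death_counts`` and ``exposure_counts`` are (3, 2) (education, obesity)
    arrays of CVD deaths and person-years.  All four Bayes terms are
    computed from these same counts, so fusion reduces algebraically to
    direct stratified counting.
    """
    deaths = np.asarray(death_counts, dtype=float)
    expo = np.asarray(exposure_counts, dtype=float)
    if (expo <= 0).any():
        raise ValueError("every micro stratum needs positive exposure")
    if deaths.sum() <= 0:
        raise ValueError("micro population has no CVD deaths")
    total_expo = expo.sum()
    p_edu = expo.sum(axis=1) / total_expo
    p_ob = expo[:, 1] / expo.sum(axis=1)
    return RateComponents(
        joint_given_cvd=deaths / deaths.sum(),
        p_cvd=float(deaths.sum() / total_expo),
        p_obesity_given_edu=p_ob,
        p_edu=p_edu,
    )


# ---------------------------------------------------------------------------
# tabulation of classified deaths


def tabulate_cvd_deaths(
    classified: pd.DataFrame, redistribute_unknown: bool = True
) -> pd.DataFrame:
    """Count CVD deaths per (age group, sex, year, education, obesity proxy).

    Education codes are harmonized per record; unknown-education deaths are
    redistributed proportionally to the known-education distribution within
    (age group, sex, year, obesity) -- the switchable policy that keeps the
    Pr(O,E|CVD) denominator unbiased under missing-at-random education.
    Returns float counts (non-integer after redistribution).
    """
    cvd = classified[classified["is_cvd"]].copy()
    if cvd.empty:
        raise ValueError("no CVD deaths to tabulate")
    cvd["education"] = harmonize_series(cvd["education_code"], cvd["education_version"])
    cvd["obese"] = cvd["is_obesity_related"].astype(int)
    counts = (
        cvd.groupby(["age_group", "sex", "year", "education", "obese"], observed=True)
        .size()
        .rename("deaths")
        .reset_index()
    )
    known = counts[counts["education"].isin(LEVELS)].copy()
    unknown = counts[~counts["education"].isin(LEVELS)]
    if redistribute_unknown and not unknown.empty:
        cell_keys = ["age_group", "sex", "year", "obese"]
        u_df = (
            unknown.groupby(cell_keys, observed=True)["deaths"].sum().rename("u").reset_index()
        )
        known = known.merge(u_df, on=cell_keys, how="left")
        known["u"] = known["u"].fillna(0.0)
        k_sum = known.groupby(cell_keys, observed=True)["deaths"].transform("sum")
        known["deaths"] = known["deaths"] * (1.0 + known["u"] / k_sum)
        known = known.drop(columns="u")
    n_unknown = int(unknown["deaths"].sum())
    if n_unknown:
        logger.info(
            "unknown-education CVD deaths: %d (%s)",
            n_unknown,
            "redistributed" if redistribute_unknown else "dropped",
        )
    known["deaths"] = known["deaths"].astype(float)
    return known.reset_index(drop=True)


def _cell_components(
    counts: pd.DataFrame,
    exposures: pd.DataFrame,
    prev_surface: pd.DataFrame,
    edu_dist: pd.DataFrame,
    age_group,
    sex,
    year,
) -> RateComponents:
    cell = counts[
        (counts["age_group"] == age_group)
        & (counts["sex"] == sex)
        & (counts["year"] == year)
    ]
    if cell["deaths"].sum() <= 0:
        raise ValueError(f"zero CVD deaths in cell age={age_group} sex={sex} year={year}")
    joint = np.zeros((3, 2))
    for row in cell.itertuples():
        joint[LEVELS.index(row.education), int(row.obese)] = row.deaths
    joint /= joint.sum()

    expo = exposures[
        (exposures["age_group"] == age_group)
        & (exposures["sex"] == sex)
        & (exposures["year"] == year)
    ]["person_years"]
    if expo.empty or float(expo.iloc[0]) <= 0:
        raise ValueError(f"zero exposure in cell age={age_group} sex={sex} year={year}")
    p_cvd = float(cell["deaths"].sum() / float(expo.iloc[0]))

    prev = prev_surface[
        (prev_surface["age_group"] == age_group)
        & (prev_surface["sex"] == sex)
        & (prev_surface["year"] == year)
    ].set_index("education")["p_obese"]
    edu = edu_dist[
        (edu_dist["age_group"] == age_group)
        & (edu_dist["sex"] == sex)
        & (edu_dist["year"] == year)
    ].set_index("education")["share"]
    p_ob = np.array([prev[lv] for lv in LEVELS])
    p_edu = np.array([edu[lv] for lv in LEVELS])
    return RateComponents(joint, p_cvd, p_ob, p_edu)


def components_from_data(
    deaths, exposures, prevalence_surface, edu_distribution, age_group, sex, year
) -> RateComponents:
    """Estimate the four Bayes terms for one (age group, sex, year) cell.

    ``deaths`` may be a classified record-level table or the output of
    :func:`tabulate_cvd_deaths`.
    """
    counts = deaths if "deaths" in deaths.columns else tabulate_cvd_deaths(deaths)
    return _cell_components(
        counts, exposures, prevalence_surface, edu_distribution, age_group, sex, year
    )


def conditional_surface(
    death_counts: pd.DataFrame,
    exposures: pd.DataFrame,
    prev_surface: pd.DataFrame,
    edu_dist: pd.DataFrame,
    small_cell_threshold: int = 5,
) -> pd.DataFrame:
    """Vectorized Pr(CVD | O, E) over every (age group, sex, year) cell.

    Returns tidy rows (age_group, sex, year, education, obesity, prob,
    prob_per_100k, deaths, small_cell).  This table is the input contract
    for the Lee-Carter stage.
    """
    strata = (
        exposures[["age_group", "sex", "year"]]
        .drop_duplicates()
        .merge(pd.DataFrame({"education": list(LEVELS)}), how="cross")
        .merge(pd.DataFrame({"obesity": list(OBESITY_STATES)}), how="cross")
    )
    df = strata.merge(
        death_counts.rename(columns={"obese": "obesity"}),
        on=["age_group", "sex", "year", "education", "obesity"],
        how="left",
    )
    df["deaths"] = df["deaths"].fillna(0.0)

    totals = df.groupby(["age_group", "sex", "year"], observed=True)["deaths"].transform("sum")
    if (totals <= 0).any():
        bad = df.loc[totals <= 0, ["age_group", "sex", "year"]].iloc[0]
        raise ValueError(f"zero CVD deaths in cell {tuple(bad)}")
    df = df.merge(exposures, on=["age_group", "sex", "year"], how="left")
    if df["person_years"].isna().any() or (df["person_years"] <= 0).any():
        raise ValueError("missing or non-positive exposure for some stratum")
    df = df.merge(prev_surface, on=["age_group", "sex", "year", "education"], how="left")
    df = df.merge(edu_dist, on=["age_group", "sex", "year", "education"], how="left")
    if df[["p_obese", "share"]].isna().any().any():
        raise ValueError("prevalence or education surface does not cover all strata")

    joint = df["deaths"] / totals
    p_cvd = totals / df["person_years"]
    p_o_e = np.where(df["obesity"] == 1, df["p_obese"], 1.0 - df["p_obese"])
    denom = p_o_e * df["share"]
    if (denom <= 0).any():
        raise ZeroDivisionError("zero Bayes denominator in conditional surface")
    df["prob"] = joint * p_cvd / denom
    df["prob_per_100k"] = df["prob"] * 1e5
    df["small_cell"] = df["deaths"] < small_cell_threshold
    return df[
        [
            "age_group",
            "sex",
            "year",
            "education",
            "obesity",
            "deaths",
            "prob",
            "prob_per_100k",
            "small_cell",
        ]
    ]


def aggregate_all_ages(
    surface: pd.DataFrame,
    exposures: pd.DataFrame,
    weighting: str = "exposure",
    pool_sexes: bool = False,
) -> pd.DataFrame:
    """All-age (35-74) aggregate of the conditional surface.

    Exposure-weighted (crude) mean across the eight 5-year age groups by
    default; ``weighting="equal"`` gives the unweighted mean.  No age
    standardization is applied.
    """
    if weighting not in ("exposure", "equal"):
        raise ValueError(f"unknown weighting: {weighting!r}")
    n_ages = exposures["age_group"].nunique()
    df = surface.merge(exposures, on=["age_group", "sex", "year"], how="left")
    if df["person_years"].isna().any():
        raise ValueError("exposures do not cover the surface")
    df["w"] = df["person_years"] if weighting == "exposure" else 1.0
    keys = ["year", "education", "obesity"] if pool_sexes else ["sex", "year", "education", "obesity"]
    sizes = df.groupby(keys, observed=True)["age_group"].nunique()
    if (sizes < n_ages).any():
        raise ValueError("missing age group in aggregation")
    df["wp"] = df["w"] * df["prob"]
    g = df.groupby(keys, observed=True)
    out = (g["wp"].sum() / g["w"].sum()).rename("prob").reset_index()
    out["prob_per_100k"] = out["prob"] * 1e5
    return out
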