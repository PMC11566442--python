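"""Survey-weighted estimation of Pr(E) and Pr(O=1 | E).

Estimators are Horvitz-Thompson style weighted proportions with a
weighted-binomial standard error on the Kish effective sample size
(n_eff = (Σw)² / Σw²).  Full design-based variance (clusters, strata,
replicate weights) is out of scope; only the weights are modelled.

``obesity_by_education`` pools survey waves into periods, estimates
prevalence per (age group, sex, education, period), anchors each estimate
at the period midpoint year and bridges to an annual series by
piecewise-linear interpolation between midpoints with flat extrapolation
at both ends.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .education import LEVELS, harmonize_series

_CLAMP = 1e-6


@dataclass(frozen=True)
class WeightedProportion:
    estimate: float
    effective_n: float
    se: float


def weighted_proportion(weights, indicator) -> WeightedProportion:
    """Weighted proportion of records where ``indicator`` is true."""
    w = np.asarray(weights, dtype=float)
    x = np.asarray(indicator, dtype=float)
    if w.size == 0:
        raise ValueError("weighted_proportion: empty input")
    if (w <= 0).any():
        raise ValueError("weighted_proportion: weights must be positive")
    total = w.sum()
    est = float((w * x).sum() / total)
    n_eff = float(total**2 / (w**2).sum())
    se = float(np.sqrt(max(est * (1.0 - est), 0.0) / n_eff))
    return WeightedProportion(est, n_eff, se)


def education_distribution(edu_survey: pd.DataFrame, scheme: str = "acs") -> pd.DataFrame:
    """Weighted education shares per (age group, sex, year).

    Unknown-education records are dropped and the known shares renormalized
    (proportional redistribution).  Returns tidy rows
    (age_group, sex, year, education, share); shares sum to 1 within 1e-12
    in every cell.
    """
    if edu_survey.empty:
        raise ValueError("education survey is empty")
    df = edu_survey.copy()
    df["education"] = harmonize_series(df["education_code"], scheme)
    df = df[df["education"].isin(LEVELS)]
    if df.empty:
        raise ValueError("education survey has no records with known education")
    g = df.groupby(["age_group", "sex", "year", "education"], observed=True)["weight"].sum()
    shares = g / g.groupby(["age_group", "sex", "year"], observed=True).transform("sum")
    out = shares.rename("share").reset_index()
    # complete each cell with all three levels (an absent level has share 0;
    # the fusion stage rejects the resulting zero denominator explicitly)
    cells = out[["age_group", "sex", "year"]].drop_duplicates()
    full = cells.merge(pd.DataFrame({"education": list(LEVELS)}), how="cross")
    out = full.merge(out, on=["age_group", "sex", "year", "education"], how="left")
    out["share"] = out["share"].fillna(0.0)
    return out


def _pool_periods(prev_survey: pd.DataFrame, pooling: str, years: np.ndarray) -> pd.DataFrame:
    df = prev_survey.copy()
    if pooling == "wave":
        df["period"] = df["wave"].astype(str)
        df["period_mid"] = df["wave_midpoint"]
    elif pooling == "two-period":
        split = 2011  # first/second half of a 2003-2019-style span
        first = df["wave_midpoint"] < split
        df["period"] = np.where(first, "early", "late")
        mids = df.groupby("period")["wave_midpoint"].transform("mean")
        df["period_mid"] = mids
    else:
        raise ValueError(f"unknown pooling policy: {pooling!r}")
    return df


def obesity_by_education(
    prev_survey: pd.DataFrame,
    years,
    pooling: str = "wave",
    bmi_cutoff: float = 30.0,
) -> pd.DataFrame:
    """Annual obesity prevalence given education per (age group, sex).

    Obesity is BMI >= 30 (the cutoff value itself counts as obese).
    Returns tidy rows (age_group, sex, year, education, p_obese) clamped to
    (1e-6, 1-1e-6) for every requested analysis year.
    """
    years = np.asarray(sorted(int(y) for y in np.atleast_1d(years)))
    if prev_survey.empty:
        raise ValueError("prevalence survey is empty")
    df = _pool_periods(prev_survey, pooling, years)
    df["education"] = harmonize_series(df["education_code"], "nhanes")
    df = df[df["education"].isin(LEVELS)]
    df["obese"] = df["bmi"] >= bmi_cutoff

    keys = ["age_group", "sex", "education"]
    n_periods = df["period"].nunique()
    records = []
    for (ag, sex, edu), grp in df.groupby(keys, observed=True):
        if grp["period"].nunique() < n_periods:
            missing_p = set(df["period"].unique()) - set(grp["period"].unique())
            raise ValueError(
                f"empty prevalence cell: age={ag} sex={sex} education={edu} "
                f"period(s) {sorted(missing_p)}"
            )
        per_period = []
        for (period, mid), pgrp in grp.groupby(["period", "period_mid"], observed=True):
            wp = weighted_proportion(pgrp["weight"], pgrp["obese"])
            per_period.append((float(mid), wp.estimate))
        per_period.sort()
        mids = np.array([m for m, _ in per_period])
        ests = np.array([e for _, e in per_period])
        annual = np.interp(years, mids, ests)  # flat beyond the end midpoints
        annual = np.clip(annual, _CLAMP, 1.0 - _CLAMP)
        for y, p in zip(years, annual):
            records.append((ag, sex, int(y), edu, float(p)))
    out = pd.DataFrame(records, columns=["age_group", "sex", "year", "education", "p_obese"])

    expected = set()
    present = set(map(tuple, out[keys].drop_duplicates().itertuples(index=False)))
    for ag in df["age_group"].unique():
        for sex in df["sex"].unique():
            for edu in LEVELS:
                expected.add((ag, sex, edu))
    missing = expected - present
    if missing:
        raise ValueError(f"empty prevalence cell(s): {sorted(missing)[:3]}")
    return out
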