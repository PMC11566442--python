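"""Generators for the four source datasets.

Emulated sources (flat CSV files, documented headers):

* **deaths** -- one row per death certificate: demographics, an education
  code in one of four coding schemes, and semicolon-joined ICD-10 code lists
  for part 1 (chain of events) and part 2 (contributing conditions) of the
  certificate.  Emulates a national multiple-cause-of-death file.
* **exposures** -- person-years by age group, sex and year (census-style).
* **education survey** -- person-level education codes with survey weights
  (household-survey style); sampling is deliberately unequal across
  education levels so unweighted shares are biased and the weights are
  informative.
* **prevalence survey** -- person-level BMI, education and weights in
  two-year waves (examination-survey style), same informative-weights
  design.

Obesity is latent at the individual death level: the generated certificate
carries at least one obesity marker code with probability
``marker_sensitivity`` for obese decedents and ``marker_false_positive``
for non-obese ones, mirroring the marker-code proxy the downstream
classifier uses.  All stochasticity flows from named child streams of the
world seed, so every generator is deterministic given the world.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .education import load_education_table
from .world import GroundTruthWorld

# RNG stream ids (children of the world seed)
_STREAM_DEATH_COUNTS = 1
_STREAM_DEATH_ATTRS = 2
_STREAM_EDU_SURVEY = 3
_STREAM_PREV_SURVEY = 4

#: CVD cause-of-death codes used by the generator.  Deliberately disjoint
#: from the obesity marker set so the marker proxy is identifiable.
CVD_CAUSE_CODES = np.array(
    ["I219", "I251", "I500", "I639", "I269", "I429", "I709", "I489"]
)
_CVD_CAUSE_WEIGHTS = np.array([0.28, 0.22, 0.16, 0.14, 0.06, 0.06, 0.04, 0.04])

MARKER_CODES = np.array(["E119", "E149", "N189", "E669", "E780", "I10", "I119", "I129"])
_MARKER_WEIGHTS = np.array([0.22, 0.08, 0.12, 0.10, 0.12, 0.20, 0.10, 0.06])

#: non-CVD, non-marker comorbidities occasionally added to part 2
COMORBID_CODES = np.array(["J449", "K729", "F102", "G309"])

_UNKNOWN_CODE = {"v1989": 99, "v2003": 9, "acs": 0, "nhanes": 9}
_DEATH_SCHEMES = ("v1989", "v2003", "acs", "nhanes")


def _scheme_level_codes() -> dict[tuple[str, str], np.ndarray]:
    table = load_education_table()
    known = table[table["level"] != "unknown"]
    return {
        (scheme, level): grp["code"].to_numpy()
        for (scheme, level), grp in known.groupby(["scheme", "level"])
    }


_LEVEL_CODES = _scheme_level_codes()


def _select_years(world: GroundTruthWorld, years) -> np.ndarray:
    if years is None:
        return np.arange(len(world.years))
    idx = [world.year_index(int(y)) for y in years]
    return np.asarray(idx)


def generate_exposures(world: GroundTruthWorld, years=None) -> pd.DataFrame:
    """Person-years by (age group, sex, year).  Exact expected counts."""
    world.validate()
    tsel = _select_years(world, years)
    rows = [
        (ag, sex, int(world.years[t]), int(world.pop_size))
        for ag in world.age_groups
        for sex in world.sexes
        for t in tsel
    ]
    return pd.DataFrame(rows, columns=["age_group", "sex", "year", "person_years"])


def generate_deaths(world: GroundTruthWorld, years=None) -> pd.DataFrame:
    """Simulate one row per CVD death.

    Per (age, sex, year, education, obesity) cell the death count is
    binomial(cell person-years, Pr(CVD|O,E)); counts for all cells are drawn
    in a single vectorized binomial call in C-order of
    (age, sex, year, education, obesity) from RNG stream
    ``[seed, 1]`` -- the replay oracle in the tests re-draws exactly this.

    Returned columns: age_group, sex, year, education_code,
    education_version, part1_codes, part2_codes plus generator ground truth
    ``true_education`` / ``true_obesity`` (dropped when writing the flat
    file).
    """
    world.validate()
    tsel = _select_years(world, years)
    expo = world.stratum_exposures()[:, :, tsel]      # (A,S,Tsel,3,2)
    prob = world.cond_prob[:, :, tsel]
    rng_counts = np.random.default_rng([world.seed, _STREAM_DEATH_COUNTS])
    counts = rng_counts.binomial(expo, prob)

    A, S, T, E, O = counts.shape
    flat = counts.ravel()
    n = int(flat.sum())
    cell_idx = np.repeat(np.arange(flat.size), flat)
    ai, si, ti, ei, oi = np.unravel_index(cell_idx, counts.shape)

    rng = np.random.default_rng([world.seed, _STREAM_DEATH_ATTRS])
    cause = rng.choice(CVD_CAUSE_CODES, size=n, p=_CVD_CAUSE_WEIGHTS)
    has_marker = np.where(
        oi == 1,
        rng.random(n) < world.marker_sensitivity,
        rng.random(n) < world.marker_false_positive,
    )
    marker = rng.choice(MARKER_CODES, size=n, p=_MARKER_WEIGHTS)
    marker_in_part1 = rng.random(n) < 0.5
    comorbid_mask = rng.random(n) < 0.5
    comorbid = rng.choice(COMORBID_CODES, size=n)

    part1 = cause.astype("<U24")
    m1 = has_marker & marker_in_part1
    part1[m1] = np.char.add(np.char.add(part1[m1], ";"), marker[m1])
    part2 = np.full(n, "", dtype="<U24")
    m2 = has_marker & ~marker_in_part1
    part2[m2] = marker[m2]
    cm = comorbid_mask
    sep = np.where(part2[cm] == "", "", ";")
    part2[cm] = np.char.add(np.char.add(part2[cm], sep), comorbid[cm])

    # education coding scheme rotates across records so every harmonization
    # path is exercised end to end
    scheme_idx = np.arange(n) % len(_DEATH_SCHEMES)
    edu_code = np.empty(n, dtype=np.int64)
    for k, scheme in enumerate(_DEATH_SCHEMES):
        for e, level in enumerate(world.edu_levels):
            mask = (scheme_idx == k) & (ei == e)
            pool = _LEVEL_CODES[(scheme, level)]
            edu_code[mask] = pool[rng.integers(0, len(pool), size=int(mask.sum()))]
    unknown = rng.random(n) < world.unknown_edu_rate
    for k, scheme in enumerate(_DEATH_SCHEMES):
        mask = unknown & (scheme_idx == k)
        edu_code[mask] = _UNKNOWN_CODE[scheme]

    return pd.DataFrame(
        {
            "age_group": pd.Categorical.from_codes(ai, world.age_groups),
            "sex": pd.Categorical.from_codes(si, list(world.sexes)),
            "year": world.years[tsel][ti],
            "education_code": edu_code,
            "education_version": pd.Categorical.from_codes(
                scheme_idx, list(_DEATH_SCHEMES)
            ),
            "part1_codes": part1,
            "part2_codes": part2,
            "true_education": pd.Categorical.from_codes(ei, list(world.edu_levels)),
            "true_obesity": oi,
        }
    )


def generate_education_survey(
    world: GroundTruthWorld,
    n_per_cell: int = 5000,
    years=None,
    oversample: tuple = (2.0, 1.0, 1.0),
) -> pd.DataFrame:
    """Person-level education survey (ACS-style codes) with informative weights.

    Sampling probability within an (age, sex, year) cell is proportional to
    the true share times the per-level ``oversample`` factor; the record
    weight is the inverse sampling rate, so weighted shares are unbiased
    while unweighted shares are not.
    """
    world.validate()
    if n_per_cell < 10:
        raise ValueError("n_per_cell must be at least 10")
    tsel = _select_years(world, years)
    over = np.asarray(oversample, dtype=float)
    rng = np.random.default_rng([world.seed, _STREAM_EDU_SURVEY])

    shares = world.edu_shares[:, :, tsel].reshape(-1, 3)        # (cells, 3)
    p_samp = shares * over
    p_samp /= p_samp.sum(axis=1, keepdims=True)
    counts = rng.multinomial(n_per_cell, p_samp)                # (cells, 3)
    weights_mat = shares / p_samp

    A, S, T = len(world.age_groups), len(world.sexes), len(tsel)
    cell_idx = np.repeat(np.arange(counts.size), counts.ravel())
    ci, ei = np.unravel_index(cell_idx, counts.shape)
    ai, si, ti = np.unravel_index(ci, (A, S, T))
    n = cell_idx.size
    edu_code = np.empty(n, dtype=np.int64)
    for e, level in enumerate(world.edu_levels):
        mask = ei == e
        pool = _LEVEL_CODES[("acs", level)]
        edu_code[mask] = pool[rng.integers(0, len(pool), size=int(mask.sum()))]

    return pd.DataFrame(
        {
            "age_group": pd.Categorical.from_codes(ai, world.age_groups),
            "sex": pd.Categorical.from_codes(si, list(world.sexes)),
            "year": world.years[tsel][ti],
            "education_code": edu_code,
            "weight": weights_mat[ci, ei],
        }
    )


def default_waves(world: GroundTruthWorld) -> list[tuple[int, ...]]:
    """Consecutive two-year waves over the world's years (last may be a
    single year when the span is odd)."""
    ys = list(map(int, world.years))
    waves = [tuple(ys[i : i + 2]) for i in range(0, len(ys), 2)]
    return waves


def wave_label(wave: tuple[int, ...]) -> str:
    return "-".join(str(y) for y in wave) if len(wave) > 1 else str(wave[0])


def wave_midpoint(wave: tuple[int, ...]) -> float:
    return float(np.mean(wave))


def generate_prevalence_survey(
    world: GroundTruthWorld,
    waves: list[tuple[int, ...]] | None = None,
    n_per_wave: int = 5000,
    oversample: tuple = (2.5, 0.8, 1.2),
) -> pd.DataFrame:
    """Person-level BMI survey in two-year waves (NHANES-style codes).

    ``n_per_wave`` is the sample size per (age group, sex) cell per wave.
    BMI is drawn from a two-component mixture whose weighted fraction with
    BMI >= 30 given education equals the world's obesity prevalence at the
    wave midpoint year.  Education sampling is informative (see
    ``generate_education_survey``).
    """
    world.validate()
    if n_per_wave < 10:
        raise ValueError("n_per_wave must be at least 10")
    if waves is None:
        waves = default_waves(world)
    for w in waves:
        for y in w:
            world.year_index(int(y))  # raises if outside the world years
    over = np.asarray(oversample, dtype=float)
    rng = np.random.default_rng([world.seed, _STREAM_PREV_SURVEY])

    A, S, W = len(world.age_groups), len(world.sexes), len(waves)
    tidx = [[world.year_index(int(y)) for y in w] for w in waves]
    # wave-midpoint truth: mean of the wave's annual surfaces
    shares = np.stack(
        [world.edu_shares[:, :, ts].mean(axis=2) for ts in tidx], axis=2
    )  # (A,S,W,3)
    prev = np.stack(
        [world.obesity_prev[:, :, ts].mean(axis=2) for ts in tidx], axis=2
    )

    shares_flat = shares.reshape(-1, 3)
    p_samp = shares_flat * over
    p_samp /= p_samp.sum(axis=1, keepdims=True)
    counts = rng.multinomial(n_per_wave, p_samp)
    weights_mat = shares_flat / p_samp

    cell_idx = np.repeat(np.arange(counts.size), counts.ravel())
    ci, ei = np.unravel_index(cell_idx, counts.shape)
    ai, si, wi = np.unravel_index(ci, (A, S, W))
    n = cell_idx.size

    p_obese = prev.reshape(-1, 3)[ci, ei]
    obese = rng.random(n) < p_obese
    bmi = np.empty(n)
    n_ob = int(obese.sum())
    bmi[obese] = np.clip(30.0 + rng.gamma(2.0, 3.0, size=n_ob), 30.0, 80.0)
    bmi[~obese] = np.clip(30.0 - rng.gamma(2.0, 2.2, size=n - n_ob), 12.0, 29.99)

    edu_code = np.empty(n, dtype=np.int64)
    for e, level in enumerate(world.edu_levels):
        mask = ei == e
        pool = _LEVEL_CODES[("nhanes", level)]
        edu_code[mask] = pool[rng.integers(0, len(pool), size=int(mask.sum()))]

    labels = [wave_label(w) for w in waves]
    return pd.DataFrame(
        {
            "age_group": pd.Categorical.from_codes(ai, world.age_groups),
            "sex": pd.Categorical.from_codes(si, list(world.sexes)),
            "wave": pd.Categorical.from_codes(wi, labels),
            "wave_midpoint": np.array([wave_midpoint(w) for w in waves])[wi],
            "education_code": edu_code,
            "bmi": np.round(bmi, 2),
            "weight": weights_mat[ci, ei],
        }
    )
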