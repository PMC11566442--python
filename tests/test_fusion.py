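import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cvdfusion import synth
from cvdfusion.fusion import (
    RateComponents,
    aggregate_all_ages,
    components_from_data,
    components_from_micro,
    conditional_probability,
    conditional_surface,
    tabulate_cvd_deaths,
)
from cvdfusion.icd import classify_deaths
from cvdfusion.world import build_world


def _components(joint, p_cvd, p_ob, p_edu):
    return RateComponents(
        np.asarray(joint, dtype=float),
        float(p_cvd),
        np.asarray(p_ob, dtype=float),
        np.asarray(p_edu, dtype=float),
    )


def test_independence_case_returns_marginal_rate():
    """When Pr(O,E|CVD) factorizes as Pr(O|E)Pr(E), every conditional
    probability equals Pr(CVD) -- the Bayes identity."""
    p_edu = np.array([0.2, 0.5, 0.3])
    p_ob = np.array([0.45, 0.4, 0.3])
    joint = p_edu[:, None] * np.stack([1 - p_ob, p_ob], axis=1)
    out = conditional_probability(_components(joint, 3e-3, p_ob, p_edu))
    np.testing.assert_allclose(out, 3e-3, rtol=1e-12)


@given(
    st.lists(st.floats(0.01, 10.0), min_size=6, max_size=6),
    st.lists(st.floats(0.05, 0.95), min_size=3, max_size=3),
    st.lists(st.floats(0.05, 10.0), min_size=3, max_size=3),
    st.floats(1e-5, 0.05),
)
@settings(derandomize=True, max_examples=150)
def test_total_probability_conserved(raw_joint, p_ob, raw_edu, p_cvd):
    """sum_{O,E} Pr(CVD|O,E) Pr(O|E) Pr(E) == Pr(CVD) to 1e-10 for any
    valid components."""
    joint = np.array(raw_joint).reshape(3, 2)
    joint /= joint.sum()
    p_edu = np.array(raw_edu) / np.sum(raw_edu)
    c = _components(joint, p_cvd, p_ob, p_edu)
    cond = conditional_probability(c)
    denom = p_edu[:, None] * np.stack([1 - np.array(p_ob), np.array(p_ob)], axis=1)
    assert abs((cond * denom).sum() - p_cvd) < 1e-10


def test_unit_joint_vector():
    """All CVD deaths obese + low education: the joint is a unit vector and
    only that cell has positive conditional probability."""
    joint = np.zeros((3, 2))
    joint[0, 1] = 1.0
    out = conditional_probability(_components(joint, 1e-3, [0.4, 0.4, 0.3], [0.2, 0.5, 0.3]))
    assert out[0, 1] > 0
    assert (out.ravel()[np.arange(6) != 1] == 0).all()


def test_zero_denominator_rejected():
    joint = np.full((3, 2), 1 / 6)
    with pytest.raises(ZeroDivisionError):
        conditional_probability(_components(joint, 1e-3, [0.4, 0.4, 0.3], [0.0, 0.7, 0.3]))


def test_invalid_components_rejected():
    with pytest.raises(ValueError):
        conditional_probability(_components(np.full((3, 2), 0.2), 1e-3, [0.4] * 3, [0.2, 0.5, 0.3]))


def test_micro_oracle_equivalence():
    """On a fully enumerated population with a perfect proxy, Bayes fusion
    from shared micro counts equals direct stratified counting."""
    w = build_world(seed=13, pop_size=150_000)
    t = w.year_index(2012)
    expo = w.stratum_exposures()[:, :, t]                       # (A,S,3,2)
    rng = np.random.default_rng(99)
    deaths = rng.binomial(expo, w.cond_prob[:, :, t])
    for ai in range(2):
        for si in range(2):
            d, e = deaths[ai, si].astype(float), expo[ai, si].astype(float)
            fused = conditional_probability(components_from_micro(d, e))
            np.testing.assert_allclose(fused, d / e, rtol=1e-12, atol=0)


def test_components_scale_invariance():
    d = np.array([[30.0, 50.0], [40.0, 60.0], [10.0, 20.0]])
    e = np.array([[1e4, 8e3], [2e4, 1.4e4], [9e3, 4e3]])
    a = conditional_probability(components_from_micro(d, e))
    b = conditional_probability(components_from_micro(2 * d, 2 * e))
    np.testing.assert_allclose(a, b, rtol=1e-12)


def test_monotonicity_in_stratum_deaths():
    """Adding deaths to one (O,E) stratum (components re-estimated from the
    same death file) never decreases that stratum's conditional probability."""
    base = np.array([[30.0, 50.0], [40.0, 60.0], [10.0, 20.0]])
    e = np.full((3, 2), 1e5)
    p_ob, p_edu = np.array([0.45, 0.4, 0.3]), np.array([0.2, 0.5, 0.3])
    prev_vals = None
    for extra in (0.0, 10.0, 50.0, 200.0):
        d = base.copy()
        d[1, 1] += extra
        joint = d / d.sum()
        cond = conditional_probability(
            _components(joint, d.sum() / e.sum(), p_ob, p_edu)
        )
        if prev_vals is not None:
            assert cond[1, 1] >= prev_vals - 1e-15
        prev_vals = cond[1, 1]


def test_tabulation_redistributes_unknown_education(small_world):
    deaths = synth.generate_deaths(small_world, years=[2010])
    classified = classify_deaths(deaths)
    with_r = tabulate_cvd_deaths(classified, redistribute_unknown=True)
    without = tabulate_cvd_deaths(classified, redistribute_unknown=False)
    # redistribution conserves the total CVD death count
    assert with_r["deaths"].sum() == pytest.approx(classified["is_cvd"].sum())
    assert without["deaths"].sum() < with_r["deaths"].sum()
    # per (cell, obesity) the known-education proportions are unchanged
    key = ["age_group", "sex", "year", "obese"]
    a = with_r.set_index(key + ["education"])["deaths"]
    b = without.set_index(key + ["education"])["deaths"]
    ratio = (a / b).dropna()
    per_cell = ratio.groupby(level=key, observed=True)
    assert float((per_cell.max() - per_cell.min()).max()) < 1e-9


def test_cell_component_recovery(small_world):
    """Components estimated from one generated cell sit within sampling
    error of the world-implied values."""
    year = 2010
    deaths = synth.generate_deaths(small_world, years=[year])
    classified = classify_deaths(deaths)
    counts = tabulate_cvd_deaths(classified)
    exposures = synth.generate_exposures(small_world, years=[year])
    prev = []
    edu = []
    t = small_world.year_index(year)
    for ai, ag in enumerate(small_world.age_groups):
        for si, sex in enumerate(small_world.sexes):
            for ei, lv in enumerate(small_world.edu_levels):
                prev.append((ag, sex, year, lv, small_world.obesity_prev[ai, si, t, ei]))
                edu.append((ag, sex, year, lv, small_world.edu_shares[ai, si, t, ei]))
    prev = pd.DataFrame(prev, columns=["age_group", "sex", "year", "education", "p_obese"])
    edu = pd.DataFrame(edu, columns=["age_group", "sex", "year", "education", "share"])
    rc = components_from_data(counts, exposures, prev, edu, "60-64", "male", year)
    ai, si = 5, 1
    true_p = small_world.cond_prob[ai, si, t]
    expo = small_world.stratum_exposures()[ai, si, t]
    true_p_cvd = (expo * true_p).sum() / expo.sum()
    assert rc.p_cvd == pytest.approx(true_p_cvd, rel=0.1)
    true_joint = expo * true_p / (expo * true_p).sum()
    assert np.abs(rc.joint_given_cvd - true_joint).max() < 0.05


def test_cell_errors_are_named():
    counts = pd.DataFrame(
        {"age_group": ["35-39"], "sex": ["female"], "year": [2010],
         "education": ["low"], "obese": [1], "deaths": [0.0]}
    )
    expo = pd.DataFrame(
        {"age_group": ["35-39"], "sex": ["female"], "year": [2010], "person_years": [1000]}
    )
    with pytest.raises(ValueError, match="zero CVD deaths"):
        components_from_data(counts, expo, None, None, "35-39", "female", 2010)


def test_aggregate_age_constant_and_equal_weights(small_run):
    surface = small_run["surface"].copy()
    exposures = small_run["exposures"]
    surface["prob"] = 2.5e-3                      # age-constant surface
    agg = aggregate_all_ages(surface, exposures)
    np.testing.assert_allclose(agg["prob"], 2.5e-3, rtol=1e-12)
    # equal exposures: exposure weighting equals the simple mean
    surface2 = small_run["surface"]
    a = aggregate_all_ages(surface2, exposures, weighting="exposure")
    b = aggregate_all_ages(surface2, exposures, weighting="equal")
    pd.testing.assert_frame_equal(a, b)           # pop_size constant per cell


def test_aggregate_missing_age_rejected(small_run):
    surface = small_run["surface"]
    trimmed = surface[surface["age_group"] != "50-54"]
    with pytest.raises(ValueError, match="missing age group"):
        aggregate_all_ages(trimmed, small_run["exposures"])


def test_conditional_surface_matches_componentwise_path(small_run):
    """The vectorized surface equals the per-cell components route."""
    surface = small_run["surface"]
    sel = surface[(surface["age_group"] == "55-59") & (surface["sex"] == "female")
                  & (surface["year"] == 2011)]
    rc = components_from_data(
        small_run["counts"], small_run["exposures"], small_run["prev_surface"],
        small_run["edu_dist"], "55-59", "female", 2011,
    )
    cond = conditional_probability(rc)
    for row in sel.itertuples():
        e = ["low", "middle", "high"].index(row.education)
        assert row.prob == pytest.approx(cond[e, int(row.obesity)], rel=1e-10)
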