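"""Parametric ground-truth world for the synthetic data generators.

The world encodes, for every (age group, sex, year) stratum of the premature
(35-74 y) population:

* ``edu_shares``      -- Pr(E), the education distribution over {low, middle, high};
* ``obesity_prev``    -- Pr(O=1 | E), obesity prevalence given education;
* ``cond_prob``       -- Pr(CVD death | O, E), the annual probability of a
  cardiovascular death given obesity status and education.

``cond_prob`` is log-linear in calendar year: each (education, obesity)
stratum has an anchor value in the first year and a constant annual log
drift (``trend_slopes``), so the true surfaces are exactly
``anchor * exp(slope * (year - year0))``.  Default parameters are calibrated
so that, in the final year, obesity prevalence is higher at low/middle than
at high education, the conditional death probability is ordered
obese > non-obese within each education level and low > middle > high within
each obesity status, and the all-age obese-low / non-obese-high ratio is
about 6 -- the disparity regime reported for the US in 2019.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

EDU_LEVELS = ("low", "middle", "high")
SEXES = ("female", "male")
OBESITY = (0, 1)  # 0 = non-obese, 1 = obese

#: default per-(education, obesity) annual log drifts of Pr(CVD | O, E).
#: Rows follow EDU_LEVELS, columns (non-obese, obese).  Non-obese strata
#: decline (fastest at high education), obese strata rise.
DEFAULT_TREND_SLOPES = np.array(
    [
        [-0.004, 0.010],  # low
        [-0.006, 0.012],  # middle
        [-0.014, 0.006],  # high
    ]
)

_BASE_LOG_PROB = np.log(6.0e-4)  # age 35-39, female, middle edu, non-obese, year0
_AGE_LOG_STEP = 0.28             # log-rate increase per 5-year age band
_MALE_LOG_EFFECT = 0.35
_EDU_LOG_EFFECTS = np.array([0.45, 0.0, -0.55])  # low, middle, high
_OBESITY_LOG_EFFECT = 0.45


def default_age_groups() -> list[str]:
    return [f"{a}-{a + 4}" for a in range(35, 75, 5)]


@dataclass
class GroundTruthWorld:
    """True parameters of the synthetic population.

    Array axes are (age, sex, year[, education[, obesity]]) with categories
    ordered as ``age_groups``, ``SEXES``, ``years``, ``EDU_LEVELS``,
    ``OBESITY``.
    """

    years: np.ndarray
    age_groups: list[str]
    edu_shares: np.ndarray        # (A, S, T, 3)
    obesity_prev: np.ndarray      # (A, S, T, 3)
    cond_prob: np.ndarray         # (A, S, T, 3, 2)
    trend_slopes: np.ndarray      # (3, 2)
    pop_size: int = 4_000_000
    marker_sensitivity: float = 1.0
    marker_false_positive: float = 0.0
    unknown_edu_rate: float = 0.03
    seed: int = 0
    sexes: tuple = SEXES
    edu_levels: tuple = EDU_LEVELS

    # -- validation -------------------------------------------------------

    def validate(self) -> None:
        A, S, T = len(self.age_groups), len(self.sexes), len(self.years)
        if self.edu_shares.shape != (A, S, T, 3):
            raise ValueError(f"edu_shares shape {self.edu_shares.shape} != {(A, S, T, 3)}")
        if self.obesity_prev.shape != (A, S, T, 3):
            raise ValueError("obesity_prev has wrong shape")
        if self.cond_prob.shape != (A, S, T, 3, 2):
            raise ValueError("cond_prob has wrong shape")
        sums = self.edu_shares.sum(axis=-1)
        if not np.allclose(sums, 1.0, atol=1e-12, rtol=0):
            raise ValueError("edu_shares vectors must sum to 1 within 1e-12")
        for name, arr in [
            ("edu_shares", self.edu_shares),
            ("obesity_prev", self.obesity_prev),
            ("cond_prob", self.cond_prob),
        ]:
            if not ((arr > 0.0) & (arr < 1.0)).all():
                raise ValueError(f"{name} must lie strictly inside (0, 1)")
        for name, p in [
            ("marker_sensitivity", self.marker_sensitivity),
            ("marker_false_positive", self.marker_false_positive),
            ("unknown_edu_rate", self.unknown_edu_rate),
        ]:
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.pop_size <= 0:
            raise ValueError("pop_size must be positive")
        # cond_prob must reproduce exactly from its year-0 anchor and slopes
        t = np.arange(T)
        rebuilt = self.cond_prob[:, :, :1] * np.exp(
            self.trend_slopes[None, None, None] * t[None, None, :, None, None]
        )
        if not np.allclose(rebuilt, self.cond_prob, rtol=1e-12, atol=0):
            raise ValueError("cond_prob is not log-linear in year with the given slopes")

    # -- derived true quantities ------------------------------------------

    def year_index(self, year: int) -> int:
        idx = np.nonzero(self.years == year)[0]
        if idx.size == 0:
            raise ValueError(f"year {year} not in world years")
        return int(idx[0])

    def stratum_exposures(self) -> np.ndarray:
        """Integer person-years per (age, sex, year, education, obesity) cell.

        Expected counts pop_size * Pr(E) * Pr(O|E), integerized by largest
        remainder so every (age, sex, year) slice sums exactly to pop_size.
        """
        p_eo = self.edu_shares[..., None] * np.stack(
            [1.0 - self.obesity_prev, self.obesity_prev], axis=-1
        )  # (A,S,T,3,2)
        flat = p_eo.reshape(-1, 6) * self.pop_size
        floors = np.floor(flat).astype(np.int64)
        deficit = self.pop_size - floors.sum(axis=1)
        order = np.argsort(-(flat - floors), axis=1, kind="stable")
        take = np.arange(6)[None, :] < deficit[:, None]
        out = floors.copy()
        rows = np.repeat(np.arange(flat.shape[0]), 6).reshape(flat.shape[0], 6)
        out[rows[take], order[take]] += 1
        return out.reshape(p_eo.shape)

    def true_aggregate(self, year: int, pool_sexes: bool = True) -> np.ndarray:
        """True all-age (optionally sex-pooled) Pr(CVD | O, E), shape (3, 2).

        Mean of the per-(age, sex) conditional probabilities weighted by
        total (age, sex) person-years -- the same crude weighting the
        pipeline's aggregation applies (the census-style exposure table has
        no education or obesity breakdown, so per-stratum weights are not
        part of the estimand).
        """
        t = self.year_index(year)
        expo = self.stratum_exposures()[:, :, t].astype(float).sum(axis=(-2, -1))  # (A,S)
        prob = self.cond_prob[:, :, t]                                             # (A,S,3,2)
        axes = (0, 1) if pool_sexes else (0,)
        w = expo[..., None, None]
        return (w * prob).sum(axis=axes) / w.sum(axis=axes)


def _softmax(scores: np.ndarray) -> np.ndarray:
    e = np.exp(scores - scores.max(axis=-1, keepdims=True))
    return e / e.sum(axis=-1, keepdims=True)


def build_world(
    seed: int = 0,
    *,
    years: tuple[int, int] = (2003, 2019),
    pop_size: int = 4_000_000,
    marker_sensitivity: float = 1.0,
    marker_false_positive: float = 0.0,
    unknown_edu_rate: float = 0.03,
    trend_slopes: np.ndarray | float | None = None,
    edu_shares_const: tuple | None = None,
    obesity_prev_const: float | None = None,
    cond_prob_const: float | None = None,
) -> GroundTruthWorld:
    """Construct a (deterministic) ground-truth world.

    Parameters
    ----------
    seed
        Stored on the world and used by the stochastic generators; the world
        itself is a deterministic function of its parameters.
    trend_slopes
        (3, 2) array of per-(education, obesity) annual log drifts, or a
        scalar applied everywhere (0 gives a time-constant world).
    edu_shares_const, obesity_prev_const, cond_prob_const
        Override the default structured surfaces with spatially/temporally
        constant values -- useful for homogeneous-world checks.
    """
    y0, y1 = years
    if y1 < y0:
        raise ValueError("years range is reversed")
    yrs = np.arange(y0, y1 + 1)
    ages = default_age_groups()
    A, S, T = len(ages), len(SEXES), len(yrs)
    i = np.arange(A)[:, None, None]           # age index
    s = np.arange(S)[None, :, None]           # 0 female, 1 male
    t = np.arange(T)[None, None, :]

    if trend_slopes is None:
        slopes = DEFAULT_TREND_SLOPES.copy()
    else:
        slopes = np.broadcast_to(np.asarray(trend_slopes, dtype=float), (3, 2)).copy()

    if edu_shares_const is not None:
        shares_vec = np.asarray(edu_shares_const, dtype=float)
        if abs(shares_vec.sum() - 1.0) > 1e-12:
            raise ValueError("edu_shares_const must sum to 1")
        edu_shares = np.broadcast_to(shares_vec, (A, S, T, 3)).copy()
    else:
        score = np.empty((A, S, T, 3))
        score[..., 0] = -1.20 - 0.030 * t + 0.080 * i          # low
        score[..., 1] = 0.55                                    # middle
        score[..., 2] = -0.25 + 0.035 * t - 0.060 * i + 0.10 * (1 - s)  # high
        edu_shares = _softmax(score)

    if obesity_prev_const is not None:
        obesity_prev = np.full((A, S, T, 3), float(obesity_prev_const))
    else:
        base = np.array([-0.40, -0.36, -1.05])                  # low, middle, high
        logit = (
            base[None, None, None, :]
            + 0.022 * t[..., None]
            - 0.010 * (i[..., None] - 4.5) ** 2
        ) * np.ones((A, S, T, 3))
        obesity_prev = 1.0 / (1.0 + np.exp(-logit))

    if cond_prob_const is not None:
        anchor = np.full((A, S, 1, 3, 2), float(cond_prob_const))
    else:
        log_anchor = (
            _BASE_LOG_PROB
            + _AGE_LOG_STEP * i[..., None, None]
            + _MALE_LOG_EFFECT * s[..., None, None]
            + _EDU_LOG_EFFECTS[None, None, None, :, None]
            + _OBESITY_LOG_EFFECT * np.array([0.0, 1.0])[None, None, None, None, :]
        )
        anchor = np.exp(log_anchor[:, :, :1])
    cond_prob = anchor * np.exp(slopes[None, None, None] * np.arange(T)[None, None, :, None, None])

    world = GroundTruthWorld(
        years=yrs,
        age_groups=ages,
        edu_shares=edu_shares,
        obesity_prev=obesity_prev,
        cond_prob=cond_prob,
        trend_slopes=slopes,
        pop_size=int(pop_size),
        marker_sensitivity=float(marker_sensitivity),
        marker_false_positive=float(marker_false_positive),
        unknown_edu_rate=float(unknown_edu_rate),
        seed=int(seed),
    )
    world.validate()
    return world
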