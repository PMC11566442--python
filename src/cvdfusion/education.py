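"""Harmonization of education codes to three attainment levels.

Four coding schemes are supported, mirroring the sources a US mortality
analysis must reconcile:

* ``v1989`` -- death-certificate years of schooling (1989 revision);
* ``v2003`` -- death-certificate attainment categories (2003 revision);
* ``acs``   -- household-survey attainment codes (SCHL-style);
* ``nhanes`` -- examination-survey attainment codes (DMDEDUC2-style).

Every code maps onto {low, middle, high, unknown}: low = did not complete
high school; middle = high school diploma or GED up to, but not including,
a Bachelor's degree (some college and associate degrees are middle);
high = Bachelor's degree or higher.  The per-scheme lookup tables ship as
``data/education_codes.csv`` and are the single source of truth.
"""

from __future__ import annotations

import logging
from importlib import resources

import pandas as pd

logger = logging.getLogger(__name__)

LEVELS = ("low", "middle", "high")
SCHEMES = ("v1989", "v2003", "acs", "nhanes")


def load_education_table() -> pd.DataFrame:
    """The shipped scheme/code/label/level lookup table."""
    with resources.files("cvdfusion.data").joinpath("education_codes.csv").open() as fh:
        df = pd.read_csv(fh)
    df["code"] = df["code"].astype(int)
    return df


_TABLE = load_education_table()
_LOOKUP: dict[tuple[str, int], str] = {
    (row.scheme, row.code): row.level for row in _TABLE.itertuples()
}


def harmonize_education(code: int, version: str) -> str:
    """Map a scheme-specific education code to a harmonized level.

    Unseen codes map to ``"unknown"`` (and are logged) rather than raising:
    real vital-statistics files contain stray codes.
    """
    if version not in SCHEMES:
        raise ValueError(f"unknown education coding scheme: {version!r}")
    level = _LOOKUP.get((version, int(code)))
    if level is None:
        logger.warning("unseen education code %r in scheme %s -> unknown", code, version)
        return "unknown"
    return level


def harmonize_series(codes: pd.Series, versions: pd.Series | str) -> pd.Series:
    """Vectorized harmonization; ``versions`` may be a scalar scheme name."""
    if isinstance(versions, str):
        if versions not in SCHEMES:
            raise ValueError(f"unknown education coding scheme: {versions!r}")
        versions = pd.Series(versions, index=codes.index)
    frame = pd.DataFrame({"scheme": versions.values, "code": codes.astype(int).values})
    merged = frame.merge(_TABLE[["scheme", "code", "level"]], on=["scheme", "code"], how="left")
    return pd.Series(merged["level"].fillna("unknown").values, index=codes.index)
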