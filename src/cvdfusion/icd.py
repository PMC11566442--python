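"""Multiple-cause-of-death ICD-10 classification.

A death is a CVD death if *any* code on the certificate (part 1 chain of
events or part 2 contributing conditions) falls in I00-I45 or I47-I99;
cardiac arrest (I46) is deliberately excluded, which is why the CVD set is
two ranges rather than I00-I99 minus I46.  A CVD death is obesity-related
if the certificate additionally carries at least one marker code for a
condition with elevated mortality risk under obesity: diabetes (E10-E14),
chronic kidney disease (N18), obesity (E65-E66), lipidemias (E78) or
hypertension (I10-I15).  Membership is decided on the 3-character category:
a 4th or later character never disqualifies a matching category (E11.9
counts as E11).

The range definitions ship as an editable data file
(``data/code_sets.csv``) and are loaded at import time.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources

import pandas as pd

#: ICD-10 code grammar: letter, two digits, optional dot, 0-2 alphanumerics.
_CODE_RE = re.compile(r"^[A-Z][0-9]{2}\.?[0-9A-Z]{0,2}$")


@dataclass(frozen=True)
class CodeSet:
    """A named union of inclusive 3-character ICD-10 category ranges."""

    name: str
    ranges: tuple[tuple[str, str], ...]

    def __post_init__(self):
        for start, end in self.ranges:
            if len(start) != 3 or len(end) != 3 or start > end:
                raise ValueError(f"bad range ({start}, {end}) in code set {self.name}")


def _load_code_sets() -> dict[str, CodeSet]:
    with resources.files("cvdfusion.data").joinpath("code_sets.csv").open() as fh:
        df = pd.read_csv(fh)
    out = {}
    for name, grp in df.groupby("set_name"):
        out[name] = CodeSet(name, tuple(zip(grp["start"], grp["end"])))
    return out


_SETS = _load_code_sets()
CVD_SET: CodeSet = _SETS["cvd"]
MARKER_SET: CodeSet = _SETS["obesity_marker"]


def code_in_set(code: str, code_set: CodeSet) -> bool:
    """True if the code's 3-character category lies in any range of the set.

    Raises ``ValueError`` on a malformed code -- malformed input is never
    silently classified as a non-match.
    """
    code = code.strip().upper()
    if not _CODE_RE.match(code):
        raise ValueError(f"malformed ICD-10 code: {code!r}")
    cat = code[:3]
    return any(start <= cat <= end for start, end in code_set.ranges)


def _any_in_set(codes, code_set: CodeSet) -> bool:
    return any(code_in_set(c, code_set) for c in codes)


def is_cvd_death(part1_codes, part2_codes) -> bool:
    """Any-mention CVD death: >=1 CVD code anywhere on the certificate."""
    if not part1_codes:
        raise ValueError("part 1 of a death certificate cannot be empty")
    return _any_in_set(part1_codes, CVD_SET) or _any_in_set(part2_codes, CVD_SET)


def is_obesity_related_cvd(part1_codes, part2_codes) -> bool:
    """CVD death that also mentions >=1 obesity marker code (proxy for
    CVD death of an obese decedent)."""
    return is_cvd_death(part1_codes, part2_codes) and (
        _any_in_set(part1_codes, MARKER_SET) or _any_in_set(part2_codes, MARKER_SET)
    )


def classify_deaths(deaths: pd.DataFrame) -> pd.DataFrame:
    """Vectorized classification of a death-record table.

    ``deaths`` must have semicolon-joined ``part1_codes`` / ``part2_codes``
    string columns.  Returns a copy with boolean ``is_cvd`` and
    ``is_obesity_related`` columns.  Membership is evaluated once per unique
    code, so national-scale files classify in seconds.
    """
    part1 = deaths["part1_codes"].fillna("")
    part2 = deaths["part2_codes"].fillna("")
    if (part1.str.len() == 0).any():
        raise ValueError("part 1 of a death certificate cannot be empty")
    joined = part1.str.cat(part2, sep=";").str.rstrip(";")
    unique_lists = joined.unique()
    cvd_map, marker_map = {}, {}
    for entry in unique_lists:
        codes = entry.split(";")
        cvd_map[entry] = _any_in_set(codes, CVD_SET)
        marker_map[entry] = _any_in_set(codes, MARKER_SET)
    out = deaths.copy()
    out["is_cvd"] = joined.map(cvd_map).astype(bool)
    out["is_obesity_related"] = out["is_cvd"] & joined.map(marker_map).astype(bool)
    return out
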