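"""Shared configuration for the numbered analysis scripts.

The analysis runs the default 2003-2019 world at one million person-years
per (age group, sex, year) -- large enough that every stratum is densely
observed, small enough that each script finishes in seconds and the flat
files stay modest.  All scripts write under results/analysis/.
"""

from pathlib import Path

from cvdfusion.pipeline import RunConfig

OUTDIR = Path(__file__).resolve().parent.parent / "results" / "analysis"

CONFIG = RunConfig(seed=0, pop_size=1_000_000)


def outpath(name: str) -> Path:
    OUTDIR.mkdir(parents=True, exist_ok=True)
    return OUTDIR / name
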