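"""Annualized CVD mortality trends and projection figures.

Computes the annualized % rate of change in the overall CVD mortality rate
per sex and age group (Poisson log-linear regression with exposure offset)
for 2003-2011, 2011-2019 and the full span, and draws the actual+projected
conditional-probability panels (log scale, shaded 95% prediction
intervals).
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import CONFIG, outpath

import pandas as pd

from cvdfusion.fusion import tabulate_cvd_deaths
from cvdfusion.icd import classify_deaths
from cvdfusion.pipeline import _trend_table
from cvdfusion.plots import plot_aggregate_projection


def main():
    deaths = pd.read_csv(outpath("deaths.csv"))
    classified = classify_deaths(deaths)
    exposures = pd.read_csv(outpath("exposures.csv"))
    trends = _trend_table(classified, exposures, CONFIG)
    trends.to_csv(outpath("annualized_trends.csv"), index=False)

    print("annualized % change in overall CVD mortality (95% CI):")
    for r in trends[trends["age_group"].isin(["35-39", "70-74"])].itertuples():
        print(f"  {r.sex:<6} {r.age_group} {r.period}: "
              f"{r.annual_pct_change:+.1f}% ({r.lower:+.1f} to {r.upper:+.1f})")

    aggregate = pd.read_csv(outpath("conditional_aggregate.csv"))
    proj = pd.read_csv(outpath("projections_aggregate.csv"))
    for sex in ("female", "male"):
        path = outpath(f"projection_{sex}.png")
        plot_aggregate_projection(aggregate, proj, sex, path)
        print(f"wrote {path}")


if __name__ == "__main__":
    main()
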