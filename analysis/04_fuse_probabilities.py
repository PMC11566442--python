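"""Bayes fusion into Pr(CVD | obesity, education).

Combines the tabulated CVD deaths, exposures and the two survey surfaces
into the conditional probability of premature CVD death per age group, sex
and year, plus the exposure-weighted all-age aggregate.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import CONFIG, outpath

import pandas as pd

from cvdfusion.fusion import aggregate_all_ages, conditional_surface


def main():
    surface = conditional_surface(
        pd.read_csv(outpath("cvd_death_counts.csv")),
        pd.read_csv(outpath("exposures.csv")),
        pd.read_csv(outpath("obesity_prevalence.csv")),
        pd.read_csv(outpath("education_distribution.csv")),
    )
    aggregate = aggregate_all_ages(surface, pd.read_csv(outpath("exposures.csv")))
    surface.to_csv(outpath("conditional_surface.csv"), index=False)
    aggregate.to_csv(outpath("conditional_aggregate.csv"), index=False)

    last = CONFIG.years[1]
    sel = aggregate[aggregate["year"] == last].set_index(["sex", "education", "obesity"])
    print(f"all-age Pr(CVD | O, E) per 100,000, {last}:")
    for sex in ("female", "male"):
        row = {
            (edu, ob): sel.loc[(sex, edu, ob), "prob_per_100k"]
            for edu in ("low", "middle", "high")
            for ob in (0, 1)
        }
        print(f"  {sex:<6} " + "  ".join(
            f"{edu[0].upper()}{'ob' if ob else 'no'}={row[(edu, ob)]:6.1f}"
            for edu in ("low", "middle", "high") for ob in (1, 0)
        ))
        ratio = row[("low", 1)] / row[("high", 0)]
        print(f"         obese-low vs non-obese-high disparity: {ratio:.1f}x")


if __name__ == "__main__":
    main()
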