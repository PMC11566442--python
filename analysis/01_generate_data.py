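"""Generate the four synthetic source datasets.

Builds the default ground-truth world (2003-2019, eight 5-year age bands
35-74, both sexes) and writes the death-certificate file, the census-style
exposure table and the two weighted surveys, plus the manifest that makes
every later table re-derivable.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import CONFIG, outpath

import yaml

from cvdfusion.pipeline import synthesize


def main():
    data = synthesize(CONFIG)
    deaths = data["deaths"].drop(columns=["true_education", "true_obesity"])
    deaths.to_csv(outpath("deaths.csv"), index=False)
    data["exposures"].to_csv(outpath("exposures.csv"), index=False)
    data["edu_survey"].to_csv(outpath("education_survey.csv"), index=False)
    data["prev_survey"].to_csv(outpath("prevalence_survey.csv"), index=False)
    outpath("manifest.yaml").write_text(yaml.safe_dump({"config": CONFIG.to_dict()}))

    w = data["world"]
    print(f"world: {len(w.years)} years x {len(w.age_groups)} age groups x 2 sexes, "
          f"pop {w.pop_size:,} per cell")
    print(f"deaths:             {len(deaths):>9,} records")
    print(f"education survey:   {len(data['edu_survey']):>9,} records")
    print(f"prevalence survey:  {len(data['prev_survey']):>9,} records")
    agg = w.true_aggregate(int(w.years[-1]))
    print(f"true 2019 obese-low / non-obese-high disparity: {agg[0, 1] / agg[2, 0]:.2f}")


if __name__ == "__main__":
    main()
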