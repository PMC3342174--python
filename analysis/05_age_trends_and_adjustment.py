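#!/usr/bin/env python
"""Age trends and age-adjusted disease association.

Per CpG: the least-squares methylation-on-age trend in T1D cases (the
young-cohort calibration carries no built-in slope), an age-trend run on
an older-cohort variant with a -0.2 %/yr drift enabled, and the
age-adjusted logistic regression of disease on methylation.
"""

from pathlib import Path

import pandas as pd

from insmeth import loci
from insmeth.association_stats import age_trend, logistic_adjusted
from insmeth.synthetic_cohort import (generate_cohort, t1d_default,
                                      with_age_slopes)

ROOT = Path(__file__).resolve().parents[1]
SEED = 1


def main() -> None:
    results = ROOT / "results"
    results.mkdir(exist_ok=True)
    cohort = generate_cohort(t1d_default(seed=SEED))
    cases = cohort[cohort.group == "T1D"]

    aged_cfg = with_age_slopes(t1d_default(seed=SEED + 1), -0.2)
    aged = generate_cohort(aged_cfg)
    aged_cases = aged[aged.group == "T1D"]

    rows = []
    for c in loci.CPG_TABLE_ORDER:
        col = loci.meth_column(c)
        young = age_trend(cases[col], cases["age"], unit=c)
        old = age_trend(aged_cases[col], aged_cases["age"], unit=c)
        logit = logistic_adjusted(cohort["group"], cohort[col],
                                  cohort["age"], case_label="T1D", unit=c)
        rows.append({
            "cpg": loci.display_label(c),
            "young_slope": round(young.statistic, 3),
            "young_p": young.p_display,
            "aged_slope": round(old.statistic, 3),
            "aged_p": old.p_display,
            "adj_odds_ratio_per_percent": round(logit.statistic, 3),
            "adj_p": logit.p_display,
        })
    table = pd.DataFrame(rows)
    table.to_csv(results / "age_trends_and_adjusted.tsv", sep="\t",
                 index=False)
    print(table.to_string(index=False))
    print("\nfinding: the young-cohort calibration shows no age trend "
          "(slopes ~0); the aged variant recovers the enabled -0.2 %/yr "
          "drift at every CpG; the age-adjusted odds ratios stay below 1 "
          "at the hypomethylated CpGs (higher methylation is protective) "
          "and above 1 at CpG -180.")


if __name__ == "__main__":
    main()
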