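#!/usr/bin/env python
"""Per-CpG case-control rank-sum tests and the CpG-CpG correlation
matrix, for both cohorts.

Writes one tidy row per cohort x CpG (mean±sd per group, Wilcoxon p)
and the Pearson correlation matrix of the T1D cases, and reports which
CpGs separate cases from controls.
"""

from pathlib import Path

import pandas as pd

from insmeth import loci
from insmeth.association_stats import correlation_matrix, wilcoxon_case_control
from insmeth.synthetic_cohort import generate_cohort, t1d_default, t2d_default

ROOT = Path(__file__).resolve().parents[1]
SEED = 1


def main() -> None:
    results = ROOT / "results"
    results.mkdir(exist_ok=True)
    rows = []
    for name, factory, case_label in (("t1d", t1d_default, "T1D"),
                                      ("t2d", t2d_default, "T2D")):
        cohort = generate_cohort(factory(seed=SEED))
        cases = cohort[cohort.group == case_label]
        ctrls = cohort[cohort.group == "control"]
        for c in loci.CPG_TABLE_ORDER:
            col = loci.meth_column(c)
            res = wilcoxon_case_control(cases[col], ctrls[col], unit=c,
                                        labels=(case_label, "control"))
            s = res.group_summaries
            rows.append({
                "cohort": name, "cpg": loci.display_label(c),
                "case_mean": round(s[case_label]["mean"], 1),
                "case_sd": round(s[case_label]["sd"], 1),
                "control_mean": round(s["control"]["mean"], 1),
                "control_sd": round(s["control"]["sd"], 1),
                "p_value": res.p_value, "p_display": res.p_display,
                "direction": res.direction,
            })
    tests = pd.DataFrame(rows)
    tests.to_csv(results / "case_control_tests.tsv", sep="\t", index=False)
    print(tests.to_string(index=False))

    t1d = generate_cohort(t1d_default(seed=SEED))
    cases = t1d[t1d.group == "T1D"]
    corr = correlation_matrix(
        cases[[loci.meth_column(c) for c in loci.CPG_TABLE_ORDER]])
    r = corr.r.round(3)
    r.index = r.columns = [loci.display_label(c) for c in loci.CPG_TABLE_ORDER]
    r.to_csv(results / "correlation_matrix_t1d_cases.tsv", sep="\t")
    print("\nT1D-case Pearson correlations (disease-associated CpGs):")
    trio = ["CpG -19", "CpG -135", "CpG -234", "CpG -180"]
    print(r.loc[trio, trio].to_string())
    print("\nfinding: CpGs -19/-135/-234 are strongly case-hypomethylated "
          "and mutually correlated; in the T2D cohort CpG -19 drops while "
          "CpG -234 rises, the opposite signature.")


if __name__ == "__main__":
    main()
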