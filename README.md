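# insmeth

Case-control analysis of CpG methylation in the proximal insulin (*INS*)
gene promoter.

The *INS* locus is one of the strongest genetic risk regions for type 1
diabetes (T1D). The seven CpG dinucleotides in the ~250 bp immediately
upstream of the *INS* transcription start site (at −19, −69, −102, −135,
−180, −206 and −234 bp) show a CpG-specific methylation pattern in the
whole-blood DNA of T1D patients: CpGs −19, −135 and −234 are
hypomethylated relative to controls, CpG −180 is slightly
hypermethylated, and the remainder are unchanged. A subset of patients
carries *simultaneous* hypomethylation of CpGs −19, −135 and −234 — a
candidate multi-CpG disease signature — and four of the seven CpGs are
under strong cis-genotype control by the T1D-risk SNP rs689
(allele-specific methylation).

This package implements that analysis end to end, driven by a calibrated
synthetic-cohort generator so every stage is testable without any data
download:

- **`insmeth.synthetic_cohort`** — Gaussian-copula cohort simulation:
  per-group percent-methylation marginals `X = μ_g + σ_g·Z` with
  `Z ~ N(0, R_g)`, additive genotype effects `Σ_s β_s·g_s`, an optional
  linear age trend, and LD-structured haplotype genotypes. Shipped
  calibrations: `t1d_default` (485 cases / 317 controls) and
  `t2d_default` (132 / 186).
- **`insmeth.reference_classifier`** — the relative-hypomethylation rule:
  a subject is flagged at a CpG when their value falls strictly below
  `μ_control − 2·σ_control`; multi-CpG patterns are conjunctions of
  flags.
- **`insmeth.association_stats`** — Wilcoxon rank-sum case-control tests
  (exact for small untied samples), Kruskal–Wallis genotype–methylation
  tests, pairwise CpG–CpG correlation with p-values, least-squares age
  trends, age-adjusted logistic regression, and Fisher's exact test for
  2×2 pattern tables.
- **`insmeth.cohort_io`** — the tab-separated cohort dialect, reference
  and result JSON, and bedGraph export of cohort-mean methylation at
  user-supplied genomic coordinates.
- **`insmeth.reporting`** / **`insmeth.cli`** — the
  simulate → classify → associate → report pipeline, summary tables,
  heatmap clustering orderings, and the `insmeth` command-line tool.

## Worked example

```python
from insmeth import (t1d_default, generate_cohort, fit_reference,
                     classify_subjects, detect_pattern, pattern_counts,
                     wilcoxon_case_control)

cohort = generate_cohort(t1d_default(seed=1))        # 485 T1D + 317 controls
controls = cohort[cohort.group == "control"]

ref = fit_reference(controls)                        # per-CpG mean, SD, n
print(round(ref.mean["m135"], 1), round(ref.sd["m135"], 1))
# 68.4 5.0   -> -2SD threshold 58.3

flags = classify_subjects(cohort, ref)
detect_pattern(flags, ("m19", "m135", "m234"), "triple")
print(pattern_counts(flags, "triple").to_string(index=False))
#   group  members   n  percent
#     T1D      126 485       26
# control        1 317        0

case = cohort.loc[cohort.group == "T1D", "meth_m135"]
ctrl = controls["meth_m135"]
print(wilcoxon_case_control(case, ctrl).p_display)
# <2.2e-16
```

The numbers read as: the simulated controls at CpG −135 average 68.4 %
methylation (SD 5.0), so the hypomethylation cut-off is 58.3 %; 126 of
485 simulated cases (26 %) but essentially no control carry the
simultaneous three-CpG hypomethylation; and the case–control shift at
CpG −135 is significant far beyond the 2.2e-16 display floor.

The same pipeline runs from the shell:

```bash
insmeth run --preset t1d_default --seed 1 --out-dir bundle/
insmeth simulate --preset t2d_default --seed 1 --out cohort.tsv
insmeth classify --cohort cohort.tsv --out flags.json
insmeth associate --cohort cohort.tsv --by-genotype rs689 --out assoc.json
```

The numbered scripts under `analysis/` walk through the full study —
simulation, classification, case-control statistics, the
genotype–methylation (ASM) screen, and age trends — writing their tables
under `results/`.

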