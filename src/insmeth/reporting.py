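"""Pipeline orchestration and publication-style outputs.

``run_pipeline`` chains simulate -> classify -> associate -> summarize
and writes a reproducible result bundle; ``summarize`` renders the
case/control summary table (one row per CpG plus the multi-CpG pattern
row); ``heatmap_order`` computes the hierarchical-clustering row/column
orderings used for methylation heatmaps (complete linkage, Euclidean
distance — the defaults of the classic R heatmap.2 display) without
producing a plot.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist

from . import association_stats as ast
from . import cohort_io, loci
from .errors import ConfigError, DegenerateDataError
from .reference_classifier import (
    FlagMatrix, ReferenceModel, classify_subjects, detect_pattern,
    fit_reference, pattern_contingency, pattern_counts)
from .synthetic_cohort import GeneratorConfig, generate_cohort

__all__ = ["summarize", "heatmap_order", "run_pipeline", "PipelineResult",
           "HeatmapOrder"]


def _fmt_int(x: float) -> str:
    return str(int(round(x)))


def summarize(cohort: pd.DataFrame,
              flags: FlagMatrix,
              associations: dict[str, ast.AssociationResult],
              case_label: str,
              control_label: str,
              pattern_name: str | None = None) -> pd.DataFrame:
    """Case/control summary: mean ± sd per group, rank-sum p, and
    hypomethylated-subject counts, one row per CpG plus a pattern row.

    The pattern row summarizes the per-subject mean over the member
    CpGs.  Display columns round to integers as in the published
    tables; full-precision columns are kept alongside.
    """
    if flags.hypo.shape[0] == 0 or flags.hypo.shape[1] == 0:
        raise ConfigError("empty flag matrix")
    ids = set(cohort["subject_id"])
    if set(flags.hypo.index) - ids or ids - set(flags.hypo.index):
        raise ConfigError("flag matrix and cohort cover different subjects")

    counts = flags.flag_counts().set_index(["group", "cpg"])
    rows = []
    groups = cohort.groupby("group")
    case = groups.get_group(case_label)
    ctrl = groups.get_group(control_label)

    def one_row(label: str, case_vals, ctrl_vals, res, hypo_key):
        cm, cs = float(np.mean(case_vals)), float(np.std(case_vals, ddof=1))
        km, ks = float(np.mean(ctrl_vals)), float(np.std(ctrl_vals, ddof=1))
        row = {
            "unit": label,
            "case_mean": cm, "case_sd": cs,
            "control_mean": km, "control_sd": ks,
            "case_display": f"{_fmt_int(cm)}±{_fmt_int(cs)}",
            "control_display": f"{_fmt_int(km)}±{_fmt_int(ks)}",
            "p_value": res.p_value, "p_display": res.p_display,
        }
        if hypo_key is not None:
            ck = counts.loc[(case_label, hypo_key)] if (case_label, hypo_key) in counts.index else None
            kk = counts.loc[(control_label, hypo_key)] if (control_label, hypo_key) in counts.index else None
            if ck is not None:
                row.update(case_hypo_n=int(ck["n_flagged"]),
                           case_hypo_percent=int(ck["percent"]))
            if kk is not None:
                row.update(control_hypo_n=int(kk["n_flagged"]),
                           control_hypo_percent=int(kk["percent"]))
        return row

    for c in loci.CPG_TABLE_ORDER:
        col = loci.meth_column(c)
        res = associations[c]
        rows.append(one_row(loci.display_label(c),
                            case[col].dropna(), ctrl[col].dropna(), res, c))

    if pattern_name is not None:
        members = flags.pattern_members[pattern_name]
        cols = [loci.meth_column(c) for c in members]
        case_comp = case[cols].mean(axis=1).dropna()
        ctrl_comp = ctrl[cols].mean(axis=1).dropna()
        res = ast.wilcoxon_case_control(case_comp, ctrl_comp,
                                        unit=pattern_name)
        pc = pattern_counts(flags, pattern_name).set_index("group")
        row = one_row("CpGs " + ", ".join(str(loci.CPG_OFFSETS[c]) for c in members),
                      case_comp, ctrl_comp, res, None)
        row.update(
            case_hypo_n=int(pc.loc[case_label, "members"]),
            case_hypo_percent=int(pc.loc[case_label, "percent"]),
            control_hypo_n=int(pc.loc[control_label, "members"]),
            control_hypo_percent=int(pc.loc[control_label, "percent"]),
        )
        rows.append(row)
    return pd.DataFrame(rows).set_index("unit")


@dataclass
class HeatmapOrder:
    row_order: list
    col_order: list
    row_heights: np.ndarray
    col_heights: np.ndarray


def heatmap_order(meth_block: pd.DataFrame) -> HeatmapOrder:
    """Row/column orderings from agglomerative clustering (Euclidean
    distance, complete linkage) of the complete-case methylation matrix.

    Rows are sorted by index label before clustering, which makes the
    leaf order deterministic and invariant to input row permutation
    (ties between equal-distance merges are broken by label order).
    """
    block = meth_block.dropna(axis=0, how="any").sort_index()
    if block.shape[0] < 2:
        raise DegenerateDataError("need at least 2 complete rows to cluster")
    x = block.to_numpy(float)
    zr = linkage(pdist(x), method="complete")
    zc = linkage(pdist(x.T), method="complete") if block.shape[1] >= 2 else None
    row_order = [block.index[i] for i in leaves_list(zr)]
    col_order = (
        [block.columns[i] for i in leaves_list(zc)] if zc is not None
        else list(block.columns)
    )
    return HeatmapOrder(
        row_order=row_order,
        col_order=col_order,
        row_heights=zr[:, 2],
        col_heights=zc[:, 2] if zc is not None else np.empty(0),
    )


@dataclass
class PipelineResult:
    out_dir: Path
    cohort: pd.DataFrame
    reference: ReferenceModel
    flags: FlagMatrix
    summary: pd.DataFrame
    associations: dict = field(default_factory=dict)
    paths: dict = field(default_factory=dict)


def run_pipeline(config: GeneratorConfig | None = None,
                 cohort: pd.DataFrame | None = None,
                 out_dir: str | Path = "pipeline_out",
                 case_label: str | None = None,
                 control_label: str = "control",
                 pattern: tuple[str, ...] = loci.TRIPLE_PATTERN,
                 pattern_name: str = "triple_hypo",
                 corr_method: str = "pearson",
                 asm_snps: tuple[str, ...] = loci.SNPS,
                 write_plots: bool = False) -> PipelineResult:
    """End-to-end run: simulate (or take a cohort), fit the control
    reference, classify, test, summarize, and write the bundle.

    The bundle (cohort TSV, reference JSON, flags TSV, associations
    JSON, summary TSV/JSON, log JSON with config hash + seed) is fully
    reproducible: identical config ⇒ byte-identical numeric outputs.
    """
    if (config is None) == (cohort is None):
        raise ConfigError("provide exactly one of config or cohort")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if config is not None:
        config.validate()
        cohort = generate_cohort(config)
    cohort = cohort_io.validate_cohort(cohort.copy())

    groups = list(dict.fromkeys(cohort["group"]))
    if control_label not in groups:
        raise ConfigError(f"control group {control_label!r} not in cohort "
                          f"(groups: {groups})")
    if case_label is None:
        others = [g for g in groups if g != control_label]
        if len(others) != 1:
            raise ConfigError(f"ambiguous case group among {others}")
        case_label = others[0]

    controls = cohort[cohort["group"] == control_label]
    cases = cohort[cohort["group"] == case_label]

    ref = fit_reference(controls, source_label=control_label)
    flags = classify_subjects(cohort, ref)
    detect_pattern(flags, pattern, pattern_name)

    case_flags = classify_subjects(cases, ref)
    ctrl_flags = classify_subjects(controls, ref)
    detect_pattern(case_flags, pattern, pattern_name)
    detect_pattern(ctrl_flags, pattern, pattern_name)
    table2x2 = pattern_contingency(case_flags, ctrl_flags, pattern_name)
    try:
        fisher = ast.fisher_exact_2x2(table2x2, unit=pattern_name)
        fisher_payload = fisher.to_dict()
    except DegenerateDataError as exc:
        # e.g. no pattern carrier in either group: report, don't abort
        fisher_payload = {"degenerate": str(exc), "table": table2x2.tolist()}

    per_cpg: dict[str, ast.AssociationResult] = {}
    logistic: dict[str, dict] = {}
    trends: dict[str, dict] = {}
    for c in loci.CPG_TABLE_ORDER:
        col = loci.meth_column(c)
        per_cpg[c] = ast.wilcoxon_case_control(
            cases[col], controls[col], unit=c,
            labels=(case_label, control_label))
        logistic[c] = ast.logistic_adjusted(
            cohort["group"], cohort[col], cohort["age"],
            case_label=case_label, unit=c).to_dict()
        trends[c] = ast.age_trend(cases[col], cases["age"], unit=c).to_dict()

    corr = ast.correlation_matrix(
        cases[[loci.meth_column(c) for c in loci.CPG_TABLE_ORDER]],
        method=corr_method)

    asm: dict[str, dict[str, dict]] = {}
    for snp in asm_snps:
        gcol = loci.geno_column(snp)
        if gcol not in cohort.columns:
            continue
        asm[snp] = {}
        for c in loci.CPG_TABLE_ORDER:
            asm[snp][c] = ast.kruskal_wallis_by_genotype(
                cases[loci.meth_column(c)], cases[gcol],
                unit=f"{snp}:{c}").to_dict()

    summary = summarize(cohort, flags, per_cpg, case_label, control_label,
                        pattern_name=pattern_name)

    # ---- write bundle ------------------------------------------------
    paths = {}
    paths["cohort"] = out / "cohort.tsv"
    cohort_io.write_cohort(cohort, paths["cohort"])
    paths["reference"] = out / "reference.json"
    ref.to_json(paths["reference"])
    paths["flags"] = out / "flags.tsv"
    flag_df = flags.hypo.astype("object").join(flags.patterns.astype("object"),
                                               rsuffix="_pattern")
    flag_df.to_csv(paths["flags"], sep="\t", na_rep="NA")
    paths["summary_tsv"] = out / "summary.tsv"
    summary.to_csv(paths["summary_tsv"], sep="\t")
    paths["associations"] = out / "associations.json"
    assoc_payload = {
        "case_control_wilcoxon": {c: r.to_dict() for c, r in per_cpg.items()},
        "logistic_age_adjusted": logistic,
        "age_trend_cases": trends,
        "pattern": {
            "name": pattern_name,
            "members": list(pattern),
            "contingency": table2x2.tolist(),
            "fisher": fisher_payload,
            "counts": pattern_counts(flags, pattern_name).to_dict("records"),
        },
        "correlation": {
            "method": corr.method,
            "r": corr.r.round(10).to_dict(),
            "p": corr.p.to_dict(),
        },
        "genotype_kruskal_wallis": asm,
    }
    with open(paths["associations"], "w") as fh:
        json.dump(assoc_payload, fh, indent=2, sort_keys=True, allow_nan=True)

    cfg_json = config.to_json() if config is not None else None
    paths["log"] = out / "log.json"
    import numpy, pandas, scipy  # noqa: PLC0415
    log = {
        "seed": config.seed if config is not None else None,
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest()
        if cfg_json else None,
        "n_subjects": int(len(cohort)),
        "groups": {g: int((cohort["group"] == g).sum()) for g in groups},
        "versions": {"numpy": numpy.__version__, "scipy": scipy.__version__,
                     "pandas": pandas.__version__},
    }
    with open(paths["log"], "w") as fh:
        json.dump(log, fh, indent=2, sort_keys=True)

    if write_plots:  # optional, never part of the test surface
        _write_plots(cases, out)

    return PipelineResult(out_dir=out, cohort=cohort, reference=ref,
                          flags=flags, summary=summary,
                          associations=assoc_payload, paths=paths)


def _write_plots(cases: pd.DataFrame, out: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    block = cases[[loci.meth_column(c) for c in loci.CPG_TABLE_ORDER]]
    order = heatmap_order(block.set_axis(cases["subject_id"]))
    fig, ax = plt.subplots(figsize=(6, 8))
    ax.imshow(block.set_axis(cases["subject_id"]).loc[order.row_order,
                                                      order.col_order],
              aspect="auto", cmap="RdYlBu")
    ax.set_xticks(range(len(order.col_order)))
    ax.set_xticklabels(order.col_order, rotation=90)
    ax.set_yticks([])
    fig.tight_layout()
    fig.savefig(out / "heatmap.png", dpi=120)
    plt.close(fig)
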