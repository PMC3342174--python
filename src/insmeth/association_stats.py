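"""Inferential statistics for methylation case-control analysis.

* Wilcoxon rank-sum for case-vs-control methylation at each CpG (exact
  enumeration for small untied samples, normal approximation with tie
  correction otherwise, no continuity correction);
* Kruskal-Wallis for methylation across genotype groups (allele-specific
  methylation / mQTL screening);
* pairwise CpG-CpG correlation with p-values (Pearson default,
  Spearman optional);
* least-squares age trend;
* age-adjusted logistic regression (disease ~ methylation + age);
* Fisher's exact test for 2x2 pattern contingency tables.

Raw two-sided p-values are reported throughout (no multiple-testing
correction by default, Benjamini-Hochberg available); displayed p-values
are floored at ``<2.2e-16`` following the R convention, while the
machine-readable value keeps full precision.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, DegenerateDataError

__all__ = [
    "AssociationResult",
    "CorrelationMatrix",
    "format_p",
    "wilcoxon_case_control",
    "kruskal_wallis_by_genotype",
    "correlation_matrix",
    "age_trend",
    "logistic_adjusted",
    "fisher_exact_2x2",
    "benjamini_hochberg",
]

P_DISPLAY_FLOOR = 2.2e-16


def format_p(p: float) -> str:
    """Display convention: values below 2.2e-16 print as ``<2.2e-16``."""
    if not (0 <= p <= 1):
        raise ValueError(f"p-value {p} outside [0, 1]")
    return "<2.2e-16" if p < P_DISPLAY_FLOOR else f"{p:.3g}"


@dataclass
class AssociationResult:
    """One test result: statistic, two-sided p, group summaries, direction."""

    unit: str
    test: str
    statistic_name: str
    statistic: float
    p_value: float
    group_summaries: dict[str, dict[str, float]] = field(default_factory=dict)
    direction: float = 0.0
    extras: dict = field(default_factory=dict)

    @property
    def p_display(self) -> str:
        return format_p(self.p_value)

    def to_dict(self) -> dict:
        return {
            "unit": self.unit,
            "test": self.test,
            "statistic_name": self.statistic_name,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "p_display": self.p_display,
            "direction": self.direction,
            "group_summaries": self.group_summaries,
            **({"extras": self.extras} if self.extras else {}),
        }


def _summary(values: np.ndarray) -> dict[str, float]:
    return {
        "mean": float(np.mean(values)),
        "sd": float(np.std(values, ddof=1)) if len(values) > 1 else float("nan"),
        "n": int(len(values)),
    }


def _clean(values) -> np.ndarray:
    arr = np.asarray(pd.to_numeric(pd.Series(values), errors="coerce"), dtype=float)
    return arr[~np.isnan(arr)]


def wilcoxon_case_control(values_a, values_b,
                          unit: str = "",
                          labels: tuple[str, str] = ("cases", "controls")
                          ) -> AssociationResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Exact enumeration of the rank-sum null when both samples have
    n <= 10 and there are no ties; otherwise the normal approximation
    with the tie-corrected variance and no continuity correction (which
    preserves the H = z^2 identity with the two-group Kruskal-Wallis).
    """
    a, b = _clean(values_a), _clean(values_b)
    if len(a) == 0 or len(b) == 0:
        raise DegenerateDataError("empty sample in rank-sum test")
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        warnings.warn("all values identical in both samples; p = 1")
        return AssociationResult(
            unit=unit, test="wilcoxon_rank_sum", statistic_name="U",
            statistic=len(a) * len(b) / 2.0, p_value=1.0,
            group_summaries={labels[0]: _summary(a), labels[1]: _summary(b)},
            direction=0.0,
        )
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (len(a) <= 10 and len(b) <= 10 and not has_ties) \
        else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided",
                             method=method, use_continuity=False)
    return AssociationResult(
        unit=unit, test="wilcoxon_rank_sum", statistic_name="U",
        statistic=float(res.statistic), p_value=float(res.pvalue),
        group_summaries={labels[0]: _summary(a), labels[1]: _summary(b)},
        direction=float(np.sign(np.mean(a) - np.mean(b))),
        extras={"method": method},
    )


def kruskal_wallis_by_genotype(values, genotypes, unit: str = "") -> AssociationResult:
    """Kruskal-Wallis H across genotype groups (complete cases).

    Tie-corrected H; p from chi-square with k-1 df.  All-tied data give
    H = 0, p = 1 rather than a NaN.
    """
    v = np.asarray(pd.to_numeric(pd.Series(values), errors="coerce"), float)
    g = np.asarray(pd.to_numeric(pd.Series(genotypes), errors="coerce"), float)
    keep = ~(np.isnan(v) | np.isnan(g))
    v, g = v[keep], g[keep]
    levels = np.unique(g)
    groups = [v[g == lev] for lev in levels]
    if len(groups) < 2:
        raise DegenerateDataError(
            f"need >= 2 genotype groups, got {len(groups)}"
        )
    summaries = {f"genotype_{int(lev)}": _summary(gr)
                 for lev, gr in zip(levels, groups)}
    if np.ptp(v) == 0:
        return AssociationResult(
            unit=unit, test="kruskal_wallis", statistic_name="H",
            statistic=0.0, p_value=1.0, group_summaries=summaries,
        )
    res = stats.kruskal(*groups)
    per_allele = np.polyfit(g, v, 1)[0] if len(levels) > 1 else 0.0
    return AssociationResult(
        unit=unit, test="kruskal_wallis", statistic_name="H",
        statistic=float(res.statistic), p_value=float(res.pvalue),
        group_summaries=summaries, direction=float(np.sign(per_allele)),
        extras={"df": len(groups) - 1,
                "medians": {f"genotype_{int(lev)}": float(np.median(gr))
                            for lev, gr in zip(levels, groups)}},
    )


@dataclass
class CorrelationMatrix:
    """Pairwise correlation of methylation columns with p-values.

    ``r`` is symmetric with unit diagonal; entries that are undefined
    (constant column, too few complete pairs) are NaN and listed in
    ``undefined``.  ``adjusted_r2`` gives the auxiliary adjusted-R²
    view of each pairwise coefficient.
    """

    r: pd.DataFrame
    p: pd.DataFrame
    n: pd.DataFrame
    method: str
    undefined: list[tuple[str, str]] = field(default_factory=list)

    def adjusted_r2(self) -> pd.DataFrame:
        r2 = self.r**2
        nn = self.n
        return 1 - (1 - r2) * (nn - 1) / (nn - 2)


def correlation_matrix(meth_block: pd.DataFrame,
                       method: str = "pearson",
                       min_pairs: int = 3) -> CorrelationMatrix:
    """Pairwise CpG-CpG correlation with two-sided p (t transform).

    Complete cases per pair; a constant column makes its entries
    undefined (NaN, flagged) rather than silently zero.
    """
    if method not in ("pearson", "spearman"):
        raise ConfigError(f"unknown correlation method {method!r}")
    cols = list(meth_block.columns)
    k = len(cols)
    r = np.eye(k)
    p = np.zeros((k, k))
    n = np.full((k, k), len(meth_block), dtype=float)
    undefined: list[tuple[str, str]] = []
    data = {c: pd.to_numeric(meth_block[c], errors="coerce").to_numpy(float)
            for c in cols}
    fn = stats.pearsonr if method == "pearson" else stats.spearmanr
    for i in range(k):
        for j in range(i + 1, k):
            x, y = data[cols[i]], data[cols[j]]
            keep = ~(np.isnan(x) | np.isnan(y))
            x, y = x[keep], y[keep]
            n[i, j] = n[j, i] = len(x)
            if len(x) < min_pairs:
                raise DegenerateDataError(
                    f"fewer than {min_pairs} complete pairs for "
                    f"({cols[i]}, {cols[j]})"
                )
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                r[i, j] = r[j, i] = np.nan
                p[i, j] = p[j, i] = np.nan
                undefined.append((cols[i], cols[j]))
                continue
            res = fn(x, y)
            r[i, j] = r[j, i] = float(res.statistic)
            p[i, j] = p[j, i] = float(res.pvalue)
    idx = pd.Index(cols)
    return CorrelationMatrix(
        r=pd.DataFrame(r, index=idx, columns=idx),
        p=pd.DataFrame(p, index=idx, columns=idx),
        n=pd.DataFrame(n, index=idx, columns=idx),
        method=method,
        undefined=undefined,
    )


def age_trend(values, ages, unit: str = "") -> AssociationResult:
    """Least-squares methylation-on-age trend: slope (%/yr), r, p."""
    v = np.asarray(pd.to_numeric(pd.Series(values), errors="coerce"), float)
    a = np.asarray(pd.to_numeric(pd.Series(ages), errors="coerce"), float)
    keep = ~(np.isnan(v) | np.isnan(a))
    v, a = v[keep], a[keep]
    if len(v) < 3:
        raise DegenerateDataError(f"age trend needs n >= 3, got {len(v)}")
    if np.ptp(a) == 0:
        raise DegenerateDataError("constant age: trend undefined")
    res = stats.linregress(a, v)
    return AssociationResult(
        unit=unit, test="age_trend", statistic_name="slope",
        statistic=float(res.slope), p_value=float(res.pvalue),
        group_summaries={"all": _summary(v)},
        direction=float(np.sign(res.slope)),
        extras={"r": float(res.rvalue), "intercept": float(res.intercept),
                "stderr": float(res.stderr)},
    )


def logistic_adjusted(disease_labels, meth_values, ages,
                      case_label=None, unit: str = "",
                      maxiter: int = 50, tol: float = 1e-8
                      ) -> AssociationResult:
    """Age-adjusted logistic regression: disease ~ methylation + age.

    Newton (IRLS) maximum likelihood; per-percent odds ratio with Wald
    p.  Perfect separation or non-convergence raises an explicit
    :class:`DegenerateDataError` instead of returning huge coefficients.
    """
    import statsmodels.api as sm
    from statsmodels.tools.sm_exceptions import (
        PerfectSeparationError, PerfectSeparationWarning)

    lab = pd.Series(disease_labels)
    v = np.asarray(pd.to_numeric(pd.Series(meth_values), errors="coerce"), float)
    a = np.asarray(pd.to_numeric(pd.Series(ages), errors="coerce"), float)
    keep = ~(np.isnan(v) | np.isnan(a) | lab.isna().to_numpy())
    lab, v, a = lab[keep], v[keep], a[keep]
    classes = sorted(lab.unique())
    if len(classes) != 2:
        raise DegenerateDataError(
            f"logistic regression needs exactly 2 classes, got {classes}"
        )
    if case_label is None:
        case_label = classes[0] if classes[0] != "control" else classes[1]
    y = (lab == case_label).to_numpy(int)
    X = np.column_stack([np.ones(len(v)), v, a])
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", PerfectSeparationWarning)
            fit = sm.Logit(y, X).fit(method="newton", maxiter=maxiter,
                                     tol=tol, disp=0)
    except (PerfectSeparationError, PerfectSeparationWarning) as exc:
        raise DegenerateDataError(f"perfect separation: {exc}") from exc
    if not fit.mle_retvals.get("converged", False):
        raise DegenerateDataError("logistic regression did not converge")
    beta = float(fit.params[1])
    return AssociationResult(
        unit=unit, test="logistic_age_adjusted", statistic_name="odds_ratio",
        statistic=float(np.exp(beta)), p_value=float(fit.pvalues[1]),
        group_summaries={
            str(case_label): _summary(v[y == 1]),
            "reference": _summary(v[y == 0]),
        },
        direction=float(np.sign(beta)),
        extras={"log_or": beta, "se": float(fit.bse[1]),
                "age_log_or": float(fit.params[2]), "case_label": str(case_label)},
    )


def fisher_exact_2x2(table, unit: str = "") -> AssociationResult:
    """Two-sided Fisher exact test on a 2×2 count table.

    p sums hypergeometric probabilities (fixed margins) of tables at
    most as probable as the observed one.  The stored statistic is the
    Haldane-Anscombe (+0.5) odds ratio so it stays finite with a zero
    cell; the raw conditional odds ratio is kept in extras.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2):
        raise ConfigError(f"expected a 2x2 table, got shape {t.shape}")
    if np.any(t < 0):
        raise ConfigError("negative counts in contingency table")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise DegenerateDataError("zero margin in contingency table")
    res = stats.fisher_exact(t, alternative="two-sided")
    a, b, c, d = t.ravel().astype(float)
    or_ha = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    return AssociationResult(
        unit=unit, test="fisher_exact", statistic_name="odds_ratio_haldane",
        statistic=float(or_ha), p_value=float(res.pvalue),
        direction=float(np.sign(np.log(or_ha))),
        extras={"table": t.tolist(),
                "odds_ratio_raw": float(res.statistic)},
    )


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """BH-adjusted p-values (optional; the primary reports are raw p)."""
    from statsmodels.stats.multitest import multipletests
    return multipletests(np.asarray(p_values, float), method="fdr_bh")[1]
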