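"""Control-reference distribution fitting and the −2SD hypomethylation rule.

The classifier implements the study's definition of *relative
hypomethylation*: a subject's percent methylation at a CpG is flagged
when it falls strictly below ``control mean − 2 × control SD``, with the
reference fit on a designated control cohort of the same population
(never pooled with cases).  Multi-CpG patterns — in particular the
triple signature at CpG −19, −135 and −234 — are conjunctions of per-CpG
flags over subjects with complete data at the member CpGs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import loci
from .errors import ConfigError, DegenerateDataError

__all__ = [
    "ReferenceModel",
    "FlagMatrix",
    "fit_reference",
    "hypomethylation_threshold",
    "classify_subjects",
    "detect_pattern",
    "pattern_counts",
    "pattern_contingency",
]


@dataclass(frozen=True)
class ReferenceModel:
    """Per-CpG control mean, sample SD (n−1 divisor) and n."""

    mean: Mapping[str, float]
    sd: Mapping[str, float]
    n: Mapping[str, int]
    source_label: str = "controls"

    @property
    def cpgs(self) -> tuple[str, ...]:
        return tuple(self.mean)

    def threshold(self, cpg: str) -> float:
        return hypomethylation_threshold(self, cpg)

    def to_dict(self) -> dict:
        return {
            "source_label": self.source_label,
            "cpgs": {
                c: {"mean": self.mean[c], "sd": self.sd[c], "n": self.n[c],
                    "hypo_threshold": self.mean[c] - 2 * self.sd[c]}
                for c in self.mean
            },
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)

    @classmethod
    def from_dict(cls, d: Mapping) -> "ReferenceModel":
        cpgs = d["cpgs"]
        return cls(
            mean={c: v["mean"] for c, v in cpgs.items()},
            sd={c: v["sd"] for c, v in cpgs.items()},
            n={c: v["n"] for c, v in cpgs.items()},
            source_label=d.get("source_label", "controls"),
        )

    @classmethod
    def from_json(cls, path) -> "ReferenceModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass
class FlagMatrix:
    """Per-subject per-CpG hypomethylation flags plus pattern membership.

    ``hypo`` uses pandas nullable booleans: NA marks a missing
    methylation value.  ``patterns`` holds one column per named pattern;
    a subject missing any member CpG is NA there (excluded), not False.
    """

    hypo: pd.DataFrame
    group: pd.Series
    patterns: pd.DataFrame = field(default_factory=pd.DataFrame)
    pattern_members: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def flag_counts(self) -> pd.DataFrame:
        """Per-group per-CpG count of flagged subjects, group size and
        integer percentage."""
        rows = []
        for g, idx in self.hypo.groupby(self.group).groups.items():
            sub = self.hypo.loc[idx]
            for c in sub.columns:
                k = int((sub[c] == True).sum())  # noqa: E712 (NA-aware)
                n = len(sub)
                rows.append({"group": g, "cpg": c, "n_flagged": k,
                             "n": n, "percent": round(100 * k / n)})
        return pd.DataFrame(rows)


def fit_reference(controls: pd.DataFrame,
                  cpgs: Sequence[str] = loci.CPG_TABLE_ORDER,
                  min_n: int = 3,
                  source_label: str = "controls") -> ReferenceModel:
    """Fit the per-CpG control distribution (mean, sample SD, n).

    Raises :class:`DegenerateDataError` when fewer than ``min_n``
    non-missing control values are available at some CpG or when a CpG
    has zero variance.
    """
    if len(controls) == 0:
        raise DegenerateDataError("empty control cohort")
    mean, sd, n = {}, {}, {}
    for c in cpgs:
        col = loci.meth_column(c)
        if col not in controls.columns:
            raise ConfigError(f"control table lacks column {col!r}")
        vals = pd.to_numeric(controls[col], errors="coerce").dropna().to_numpy()
        if len(vals) < min_n:
            raise DegenerateDataError(
                f"{c}: only {len(vals)} usable control values (< {min_n})"
            )
        s = float(np.std(vals, ddof=1))
        if s == 0.0:
            raise DegenerateDataError(f"{c}: zero variance in controls")
        mean[c], sd[c], n[c] = float(np.mean(vals)), s, int(len(vals))
    return ReferenceModel(mean=mean, sd=sd, n=n, source_label=source_label)


def hypomethylation_threshold(ref: ReferenceModel, cpg: str) -> float:
    """The −2SD rule: flag values strictly below ``mean − 2 sd``."""
    if cpg not in ref.mean:
        raise ConfigError(f"unknown CpG {cpg!r}; reference covers {list(ref.mean)}")
    assert ref.sd[cpg] > 0, "zero-variance reference should be rejected at fit time"
    return ref.mean[cpg] - 2.0 * ref.sd[cpg]


def classify_subjects(table: pd.DataFrame, ref: ReferenceModel) -> FlagMatrix:
    """Apply the −2SD rule to every subject and CpG.

    ``hypo_flag = value < threshold`` (strict: a value exactly at the
    threshold is not "below" it); missing values yield NA flags.
    """
    missing = [c for c in ref.cpgs if loci.meth_column(c) not in table.columns]
    if missing:
        raise ConfigError(f"cohort lacks methylation columns for {missing}")
    flags = pd.DataFrame(index=pd.Index(table["subject_id"], name="subject_id"))
    for c in ref.cpgs:
        vals = pd.to_numeric(table[loci.meth_column(c)], errors="coerce").to_numpy()
        thr = hypomethylation_threshold(ref, c)
        col = pd.array(vals < thr, dtype="boolean")
        col[np.isnan(vals)] = pd.NA
        flags[c] = col
    group = pd.Series(table["group"].to_numpy(), index=flags.index, name="group")
    return FlagMatrix(hypo=flags, group=group,
                      patterns=pd.DataFrame(index=flags.index))


def detect_pattern(flags: FlagMatrix,
                   pattern_cpgs: Iterable[str],
                   name: str = "triple") -> FlagMatrix:
    """Add a named multi-CpG pattern: membership is the conjunction of
    the member-CpG flags; subjects missing any member value are NA."""
    members = tuple(pattern_cpgs)
    if not members:
        raise ConfigError("empty pattern set")
    unknown = [c for c in members if c not in flags.hypo.columns]
    if unknown:
        raise ConfigError(f"pattern references unflagged CpGs: {unknown}")
    sub = flags.hypo[list(members)]
    membership = sub.all(axis=1, skipna=False).astype("boolean")
    membership[sub.isna().any(axis=1)] = pd.NA
    if flags.patterns.shape[1] == 0:
        flags.patterns = pd.DataFrame(index=flags.hypo.index)
    flags.patterns[name] = membership
    flags.pattern_members[name] = members
    return flags


def pattern_counts(flags: FlagMatrix, name: str) -> pd.DataFrame:
    """Per-group pattern membership count and integer percentage.

    The denominator is the full group size (NA-membership subjects count
    as non-members), matching the published n-of-N convention.
    """
    if name not in flags.patterns.columns:
        raise ConfigError(f"unknown pattern {name!r}")
    rows = []
    col = flags.patterns[name]
    for g, idx in col.groupby(flags.group).groups.items():
        k = int((col.loc[idx] == True).sum())  # noqa: E712
        n = len(idx)
        rows.append({"group": g, "members": k, "n": n,
                     "percent": round(100 * k / n)})
    return pd.DataFrame(rows)


def pattern_contingency(case_flags: FlagMatrix,
                        control_flags: FlagMatrix,
                        name: str) -> np.ndarray:
    """2×2 table [[case members, case non-members],
    [control members, control non-members]].

    Both cohorts must be classified against the same reference; the
    caller feeds the table to the Fisher exact test.
    """
    overlap = case_flags.patterns.index.intersection(control_flags.patterns.index)
    if len(overlap):
        raise ConfigError(
            f"subject ids present in both cohorts, e.g. {overlap[0]!r}"
        )
    cells = []
    for fl in (case_flags, control_flags):
        if name not in fl.patterns.columns:
            raise ConfigError(f"pattern {name!r} not detected on both cohorts")
        col = fl.patterns[name]
        k = int((col == True).sum())  # noqa: E712
        cells.append([k, len(col) - k])
    table = np.array(cells, dtype=np.int64)
    if table.sum() == 0:
        raise DegenerateDataError("all-zero contingency table")
    return table
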