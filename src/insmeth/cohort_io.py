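"""Reading, validation and writing of cohort tables; bedGraph export.

The cohort file dialect is a tab-separated table with a header row, one
row per subject, ``NA`` as the missing-value token, and the columns::

    subject_id  group  age  sex
    meth_m19 meth_m69 meth_m102 meth_m135 meth_m180 meth_m206 meth_m234
    geno_rs689 geno_rs3842748 geno_rs4320932 geno_rs6356
    hba1c  duration

Methylation values are percentages in [0, 100] serialized with 2
decimals; genotypes are risk-allele counts in {0, 1, 2} or NA.  Unknown
extra columns are carried through untouched.
"""

from __future__ import annotations

import io
import math
from typing import Iterable, Sequence

import pandas as pd

from . import loci
from .errors import CohortValidationError, ConfigError, DegenerateDataError

__all__ = [
    "REQUIRED_COLUMNS",
    "OPTIONAL_COLUMNS",
    "NA_TOKEN",
    "validate_cohort",
    "read_cohort",
    "write_cohort",
    "export_bedgraph",
]

NA_TOKEN = "NA"
REQUIRED_COLUMNS: list[str] = ["subject_id", "group", "age", "sex"] + loci.METH_COLUMNS
OPTIONAL_COLUMNS: list[str] = loci.GENO_COLUMNS + ["hba1c", "duration"]
_METH_DECIMALS = 2


def _fail(row, column, message) -> None:
    raise CohortValidationError(f"row {row}, column {column!r}: {message}")


def validate_cohort(table: pd.DataFrame,
                    expected_groups: Iterable[str] | None = None,
                    require_genotypes: Sequence[str] | None = None) -> pd.DataFrame:
    """Validate a cohort table in place; returns the table on success.

    ``require_genotypes`` names SNPs whose geno_* column must be present
    (requested by genotype-stratified analyses).
    """
    for col in REQUIRED_COLUMNS:
        if col not in table.columns:
            raise CohortValidationError(f"missing required column {col!r}")
    if require_genotypes:
        for snp in require_genotypes:
            col = loci.geno_column(snp)
            if col not in table.columns:
                raise CohortValidationError(
                    f"genotype analysis for {snp} requested but column "
                    f"{col!r} is missing"
                )
    dup = table["subject_id"][table["subject_id"].duplicated()]
    if len(dup):
        raise CohortValidationError(f"duplicate subject_id {dup.iloc[0]!r}")
    if expected_groups is not None:
        bad = set(table["group"]) - set(expected_groups)
        if bad:
            row = table.index[table["group"].isin(bad)][0]
            _fail(row, "group", f"unknown group label {sorted(bad)[0]!r}")
    for col in loci.METH_COLUMNS:
        vals = pd.to_numeric(table[col], errors="coerce")
        bad_parse = table.index[vals.isna() & table[col].notna()]
        if len(bad_parse):
            _fail(bad_parse[0], col, f"malformed number {table.loc[bad_parse[0], col]!r}")
        out = table.index[(vals < 0) | (vals > 100)]
        if len(out):
            _fail(out[0], col, f"methylation {vals[out[0]]} outside [0, 100]")
        table[col] = vals
    for col in loci.GENO_COLUMNS:
        if col not in table.columns:
            continue
        vals = pd.to_numeric(table[col], errors="coerce")
        bad_parse = table.index[vals.isna() & table[col].notna()]
        if len(bad_parse):
            _fail(bad_parse[0], col, f"malformed genotype {table.loc[bad_parse[0], col]!r}")
        out = table.index[vals.notna() & ~vals.isin([0, 1, 2])]
        if len(out):
            _fail(out[0], col, f"genotype {vals[out[0]]} not in {{0, 1, 2}}")
        table[col] = vals
    ages = pd.to_numeric(table["age"], errors="coerce")
    neg = table.index[ages < 0]
    if len(neg):
        _fail(neg[0], "age", f"negative age {ages[neg[0]]}")
    table["age"] = ages
    for col in ("hba1c", "duration"):
        if col in table.columns:
            table[col] = pd.to_numeric(table[col], errors="coerce")
    return table


def read_cohort(path,
                expected_groups: Iterable[str] | None = None,
                require_genotypes: Sequence[str] | None = None) -> pd.DataFrame:
    """Read and validate a cohort TSV."""
    table = pd.read_csv(
        path, sep="\t", dtype=str, na_values=[NA_TOKEN], keep_default_na=False
    )
    return validate_cohort(table, expected_groups=expected_groups,
                           require_genotypes=require_genotypes)


def _format_cell(value, decimals: int) -> str:
    if value is None or (isinstance(value, float) and math.isnan(value)) or pd.isna(value):
        return NA_TOKEN
    return f"{float(value):.{decimals}f}"


def write_cohort(table: pd.DataFrame, path) -> None:
    """Serialize a cohort table; deterministic bytes for a fixed table.

    Methylation / clinical values get 2 decimals, ages 2 decimals,
    genotypes are integers; missing values become ``NA``.
    """
    validate_cohort(table.copy())
    out = pd.DataFrame(index=table.index)
    for col in table.columns:
        if col in loci.METH_COLUMNS or col in ("hba1c", "duration", "age"):
            out[col] = [_format_cell(v, _METH_DECIMALS) for v in table[col]]
        elif col in loci.GENO_COLUMNS:
            out[col] = [
                NA_TOKEN if pd.isna(v) else str(int(v)) for v in table[col]
            ]
        else:
            out[col] = [NA_TOKEN if pd.isna(v) else str(v) for v in table[col]]
    buf = io.StringIO()
    out.to_csv(buf, sep="\t", index=False, lineterminator="\n")
    with open(path, "w", newline="") as fh:
        fh.write(buf.getvalue())


def export_bedgraph(table: pd.DataFrame,
                    cpg_positions: dict[str, int],
                    chrom: str,
                    tss: int | None,
                    strand: str,
                    path,
                    track_line: bool = False,
                    name: str = "INS_promoter_methylation") -> None:
    """Write cohort-mean methylation per CpG as a bedGraph track.

    No genome build is bundled: the caller supplies the genomic TSS
    coordinate, chromosome and strand.  Intervals are 0-based half-open,
    width 1.  On the + strand a CpG at TSS-relative offset d maps to
    ``[tss + d, tss + d + 1)``; on the − strand offsets run in the
    opposite genomic direction, so it maps to ``[tss - d, tss - d + 1)``
    (offset −19 on − strand with TSS t gives ``[t + 19, t + 20)``).
    """
    if tss is None:
        raise ConfigError("a genomic TSS coordinate is required for bedGraph export")
    if strand not in ("+", "-"):
        raise ConfigError(f"strand must be '+' or '-', got {strand!r}")
    if len(table) == 0:
        raise DegenerateDataError("empty cohort: refusing to write an empty track")
    lines = []
    for cpg, offset in cpg_positions.items():
        col = loci.meth_column(cpg)
        vals = pd.to_numeric(table[col], errors="coerce").dropna()
        if vals.empty:
            raise DegenerateDataError(f"no methylation values for {cpg}")
        start = tss + offset if strand == "+" else tss - offset
        lines.append((start, f"{chrom}\t{start}\t{start + 1}\t{vals.mean():.4f}\n"))
    lines.sort(key=lambda t: t[0])
    with open(path, "w", newline="") as fh:
        if track_line:
            fh.write(f'track type=bedGraph name="{name}"\n')
        for _, line in lines:
            fh.write(line)
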