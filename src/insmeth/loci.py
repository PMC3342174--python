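"""Locus metadata: the 7 proximal INS-promoter CpG sites and the 4 SNPs.

CpG sites are named by their base-pair offset from the INS transcription
start site (TSS); all seven lie upstream, so offsets are negative.  Column
identifiers use an ``m`` prefix (``meth_m19`` = CpG at −19 bp) to keep
names sign-free; the mapping to display labels lives here and nowhere else.
"""

from __future__ import annotations

# Ordered 5' -> 3' toward the TSS (most distal first).
CPGS: tuple[str, ...] = ("m234", "m206", "m180", "m135", "m102", "m69", "m19")

#: TSS-relative position in bp (negative = upstream).
CPG_OFFSETS: dict[str, int] = {
    "m19": -19,
    "m69": -69,
    "m102": -102,
    "m135": -135,
    "m180": -180,
    "m206": -206,
    "m234": -234,
}

#: Canonical column order used in cohort files (matches the published
#: table layout, −19 first).
CPG_TABLE_ORDER: tuple[str, ...] = ("m19", "m69", "m102", "m135", "m180", "m206", "m234")

#: SNPs genotyped around the locus. rs689 (A/T, +215 bp of the TSS) tags
#: the VNTR classes; allele A marks short class I alleles and T1D risk.
SNPS: tuple[str, ...] = ("rs689", "rs3842748", "rs4320932", "rs6356")

#: The multi-CpG disease signature: simultaneous hypomethylation at
#: CpG −19, −135 and −234.
TRIPLE_PATTERN: tuple[str, ...] = ("m19", "m135", "m234")

METH_COLUMNS: list[str] = [f"meth_{c}" for c in CPG_TABLE_ORDER]
GENO_COLUMNS: list[str] = [f"geno_{s}" for s in SNPS]


def display_label(cpg: str) -> str:
    """``'m135'`` -> ``'CpG -135'``."""
    return f"CpG {CPG_OFFSETS[cpg]}"


def meth_column(cpg: str) -> str:
    return f"meth_{cpg}"


def geno_column(snp: str) -> str:
    return f"geno_{snp}"
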