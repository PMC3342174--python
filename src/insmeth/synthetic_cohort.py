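"""Synthetic cohort generator for INS-promoter methylation studies.

Generates case-control cohorts with the statistical structure the
downstream analysis assumes:

* per-group percent-methylation marginals (clipped Gaussian on the 0-100
  scale) coupled through a Gaussian copula so CpG-CpG correlations can be
  dialed in per group;
* SNP genotypes drawn as two haplotypes from a latent multivariate normal,
  so pairwise linkage disequilibrium is a single latent correlation per
  SNP pair (``ld_r = 1`` reproduces complete LD);
* additive cis-genotype effects on methylation (allele-specific
  methylation), ``beta`` percent per risk-allele copy;
* an optional linear age trend per CpG.

Two shipped presets, :func:`t1d_default` and :func:`t2d_default`,
calibrate the marginals, correlations, allele frequencies and genotype
effects to the published case-control summaries for a pediatric T1D
cohort (485 cases / 317 age-matched controls) and an adult T2D sample
(132 / 186).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.stats import norm

from . import loci
from .errors import ConfigError

__all__ = [
    "SnpSpec",
    "GroupSpec",
    "AgeModel",
    "ClinicalModel",
    "GeneratorConfig",
    "generate_genotypes",
    "generate_methylation",
    "generate_cohort",
    "t1d_default",
    "t2d_default",
    "with_age_slopes",
]

_PSD_TOL = 1e-8


@dataclass(frozen=True)
class SnpSpec:
    id: str
    risk_allele_freq: float


@dataclass(frozen=True)
class GroupSpec:
    label: str
    n: int


@dataclass(frozen=True)
class AgeModel:
    """Gaussian age distribution plus an optional linear methylation trend.

    ``slope[cpg]`` is percent methylation per year; the trend is applied
    relative to ``mean_age`` so it leaves the group mean untouched.
    """

    mean_age: float
    sd_age: float
    slope: Mapping[str, float] = field(default_factory=dict)
    min_age: float = 1.0


@dataclass(frozen=True)
class ClinicalModel:
    """Optional per-group HbA1c / disease-duration marginals.

    Generated independently of methylation: the study found no
    correlation of promoter methylation with disease duration or
    glycated haemoglobin.
    """

    hba1c_mean: float | None = None
    hba1c_sd: float | None = None
    duration_mean: float | None = None
    duration_sd: float | None = None


def _check_corr(matrix: np.ndarray, names: Sequence[str], what: str) -> None:
    m = np.asarray(matrix, dtype=float)
    k = len(names)
    if m.shape != (k, k):
        raise ConfigError(f"{what}: expected a {k}x{k} matrix, got {m.shape}")
    if not np.allclose(m, m.T, atol=1e-12):
        raise ConfigError(f"{what}: matrix is not symmetric")
    if not np.allclose(np.diag(m), 1.0, atol=1e-12):
        raise ConfigError(f"{what}: diagonal must be 1")
    if np.any(np.abs(m) > 1 + 1e-12):
        i, j = np.unravel_index(np.argmax(np.abs(m)), m.shape)
        raise ConfigError(
            f"{what}: |correlation| > 1 for pair ({names[i]}, {names[j]})"
        )
    # Walk leading principal minors so the error can name the pair that
    # first breaks positive semi-definiteness.
    for k_sub in range(2, k + 1):
        sub = m[:k_sub, :k_sub]
        if np.linalg.eigvalsh(sub).min() < -_PSD_TOL:
            offender = names[k_sub - 1]
            partner = names[int(np.argmax(np.abs(sub[k_sub - 1, : k_sub - 1])))]
            raise ConfigError(
                f"{what}: not positive semi-definite; first violated when "
                f"adding {offender} (strongest partner: {partner})"
            )


@dataclass
class GeneratorConfig:
    """Full parameterization of one synthetic cohort.

    ``marginal_mean``/``marginal_sd`` are the *baseline* (genotype-0,
    mean-age) per-group marginals in percent; the realized population
    mean at a CpG with genotype effects is shifted by
    ``sum_s 2 * freq_s * beta[s][cpg]``.
    """

    cpg_names: tuple[str, ...]
    cpg_positions: dict[str, int]
    groups: list[GroupSpec]
    marginal_mean: dict[str, dict[str, float]]  # group -> cpg -> percent
    marginal_sd: dict[str, dict[str, float]]
    latent_corr: dict[str, np.ndarray]  # group -> (n_cpg, n_cpg)
    snps: list[SnpSpec]
    ld_r: np.ndarray  # (n_snp, n_snp) latent haplotype correlation
    beta: dict[str, dict[str, float]]  # snp -> cpg -> percent per allele
    age_model: AgeModel
    seed: int = 0
    clinical: dict[str, ClinicalModel] = field(default_factory=dict)
    sex_ratio_m: float = 0.5

    # -- validation ---------------------------------------------------

    def validate(self) -> "GeneratorConfig":
        if not self.cpg_names:
            raise ConfigError("cpg_names is empty")
        if set(self.cpg_positions) != set(self.cpg_names):
            raise ConfigError("cpg_positions must cover exactly cpg_names")
        if not self.groups:
            raise ConfigError("at least one group is required")
        labels = [g.label for g in self.groups]
        if len(set(labels)) != len(labels):
            raise ConfigError("duplicate group labels")
        for g in self.groups:
            if g.n < 1:
                raise ConfigError(f"group {g.label!r}: n must be >= 1, got {g.n}")
        for g in labels:
            for table, what, lo, hi in (
                (self.marginal_mean, "marginal_mean", 0.0, 100.0),
                (self.marginal_sd, "marginal_sd", np.nextafter(0, 1), np.inf),
            ):
                if g not in table:
                    raise ConfigError(f"{what} missing group {g!r}")
                for c in self.cpg_names:
                    v = table[g].get(c)
                    if v is None:
                        raise ConfigError(f"{what}[{g}] missing CpG {c!r}")
                    if not (lo <= v <= hi):
                        raise ConfigError(f"{what}[{g}][{c}] = {v} out of range")
            if g not in self.latent_corr:
                raise ConfigError(f"latent_corr missing group {g!r}")
            _check_corr(self.latent_corr[g], self.cpg_names, f"latent_corr[{g}]")
        snp_ids = [s.id for s in self.snps]
        if len(set(snp_ids)) != len(snp_ids):
            raise ConfigError("duplicate SNP ids")
        for s in self.snps:
            if not (0.0 <= s.risk_allele_freq <= 1.0):
                raise ConfigError(
                    f"SNP {s.id}: risk_allele_freq {s.risk_allele_freq} not in [0, 1]"
                )
        if self.snps:
            _check_corr(self.ld_r, snp_ids, "ld_r")
        for snp, per_cpg in self.beta.items():
            if snp not in snp_ids:
                raise ConfigError(f"beta references unknown SNP {snp!r}")
            for c in per_cpg:
                if c not in self.cpg_names:
                    raise ConfigError(f"beta[{snp}] references unknown CpG {c!r}")
        if self.age_model.sd_age < 0:
            raise ConfigError("sd_age must be >= 0")
        if not (0.0 <= self.sex_ratio_m <= 1.0):
            raise ConfigError("sex_ratio_m must be in [0, 1]")
        return self

    # -- (de)serialization --------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["latent_corr"] = {
            g: np.asarray(m, dtype=float).tolist() for g, m in self.latent_corr.items()
        }
        d["ld_r"] = np.asarray(self.ld_r, dtype=float).tolist()
        d["cpg_names"] = list(self.cpg_names)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "GeneratorConfig":
        d = dict(d)
        d["cpg_names"] = tuple(d["cpg_names"])
        d["groups"] = [GroupSpec(**g) for g in d["groups"]]
        d["snps"] = [SnpSpec(**s) for s in d["snps"]]
        d["latent_corr"] = {g: np.asarray(m, float) for g, m in d["latent_corr"].items()}
        d["ld_r"] = np.asarray(d["ld_r"], float)
        d["age_model"] = AgeModel(**d["age_model"])
        d["clinical"] = {g: ClinicalModel(**c) for g, c in d.get("clinical", {}).items()}
        return cls(**d).validate()

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "GeneratorConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True)


# ---------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------


def _mvn(rng: np.random.Generator, corr: np.ndarray, n: int) -> np.ndarray:
    """Draw n latent vectors from N(0, corr); tolerates singular (PSD) corr."""
    return rng.multivariate_normal(
        np.zeros(corr.shape[0]), corr, size=n, method="eigh"
    )


def generate_genotypes(
    n: int,
    snps: Sequence[SnpSpec],
    ld_r: np.ndarray,
    seed: int,
) -> pd.DataFrame:
    """Draw genotypes (risk-allele counts 0/1/2) for ``n`` subjects.

    Each subject receives two haplotypes; each haplotype is a thresholded
    draw from a latent multivariate normal with correlation ``ld_r``, so a
    SNP's marginal allele frequency is exact and pairwise LD is controlled
    by the latent correlation (``ld_r = 1`` gives identical columns).
    """
    snp_ids = [s.id for s in snps]
    _check_corr(np.asarray(ld_r, float), snp_ids, "ld_r")
    for s in snps:
        if not (0.0 <= s.risk_allele_freq <= 1.0):
            raise ConfigError(f"SNP {s.id}: bad risk_allele_freq")
    rng = np.random.default_rng(seed)
    thresholds = norm.ppf([s.risk_allele_freq for s in snps])
    z = _mvn(rng, np.asarray(ld_r, float), 2 * n)  # (2n, n_snp)
    alleles = (z < thresholds).astype(np.int64)
    geno = alleles[:n] + alleles[n:]
    return pd.DataFrame(
        {loci.geno_column(s.id): geno[:, j] for j, s in enumerate(snps)}
    )


def generate_methylation(
    genotypes: pd.DataFrame,
    group_labels: Sequence[str],
    ages: Sequence[float],
    config: GeneratorConfig,
    seed: int,
) -> pd.DataFrame:
    """Draw the percent-methylation block for subjects with known
    genotypes, group labels and ages.

    Per subject: a latent vector from N(0, latent_corr[group]) is scaled
    to the group's baseline marginals, then shifted by the additive
    genotype effect (beta × risk-allele count, summed over SNPs) and the
    age trend (slope × (age − mean_age)), and clipped to [0, 100].
    """
    config.validate()
    n = len(group_labels)
    ages = np.asarray(ages, dtype=float)
    if len(ages) != n or len(genotypes) != n:
        raise ConfigError(
            f"dimension mismatch: {n} group labels, {len(ages)} ages, "
            f"{len(genotypes)} genotype rows"
        )
    cpgs = list(config.cpg_names)
    values = np.empty((n, len(cpgs)), dtype=float)
    group_arr = np.asarray(group_labels)
    known = {g.label for g in config.groups}
    unknown = set(group_arr) - known
    if unknown:
        raise ConfigError(f"unknown group label(s): {sorted(unknown)}")

    # One spawned stream per group, in config order: the draw for one
    # group is unaffected by the sizes of the others.
    children = np.random.SeedSequence(seed).spawn(len(config.groups))
    for spec, child in zip(config.groups, children):
        mask = group_arr == spec.label
        ng = int(mask.sum())
        if ng == 0:
            continue
        rng = np.random.default_rng(child)
        z = _mvn(rng, np.asarray(config.latent_corr[spec.label], float), ng)
        mu = np.array([config.marginal_mean[spec.label][c] for c in cpgs])
        sd = np.array([config.marginal_sd[spec.label][c] for c in cpgs])
        values[mask] = mu + sd * z

    for s in config.snps:
        per_cpg = config.beta.get(s.id, {})
        if not per_cpg:
            continue
        g = genotypes[loci.geno_column(s.id)].to_numpy(dtype=float)
        b = np.array([per_cpg.get(c, 0.0) for c in cpgs])
        values += np.outer(g, b)

    slope = np.array([config.age_model.slope.get(c, 0.0) for c in cpgs])
    if np.any(slope != 0):
        values += np.outer(ages - config.age_model.mean_age, slope)

    np.clip(values, 0.0, 100.0, out=values)
    return pd.DataFrame(
        {loci.meth_column(c): values[:, j] for j, c in enumerate(cpgs)}
    )


def generate_cohort(config: GeneratorConfig) -> pd.DataFrame:
    """Assemble a full cohort table from a validated config.

    Deterministic: the root seed is split into fixed, named sub-streams
    (ages/sex/clinical, genotypes, methylation), so e.g. adding a SNP to
    the config does not perturb the methylation draws.
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    demo_ss, geno_ss, meth_ss, clin_ss = ss.spawn(4)

    rows_group: list[str] = []
    ids: list[str] = []
    for spec in config.groups:
        rows_group.extend([spec.label] * spec.n)
        ids.extend(f"{spec.label}-{i:04d}" for i in range(spec.n))
    n = len(rows_group)

    demo_rng = np.random.default_rng(demo_ss)
    ages = demo_rng.normal(config.age_model.mean_age, config.age_model.sd_age, n)
    ages = np.clip(ages, config.age_model.min_age, None)
    sex = np.where(demo_rng.random(n) < config.sex_ratio_m, "M", "F")

    geno_seed = int(geno_ss.generate_state(1)[0])
    genotypes = generate_genotypes(n, config.snps, config.ld_r, geno_seed)

    meth_seed = int(meth_ss.generate_state(1)[0])
    meth = generate_methylation(genotypes, rows_group, ages, config, meth_seed)

    clin_rng = np.random.default_rng(clin_ss)
    hba1c = np.full(n, np.nan)
    duration = np.full(n, np.nan)
    group_arr = np.asarray(rows_group)
    for label, model in config.clinical.items():
        mask = group_arr == label
        ng = int(mask.sum())
        if model.hba1c_mean is not None:
            hba1c[mask] = np.clip(
                clin_rng.normal(model.hba1c_mean, model.hba1c_sd, ng), 0.0, None
            )
        if model.duration_mean is not None:
            duration[mask] = np.clip(
                clin_rng.normal(model.duration_mean, model.duration_sd, ng), 0.0, None
            )

    table = pd.DataFrame({"subject_id": ids, "group": rows_group,
                          "age": ages, "sex": sex})
    table = pd.concat([table, meth, genotypes], axis=1)
    table["hba1c"] = hba1c
    table["duration"] = duration
    return table


# ---------------------------------------------------------------------
# shipped presets
# ---------------------------------------------------------------------


def _corr_from_pairs(names: Sequence[str], pairs: Mapping[tuple[str, str], float],
                     default: float = 0.0) -> np.ndarray:
    k = len(names)
    idx = {c: i for i, c in enumerate(names)}
    m = np.full((k, k), default, dtype=float)
    np.fill_diagonal(m, 1.0)
    for (a, b), v in pairs.items():
        m[idx[a], idx[b]] = m[idx[b], idx[a]] = v
    return m


# Population summaries (percent methylation, mean/sd per CpG) the presets
# are calibrated to.  T1D: pediatric cases vs age-matched controls.
_T1D_CASE = {"m19": (54, 10), "m69": (90, 4), "m102": (73, 6), "m135": (52, 9),
             "m180": (69, 7), "m206": (91, 5), "m234": (54, 9)}
_T1D_CTRL = {"m19": (64, 6), "m69": (89, 6), "m102": (73, 9), "m135": (68, 5),
             "m180": (66, 11), "m206": (91, 7), "m234": (62, 6)}
# T2D: adult non-obese cases vs age/BMI-matched controls.
_T2D_CASE = {"m19": (47, 11), "m69": (88, 11), "m102": (68, 18), "m135": (58, 10),
             "m180": (57, 19), "m206": (91, 10), "m234": (57, 9)}
_T2D_CTRL = {"m19": (54, 10), "m69": (88, 6), "m102": (64, 13), "m135": (55, 10),
             "m180": (61, 11), "m206": (93, 7), "m234": (51, 6)}

# Latent CpG-CpG correlations.  The disease-associated trio (−19, −135,
# −234) is tightly coupled in the T1D calibration (0.77 for −19/−135,
# 0.65 for −135/−234), −180 couples moderately, the rest weakly.
_T1D_CORR_PAIRS = {
    ("m19", "m135"): 0.77, ("m135", "m234"): 0.65, ("m19", "m234"): 0.60,
    ("m19", "m180"): 0.40, ("m135", "m180"): 0.45, ("m234", "m180"): 0.40,
    ("m69", "m102"): 0.30, ("m69", "m206"): 0.30, ("m102", "m206"): 0.30,
    ("m69", "m180"): 0.25, ("m102", "m180"): 0.25, ("m206", "m180"): 0.25,
}
# T2D cohort: −19 and −234 shift independently, so their coupling is weak.
_T2D_CORR_PAIRS = {
    ("m19", "m135"): 0.40, ("m135", "m234"): 0.40, ("m19", "m234"): 0.10,
    ("m19", "m180"): 0.25, ("m135", "m180"): 0.25, ("m234", "m180"): 0.25,
    ("m69", "m102"): 0.30, ("m69", "m206"): 0.30, ("m102", "m206"): 0.30,
    ("m69", "m180"): 0.20, ("m102", "m180"): 0.20, ("m206", "m180"): 0.20,
}

_SNPS = [
    SnpSpec("rs689", 0.70),       # A allele (class I VNTR tag, T1D risk)
    SnpSpec("rs3842748", 0.68),
    SnpSpec("rs4320932", 0.30),
    SnpSpec("rs6356", 0.40),
]
_LD_PAIRS = {
    ("rs689", "rs3842748"): 0.95,
    ("rs689", "rs4320932"): 0.20, ("rs689", "rs6356"): 0.25,
    ("rs3842748", "rs4320932"): 0.20, ("rs3842748", "rs6356"): 0.25,
    ("rs4320932", "rs6356"): 0.10,
}
# Direct allele-specific effect (percent per risk-allele copy): carried by
# rs689 only; linked SNPs pick up their association through LD.
_BETA = {"rs689": {"m69": 1.5, "m102": 2.0, "m180": 3.0, "m206": 1.5}}


def _calibrated_marginals(
    targets: Mapping[str, tuple[float, float]],
    snps: Sequence[SnpSpec],
    beta: Mapping[str, Mapping[str, float]],
    cpgs: Sequence[str],
) -> tuple[dict[str, float], dict[str, float]]:
    """Back out baseline mean/sd so the *population* moments (baseline +
    additive genotype effect) match the published targets."""
    means, sds = {}, {}
    for c in cpgs:
        mu_t, sd_t = targets[c]
        shift = sum(2 * s.risk_allele_freq * beta.get(s.id, {}).get(c, 0.0)
                    for s in snps)
        extra_var = sum(
            2 * s.risk_allele_freq * (1 - s.risk_allele_freq)
            * beta.get(s.id, {}).get(c, 0.0) ** 2
            for s in snps
        )
        means[c] = mu_t - shift
        sds[c] = float(np.sqrt(max(sd_t**2 - extra_var, 1.0)))
    return means, sds


def _preset(case_label: str, case_n: int, ctrl_n: int,
            case_targets, ctrl_targets, corr_pairs, default_corr: float,
            age: AgeModel, clinical: dict[str, ClinicalModel],
            seed: int) -> GeneratorConfig:
    cpgs = loci.CPG_TABLE_ORDER
    case_mu, case_sd = _calibrated_marginals(case_targets, _SNPS, _BETA, cpgs)
    ctrl_mu, ctrl_sd = _calibrated_marginals(ctrl_targets, _SNPS, _BETA, cpgs)
    corr = _corr_from_pairs(cpgs, corr_pairs, default_corr)
    return GeneratorConfig(
        cpg_names=tuple(cpgs),
        cpg_positions={c: loci.CPG_OFFSETS[c] for c in cpgs},
        groups=[GroupSpec(case_label, case_n), GroupSpec("control", ctrl_n)],
        marginal_mean={case_label: case_mu, "control": ctrl_mu},
        marginal_sd={case_label: case_sd, "control": ctrl_sd},
        # Control correlations are not published beyond "also seen in
        # controls"; the case matrix is reused (calibration assumption).
        latent_corr={case_label: corr, "control": corr.copy()},
        snps=list(_SNPS),
        ld_r=_corr_from_pairs([s.id for s in _SNPS], _LD_PAIRS),
        beta={s: dict(c) for s, c in _BETA.items()},
        age_model=age,
        clinical=clinical,
        seed=seed,
    ).validate()


def t1d_default(seed: int = 0) -> GeneratorConfig:
    """Pediatric T1D case-control calibration: 485 cases vs 317 controls,
    ages ~12 ± 5 yr, no age trend (young cohort)."""
    return _preset(
        "T1D", 485, 317, _T1D_CASE, _T1D_CTRL, _T1D_CORR_PAIRS, 0.15,
        AgeModel(mean_age=12.0, sd_age=4.9),
        {"T1D": ClinicalModel(hba1c_mean=8.1, hba1c_sd=1.4,
                              duration_mean=7.5, duration_sd=8.5)},
        seed,
    )


def t2d_default(seed: int = 0) -> GeneratorConfig:
    """Adult non-obese T2D calibration: 132 cases vs 186 age-matched
    controls, ages ~55 ± 8 yr."""
    return _preset(
        "T2D", 132, 186, _T2D_CASE, _T2D_CTRL, _T2D_CORR_PAIRS, 0.15,
        AgeModel(mean_age=55.0, sd_age=8.0),
        {"T2D": ClinicalModel(duration_mean=4.0, duration_sd=2.0)},
        seed,
    )


def with_age_slopes(config: GeneratorConfig, slope: float | Mapping[str, float]
                    ) -> GeneratorConfig:
    """Return a copy of ``config`` with a per-CpG age trend enabled
    (e.g. ``slope=-0.2`` percent/yr emulates the downward drift seen in
    older control cohorts)."""
    if isinstance(slope, Mapping):
        slopes = dict(slope)
    else:
        slopes = {c: float(slope) for c in config.cpg_names}
    new_age = dataclasses.replace(config.age_model, slope=slopes)
    return dataclasses.replace(config, age_model=new_age).validate()

PRESETS = {"t1d_default": t1d_default, "t2d_default": t2d_default}
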