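import dataclasses

import numpy as np
import pytest

from insmeth import loci
from insmeth.synthetic_cohort import (GeneratorConfig, generate_cohort,
                                      t1d_default, t2d_default)


@pytest.fixture(scope="session")
def t1d_config() -> GeneratorConfig:
    return t1d_default(seed=1)


@pytest.fixture(scope="session")
def t2d_config() -> GeneratorConfig:
    return t2d_default(seed=1)


@pytest.fixture(scope="session")
def t1d_cohort(t1d_config):
    return generate_cohort(t1d_config)


@pytest.fixture(scope="session")
def t2d_cohort(t2d_config):
    return generate_cohort(t2d_config)


def neutral_config(n_case: int = 200, n_ctrl: int = 200, seed: int = 7,
                   corr: np.ndarray | None = None) -> GeneratorConfig:
    """A mid-range no-genotype-effect, no-age-trend variant of the T1D
    preset: means far from the [0, 100] bounds so clipping is inactive.
    Useful for fidelity/calibration properties."""
    cfg = t1d_default(seed=seed)
    cpgs = cfg.cpg_names
    mean = {g: {c: 50.0 for c in cpgs} for g in ("T1D", "control")}
    sd = {g: {c: 8.0 for c in cpgs} for g in ("T1D", "control")}
    latent = cfg.latent_corr if corr is None else {
        "T1D": corr, "control": corr.copy()}
    groups = [dataclasses.replace(cfg.groups[0], n=n_case),
              dataclasses.replace(cfg.groups[1], n=n_ctrl)]
    return dataclasses.replace(
        cfg, groups=groups, marginal_mean=mean, marginal_sd=sd,
        latent_corr=latent, beta={}, seed=seed,
    ).validate()


@pytest.fixture
def small_cohort():
    cfg = neutral_config(n_case=30, n_ctrl=25, seed=3)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def meth_columns():
    return [loci.meth_column(c) for c in loci.CPG_TABLE_ORDER]
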