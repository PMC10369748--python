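import numpy as np
import pandas as pd
import pytest

from mviv.dgp import DGPConfig, simulate_cohorts, variant_table
from mviv.gwas import SummaryStats
from mviv.instruments import HarmonisedSet


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_config():
    """Fast individual-level configuration for unit tests."""
    return DGPConfig(n_individuals=2_000, n_snps=20, n_exposure_snps=10, seed=42)


@pytest.fixture
def small_cohorts(small_config):
    return simulate_cohorts(small_config)


def make_sumstats(beta, se, pvalue=None, eaf=None, n=10_000, trait="exposure",
                  n_palindromic=0):
    """Construct a consistent SummaryStats table from raw vectors."""
    from scipy import stats as sps

    beta = np.asarray(beta, float)
    se = np.asarray(se, float)
    m = len(beta)
    df = variant_table(m, n_palindromic=n_palindromic)
    df["eaf"] = 0.3 * np.ones(m) if eaf is None else np.asarray(eaf, float)
    df["beta"] = beta
    df["se"] = se
    df["pvalue"] = (2 * sps.norm.sf(np.abs(beta / se))
                    if pvalue is None else np.asarray(pvalue, float))
    df["n"] = n
    return SummaryStats(df, trait=trait)


def make_harmonised(bx, sex, by, sey, bp=None, sep=None):
    bx = np.asarray(bx, float)
    return HarmonisedSet(
        variant_ids=[f"rs{i + 1}" for i in range(len(bx))],
        exposure_beta=bx,
        exposure_se=np.asarray(sex, float),
        outcome_beta=np.asarray(by, float),
        outcome_se=np.asarray(sey, float),
        covariate_beta=None if bp is None else np.asarray(bp, float),
        covariate_se=None if sep is None else np.asarray(sep, float),
    )


@pytest.fixture
def toy_harmonised():
    """Five strong instruments with a common true ratio of 0.5 plus noise."""
    r = np.random.default_rng(7)
    bx = r.uniform(0.08, 0.2, 5)
    sex = np.full(5, 0.005)
    sey = np.full(5, 0.01)
    by = 0.5 * bx + r.normal(0, 0.005, 5)
    return make_harmonised(bx, sex, by, sey)
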