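import numpy as np
import pytest
from hypothesis import settings

from pqtlmr.sumstats import CASE_CONTROL, QUANTITATIVE, GwasRecord, HarmonizedPair

settings.register_profile("suite", derandomize=True, deadline=None, max_examples=50)
settings.load_profile("suite")


def make_record(
    snp="rs1",
    chrom="1",
    pos=1_000_000,
    ea="A",
    oa="G",
    eaf=0.3,
    beta=0.1,
    se=0.02,
    pval=0.001,
    n=10_000,
    trait_type=QUANTITATIVE,
    case_fraction=None,
):
    if trait_type == CASE_CONTROL and case_fraction is None:
        case_fraction = 0.5
    return GwasRecord(snp, chrom, pos, ea, oa, eaf, beta, se, pval, n, trait_type, case_fraction)


def make_pair(beta_exp, beta_out, se_exp=0.01, se_out=0.05, snp="rs1", n_exp=10_000, n_out=50_000):
    exp = make_record(snp=snp, beta=beta_exp, se=se_exp, n=n_exp)
    out = make_record(
        snp=snp,
        beta=beta_out,
        se=se_out,
        n=n_out,
        trait_type=CASE_CONTROL,
        case_fraction=0.5,
    )
    return HarmonizedPair(snp, exp, out, "none")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_bundle():
    """12 proteins, one causal — shared across pipeline-level tests."""
    from pqtlmr.simulate import simulate_proteome

    return simulate_proteome(12, 1 / 12, seed=3)
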