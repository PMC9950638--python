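import numpy as np
import pytest
from hypothesis import HealthCheck, settings
from scipy import stats

from bidimr.sumstats import (HarmonizedInstrumentSet, HarmonizedRecord,
                             SummaryStatRecord)

settings.register_profile(
    "default", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("default")


def make_record(snp_id="rs1", chrom="1", pos=100, ea="A", oa="G", beta=0.1,
                se=0.02, pval=None, n=10_000, eaf=0.3, trait_id="trait"):
    if pval is None:
        pval = float(max(2 * stats.norm.sf(abs(beta / se)), 1e-320))
    return SummaryStatRecord(snp_id=snp_id, chrom=chrom, pos=pos,
                             effect_allele=ea, other_allele=oa, beta=beta,
                             se=se, pval=pval, n=n, eaf=eaf, trait_id=trait_id)


def make_hset(be, se_e, bo, se_o, n_exp=8000, n_out=8000):
    """HarmonizedInstrumentSet from parallel effect arrays."""
    records = [
        HarmonizedRecord(
            snp_id=f"rs{i}", beta_exp=float(b), se_exp=float(s),
            pval_exp=float(2 * stats.norm.sf(abs(b / s))),
            beta_out=float(bo_i), se_out=float(so_i),
            pval_out=float(2 * stats.norm.sf(abs(bo_i / so_i))),
            n_exp=n_exp, n_out=n_out)
        for i, (b, s, bo_i, so_i) in enumerate(zip(be, se_e, bo, se_o))
    ]
    return HarmonizedInstrumentSet("exp", "out", records)


@pytest.fixture
def record_factory():
    return make_record


@pytest.fixture
def hset_factory():
    return make_hset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
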