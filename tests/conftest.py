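import numpy as np
import pandas as pd
import pytest

from twostepmr.sumstats import HarmonizedSet, SummaryStats, normal_p


def make_hset(bx, sx, by, sy, snp_ids=None, outcome_scale="sd", p_out=None):
    """Single-exposure HarmonizedSet from plain arrays."""
    bx = np.asarray(bx, dtype=float)
    if snp_ids is None:
        snp_ids = [f"rs{i + 1}" for i in range(len(bx))]
    return HarmonizedSet(
        snp_ids=list(snp_ids), exposure_ids=["X"], outcome_id="Y",
        beta_exp=bx[:, None], se_exp=np.asarray(sx, float)[:, None],
        beta_out=np.asarray(by, float), se_out=np.asarray(sy, float),
        p_out=p_out, outcome_scale=outcome_scale)


def make_table(trait_id, beta, se, pvalue=None, snp_ids=None, ea="A", oa="G",
               eaf=0.3, trait_type="continuous", chrom=1, pos=None, n=1e5):
    beta = np.asarray(beta, dtype=float)
    J = len(beta)
    if snp_ids is None:
        snp_ids = [f"rs{i + 1}" for i in range(J)]
    if pvalue is None:
        pvalue = normal_p(beta, se)
    df = pd.DataFrame({
        "snp_id": snp_ids, "chrom": chrom,
        "pos": pos if pos is not None else 1_000_000 + np.arange(J) * 50_000_000,
        "effect_allele": ea, "other_allele": oa, "eaf": eaf,
        "beta": beta, "se": se, "pvalue": pvalue, "n": n,
    })
    return SummaryStats(trait_id=trait_id, trait_type=trait_type, df=df)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def five_snp_hset():
    """Small heterogeneous instrument set used by several oracle tests."""
    rng = np.random.default_rng(7)
    bx = rng.uniform(0.05, 0.2, 5) * rng.choice([-1, 1], 5)
    sx = rng.uniform(0.005, 0.02, 5)
    by = 0.4 * bx + rng.normal(0, 0.01, 5)
    sy = rng.uniform(0.005, 0.02, 5)
    return make_hset(bx, sx, by, sy)
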