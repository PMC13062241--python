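import numpy as np
import pandas as pd
import pytest

from sjoverlap.meta_analysis import EffectEstimate
from sjoverlap.sumstats_io import SumStats


def make_estimates(pairs):
    """EffectEstimates from (log_rr, se) pairs."""
    return [
        EffectEstimate(study_label=f"study{i}", log_rr=lr, se=se)
        for i, (lr, se) in enumerate(pairs)
    ]


@pytest.fixture
def sjd_trio():
    """First-degree concordant-SjD studies (logRR, SE) as published."""
    return make_estimates([(2.55, 0.31), (2.52, 0.13), (2.16, 0.077)])


@pytest.fixture
def ra_pair():
    return make_estimates([(1.08, 0.12), (0.52, 0.065)])


@pytest.fixture
def sle_trio():
    return make_estimates([(1.17, 0.78), (1.77, 0.093), (1.27, 0.13)])


def make_sumstats(
    label="trait",
    chrom=None,
    pos=None,
    beta=None,
    se=None,
    p=None,
    n=10_000,
    effect_allele=None,
    other_allele=None,
):
    """Small hand-rolled SumStats for unit tests."""
    m = len(pos)
    chrom = chrom if chrom is not None else ["1"] * m
    beta = beta if beta is not None else np.zeros(m)
    se = se if se is not None else np.ones(m)
    z = np.asarray(beta) / np.asarray(se)
    from scipy import stats as st

    p = p if p is not None else 2 * st.norm.sf(np.abs(z))
    records = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": pos,
            "effect_allele": effect_allele if effect_allele is not None else ["A"] * m,
            "other_allele": other_allele if other_allele is not None else ["G"] * m,
            "beta": beta,
            "se": se,
            "p": p,
            "n": n,
        }
    )
    return SumStats(disease_label=label, records=records)
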