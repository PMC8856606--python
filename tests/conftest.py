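import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from mrscreen import HarmonizedSet, SummaryStats

settings.register_profile("ci", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("ci")


def make_sumstats(rows, trait_name="trait", trait_type="continuous"):
    """Build a SummaryStats from a list of per-SNP dicts, filling defaults."""
    defaults = dict(CHR="1", POS=1000, EA="A", OA="G", EAF=0.3,
                    BETA=0.1, SE=0.02, P=1e-6, N=10000.0)
    full = []
    for i, row in enumerate(rows):
        r = dict(defaults)
        r.setdefault("SNP", f"rs{i + 1}")
        r.update(row)
        full.append(r)
    df = pd.DataFrame(full)[["SNP", "CHR", "POS", "EA", "OA", "EAF",
                             "BETA", "SE", "P", "N"]]
    return SummaryStats(trait_name, df, trait_type)


def make_hset(beta_exp, beta_out, se_exp=None, se_out=None, eaf=None,
              n_exp=18473.0, n_out=46351.0):
    beta_exp = np.asarray(beta_exp, dtype=float)
    beta_out = np.asarray(beta_out, dtype=float)
    k = len(beta_exp)
    se_exp = np.full(k, 0.01) if se_exp is None else np.asarray(se_exp, float)
    se_out = np.full(k, 0.05) if se_out is None else np.asarray(se_out, float)
    eaf = np.full(k, 0.3) if eaf is None else np.asarray(eaf, float)
    return HarmonizedSet(
        snp_ids=np.array([f"rs{i + 1}" for i in range(k)]),
        beta_exp=beta_exp, se_exp=se_exp, eaf_exp=eaf,
        beta_out=beta_out, se_out=se_out, eaf_out=eaf,
        n_exp=np.full(k, n_exp), n_out=np.full(k, n_out),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20231101)
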