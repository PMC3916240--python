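import numpy as np
import pytest

from xwas.assoc import SexStratifiedEstimate

# Published joint sex-stratified summary statistics (slope02 male coding)
# for the three lead SNPs: (beta_F, se_F, eaf_F, beta_M, se_M, eaf_M,
# combined EAF). rs1751138 sits near ITM2A, rs182838724 near ATRX (both
# height); rs139163435 is the Xq23 fasting-insulin signal.
LEAD_SNPS = {
    "rs1751138": (0.093, 0.014, 0.645, 0.036, 0.010, 0.642, 0.643),
    "rs182838724": (0.058, 0.015, 0.301, 0.052, 0.010, 0.293, 0.297),
    "rs139163435": (-0.118, 0.039, 0.071, -0.139, 0.028, 0.072, 0.072),
}


def lead_estimates(snp_id):
    bf, sf, eaf_f, bm, sm, eaf_m, eaf = LEAD_SNPS[snp_id]
    est_f = SexStratifiedEstimate(snp_id=snp_id, sex="female", beta=bf, se=sf,
                                  p=0.5, n=12000, eaf=eaf_f)
    est_m = SexStratifiedEstimate(snp_id=snp_id, sex="male", beta=bm, se=sm,
                                  p=0.5, n=12000, eaf=eaf_m,
                                  male_coding="slope02")
    return est_f, est_m, eaf


@pytest.fixture
def rng():
    return np.random.default_rng(20140206)
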