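import numpy as np
import pytest

from dnphkin import RateConstantSet, ReactionConditions

#: WT-like first-half-reaction constants (single-turnover regime)
WT_K1, WT_K2, WT_K3 = 1.0, 2.36, 0.219
#: slow-second-half variant: first half nearly unchanged, covalent-intermediate
#: hydrolysis slowed so that turnover is limited by the second half-reaction
SLOW2_K3 = 0.270
SLOW2_KCAT = 0.00158
SLOW2_K5 = SLOW2_KCAT * SLOW2_K3 / (SLOW2_K3 - SLOW2_KCAT)


@pytest.fixture
def wt_rates() -> RateConstantSet:
    return RateConstantSet(k1=WT_K1, k2=WT_K2, k3=WT_K3)


@pytest.fixture
def slow_second_half_rates() -> RateConstantSet:
    return RateConstantSet(k1=1.0, k2=2.4, k3=SLOW2_K3, k5=SLOW2_K5)


@pytest.fixture
def single_turnover_conditions():
    def make(enzyme_total: float, substrate_total: float = 10.0, **kwargs):
        kwargs.setdefault("dead_time", 0.0)
        return ReactionConditions(
            enzyme_total=enzyme_total, substrate_total=substrate_total, **kwargs
        )

    return make
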